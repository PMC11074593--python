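{
  "table2_loci.tsv": "0b8d4951292e6c200041af8807db5cbbec730aec182b8e89858f8f8d3473cff3",
  "table3_i2_bins.tsv": "ea78cb9211196381983f9b425b1fc1646d9d5482e45b036e3a4fe56cdbc3725b"
}
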