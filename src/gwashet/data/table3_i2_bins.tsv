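dataset	n_variants	i2_low	i2_moderate	i2_large	i2_extreme	or_printed	ci_printed	p_printed
GWAS2013	19	18	1	0	0	NA	NA	NA
GWAS2019	25	24	1	0	0	0.75	0.04–12.82	1
GWAS+GWAX2017	25	13	5	2	5	16.62	1.91–144.24	6.07E-03
GWAS+GWAX2018	26	1	2	2	21	450	26.36–7681.35	6.97E-09
GWAS+GWAX2021a	33	16	3	8	6	19.13	2.28–160.34	2.12E-03
GWAS+GWAX2021c	36	21	2	9	4	12.86	1.54–107.11	1.19E-02
GWAS+GWAX2022a	83	56	19	8	0	8.68	1.1–68.46	3.42E-02
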