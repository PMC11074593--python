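# Methods

## Model and estimators

All effects are natural-log odds ratios; odds ratios appear only at I/O
boundaries, because every estimator below is additive in the effect.

Given k study effects x_i with standard errors s_i and weights
w_i = 1/s_i^2:

* **Fixed-effects IVW.**  X = Σ w_i x_i / Σ w_i, var(X) = 1/Σ w_i,
  Z = X/SE(X), two-sided P from the standard normal.  The model assumes a
  single common true effect.
* **Cochran's Q.**  Q = Σ w_i (x_i − X)^2, referred to the upper tail of
  chi-square with k−1 df.  Q grows with both the number and the size of
  studies.
* **I².**  I² = max{0, (Q − (k−1))/Q}, reported in percent.  The formula
  is 0/0 at Q = 0; the package defines I²(Q=0) = 0, which is the limit
  from above and the only value consistent with "no observed dispersion".
* **τ² (DerSimonian–Laird).**  τ² = max{0, (Q − (k−1)) /
  (Σ w_i − Σ w_i²/Σ w_i)}.  This moment estimator is the only τ²
  estimator implemented (no REML or Paule–Mandel): it is the one whose
  behaviour the downstream analyses are calibrated against.  A degenerate
  denominator (all weight concentrated in one study) returns 0 with a
  warning.
* **Random-effects IVW.**  Weights w_i^R = 1/(s_i² + τ²); the pooled
  estimate, SE and Z follow the same algebra.  When τ² = 0 the result
  equals the fixed-effects result exactly (same code path invariant,
  tested).
* **Sample-size-weighted Z.**  Z = Σ √N_i z_i d_i / √(Σ N_i).  This is
  the documented approximation to sample-size-weighted meta-analysis of
  Z statistics; correction for sample overlap between input studies is
  deliberately out of scope.

k = 1 inputs return the study itself with the heterogeneity block absent
(`het=None`) rather than erroring, to keep pipelines total;
heterogeneity statistics themselves require k ≥ 2.

## Heterogeneity profiles and contingency comparisons

Per-variant I² values are binned as [0–25] low, (25–50] moderate,
(50–75] large, (75–100] extreme; the first bin is closed at 25, matching
the bracket notation of the published bin table.  Dataset-vs-reference
comparisons dichotomise each profile at I² = 25 (strictly above vs
at-or-below) and form the 2×2 table [[a,b],[c,d]] with the dataset on
the top row.  Then:

* OR = (a·d)/(b·c), 95% CI by Woolf's log method with multiplier 1.96
  (the conventional rounded value, which is what reproduces the printed
  CI bounds digit-for-digit; the exact quantile 1.95996 differs in the
  last printed digit for extreme ORs).
* Chi-square with Yates continuity correction, each cell contributing
  (max{0, |O−E|−0.5})²/E.  The truncation at zero means P = 1 exactly
  when every |O−E| ≤ 0.5 — which is how the printed "P = 1" for the
  GWAS2019 row arises.  This variant was selected because it reproduces
  all seven printed P-values; Fisher's exact test does not.
* A zero cell leaves OR/CI undefined (flagged) by default; a Haldane
  +0.5 on all cells is available but off, since every printed table cell
  is positive.

Display rounding is half-up to 2 decimals for OR/CI (Python's built-in
banker's rounding would print 19.12 where the published table prints
19.13) and 3 significant figures in scientific notation for P.
Integer percentages everywhere use round-half-up.

## Fixtures and their quirks

Two fixtures ship as tab-delimited text with a SHA-256 manifest checked
at load time.

The 82-locus table (324 records, 9 datasets) is transcribed verbatim,
including its oddities, which are preserved rather than corrected:

* one record (rs4147929) is printed with chromosome 1 inside a
  chromosome-19 locus; it carries a `chrom_typo` curation flag, and
  analyses key on the locus label, never the position;
* two distinct loci share the cytoband 19p13.3, so locus labels are
  `"<index>:<cytoband>"` to stay unique;
* indel alleles (TC, GTCTT, TGAG, GC) occur, so allele validation
  accepts any non-empty ACGT string while still rejecting multi-allele
  lists;
* the strongest signals are printed as "0", "<1.0e-300" or with
  exponents below double-precision underflow; "<x" parses to its bound
  and sub-underflow values to 0.0, so records admit p ∈ [0,1] with 0
  documented as underflow (user-facing readers still enforce p ∈ (0,1]);
* no standard errors are printed; where a 95% CI is available,
  se = (ln hi − ln lo)/(2·1.96) is recovered at load, and OR-less rows
  carry beta = se = None (the census and best-signal analyses use only
  P).

**Census membership.**  Six printed records have P ≥ 5×10⁻⁸ (two loci
consist only of such records), so re-applying the strict genome-wide
threshold to the printed table drops loci that the published census
counts.  The reproduction path therefore treats membership in the
curated table as the hit definition (`build_matrix(..., alpha=None)`);
user-supplied data defaults to the strict threshold.  Even so, the
published "32 single-dataset / 50 replicated" split is not derivable
from the printed table under any counting rule we could construct
(dataset-presence counting gives 35/47, strict thresholding 34/46); the
totals 82, the all-nine count 14 (17%) and the named 14-locus set do
reproduce.  The `reproduce-paper` report prints the discrepant lines as
FAIL and exits nonzero rather than papering over them.

## Synthetic panels

The generator emulates the data-generating process the heterogeneity
analysis presumes, not real LD-structured genomes:

* per variant, a control-allele frequency is drawn uniformly from
  `maf_range` (default 0.05–0.5) and **shared across cohorts**, so
  effect-size differences are the only source of Q;
* true per-cohort log-ORs are mu + N(0, τ²); proxy cohorts are then
  scaled by `proxy_dilution` (default 0.5: one affected first-degree
  relative shares half the proband's alleles; the factor is a parameter
  because ascertainment with two affected relatives would differ);
* misclassification of a fraction π of the case group is modelled as
  multiplicative attenuation of the log-OR by (1 − π) — its first-order
  effect — with an exact mixture mode (case allele frequency mixed with
  the control frequency) for validation; the two agree to ~1% at
  β = 0.1, π = 0.2;
* observed tables are multinomial draws over the four allele-count cells
  at 2(n_cases + n_controls) alleles; the observed log-OR is ln(ad/bc)
  with SE √(1/a+1/b+1/c+1/d), Haldane +0.5 applied only when a zero cell
  occurs; P is the Wald two-sided normal tail.

The RNG seed is a mandatory config field; there is no hidden global
state, and fixed seeds reproduce tables bit-for-bit.

What passing simulation tests do **not** show: behaviour under LD,
allele-frequency differences between cohorts, covariate adjustment,
imputation error, or sample overlap between cohorts — all absent from
the generator by design.

Default problem sizes (2000 variants for the emergence contrast at
cohort sizes 25k/25k clinical and 100k/100k proxy; 5000 variants × 10
cohorts for τ² recovery; 10⁴ replicates per Monte-Carlo power point)
were chosen as the smallest panels at which the binomial/Monte-Carlo
error is comfortably below the effects being measured.

## Power

Analytic power uses the Wald noncentrality NCP = (β_eff/se)² with
β_eff = β·dilution for proxy designs and se from the **expected**
allele-count table; power = P(χ²₁(NCP) > χ²₁ quantile at 1−α), with
α = 5×10⁻⁸ by default.  At β = 0 this returns exactly α.  Power is not
symmetric in the sign of β at fixed control-allele frequency, because
the implied case frequency (and hence the information) shifts
asymmetrically.

`required_n_ratio` solves, by bisection on a log sample-size multiplier
(brentq, xtol 1e-12), the proxy and clinical total N reaching a target
power and returns their ratio.  The ratio tends to (1/dilution)² as
β → 0 — the "about four times" rule at dilution 0.5 — and drifts from it
at large β; the fourfold figure is asserted only in the small-effect
limit.

`heterogeneity_power_loss` estimates by Monte Carlo the rejection rate
of the fixed- and random-effects meta Z tests across a τ² grid at fixed
per-cohort sample size.  Caveat documented here because it is easy to
misread: the DerSimonian–Laird random-effects test is **anti-conservative
at small k** under real heterogeneity (measured type-I ≈ 0.12 at k = 5,
τ² = 0.01, nominal 0.05), converging to nominal as k grows (≈ 0.054 at
k = 40).  The tests assert this actual behaviour, not idealised
calibration.

## Design choices where the design was open

* Genome-wide significance is a strict inequality (P < 5×10⁻⁸);
  a boundary P is not a hit.
* Palindromic (A/T, C/G) variants default to "warn and keep" during
  harmonization — the packaged tables carry no frequency data that could
  resolve strand — with a strict refuse mode available.
* Best-signal ties are reported in full, never broken arbitrarily.
* Locus identity for the packaged table comes solely from its printed
  locus grouping; positional single-linkage merging (500 kb window) is
  only for user data and never overwrites existing labels.
* Multi-variant loci keep every printed record; the replication census
  resolves at locus level.

## Known limitations

* No sample-overlap correction anywhere: the nine packaged datasets
  share cohorts extensively, so cross-dataset statistics describe the
  printed record, not independent evidence.
* The per-variant I² values behind the packaged bin counts live in
  sources not shipped here; the bin counts are the unit of analysis.
* The simulator's multiplicative misclassification model is first-order;
  use the mixture mode when π is large.
* DerSimonian–Laird τ² is known to be biased low under strong
  heterogeneity with few studies; measured recovery bias at k = 10 is
  ~1–2% for τ² ∈ {0.01, 0.05} at the default simulation sizes.
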