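# gwashet

Heterogeneity-centric meta-analysis of GWAS and GWAS-by-proxy (GWAX)
summary statistics.

## The problem

Alzheimer's-disease genetics has spent a decade pooling clinically
diagnosed case-control GWAS with family-history proxy studies (GWAX) from
population biobanks.  The combined meta-analyses keep growing, yet loci
replicate poorly across them and the estimated SNP heritability falls as
samples grow.  A proxy case carries a diluted effect (about half the log
odds ratio when ascertainment is one affected parent), so mixing clinical
and proxy cohorts builds *statistical heterogeneity* into the
meta-analysis by construction — and heterogeneity erodes the power of the
fixed-effects model those studies rely on.

`gwashet` packages the statistical machinery needed to quantify this:

* **Meta-analysis core** — for study effects $x_i$ (log odds ratios) with
  standard errors $s_i$ and weights $w_i = 1/s_i^2$:
  fixed-effects IVW $\bar X = \sum w_i x_i / \sum w_i$,
  $\mathrm{SE}(\bar X) = 1/\sqrt{\sum w_i}$, $Z = \bar X/\mathrm{SE}$;
  Cochran's $Q = \sum w_i (x_i - \bar X)^2 \sim \chi^2_{k-1}$;
  $I^2 = \max\{0, (Q - (k-1))/Q\}$ (percent);
  DerSimonian–Laird
  $\tau^2 = \max\{0,(Q-(k-1))/(\sum w_i - \sum w_i^2/\sum w_i)\}$;
  random-effects IVW with $w_i^R = 1/(s_i^2 + \tau^2)$; and a
  $\sqrt N$-weighted Z combination.
* **Heterogeneity profiles** — per-variant $I^2$ binned as low [0–25],
  moderate (25–50], large (50–75], extreme (75–100], with 2×2
  dataset-vs-reference comparisons (odds ratio, Woolf 95% CI,
  Yates-corrected chi-square).
* **Replication census** — a locus × dataset matrix of genome-wide
  significant hits ($P < 5\times10^{-8}$), counts of loci significant in
  one / at least two / all datasets, and best-signal attribution.
* **Synthetic panels** — multi-cohort case-control + proxy summary
  statistics with between-cohort variance $\tau^2$, proxy dilution, and
  case-group misclassification, sampled at realistic allele counts.
* **Power** — Wald noncentrality power at genome-wide $\alpha$, the
  proxy/clinical sample-size ratio for equal power (≈ $1/\text{dilution}^2$,
  i.e. fourfold at dilution 0.5), and Monte-Carlo power loss under
  heterogeneity.

Packaged fixtures transcribe, verbatim, the printed record of nine
AD association datasets: an 82-locus table of genome-wide significant
records and the per-dataset $I^2$ bin counts, so the desk-scale analyses
are reproducible offline.

## Worked example

```python
from gwashet import CohortEffect, fixed_effects_ivw, random_effects_ivw

studies = [CohortEffect("study_1", x=0.1, s=0.1),
           CohortEffect("study_2", x=0.3, s=0.1)]
fixed = fixed_effects_ivw(studies)
print(fixed.estimate, fixed.het.q, fixed.het.i2, fixed.het.tau2)
```

Running `python examples/meta_analysis_basics.py` prints

```
fixed effects : estimate=0.2000  se=0.0707  z=2.828  p=4.678e-03
heterogeneity : Q=2.000 (df=1, p=0.157)  I^2=50.0%  tau^2=0.0100
random effects: estimate=0.2000  se=0.1000  z=2.000  p=4.550e-02
```

The two studies disagree by two pooled standard errors, so half the
observed variability is between-study ($I^2 = 50\%$); the random-effects
model inflates the standard error from 0.071 to 0.100 and the pooled
association drops from $p = 0.005$ to $p = 0.046$ — exactly the power
cost heterogeneity imposes.

The other `examples/` scripts are equally short: heterogeneity profiles
and contingency comparisons (`heterogeneity_profiles.py`), the 82-locus
replication census (`replication_census.py`), heterogeneity emergence in
simulated clinical+proxy panels (`simulate_gwax_panel.py`) and proxy
power arithmetic (`proxy_power.py`).

A thin CLI wraps the same functions:

```sh
gwashet meta study_a.tsv study_b.tsv --model random
gwashet replicate            # census of the packaged locus table
gwashet reproduce      # PASS/FAIL report against the printed values
gwashet simulate --config sim.json --out panel/
gwashet power --beta 0.02 --dilution 0.5
```

`reproduce` recomputes every desk-scale printed statistic and
annotates each line PASS/FAIL; it exits nonzero if any line differs (two
census lines are known not to be derivable from the printed table — see
`docs/methods.md`).

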