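"""Power arithmetic of proxy designs and heterogeneous meta-analyses.

A proxy (family-history) case carries roughly half the log odds ratio of
a clinically diagnosed case, so its Wald noncentrality is quartered: a
proxy study needs about four times the sample for equal power.  The
second block shows how between-study variance tau^2 erodes fixed-effects
meta-analysis power at constant total sample size.
"""

from gwashet import (
    PowerQuery,
    analytic_power,
    heterogeneity_power_loss,
    required_n_ratio,
)

clin = PowerQuery(beta=0.1, maf=0.2, n_cases=20_000, n_controls=20_000)
prox = PowerQuery(beta=0.1, maf=0.2, n_cases=20_000, n_controls=20_000,
                  design="proxy", dilution=0.5)
print(f"clinical power (beta=0.1, 20k/20k): {analytic_power(clin):.3f}")
print(f"proxy power    (same n, dilution 0.5): {analytic_power(prox):.3f}")
ratio = required_n_ratio(0.02, dilution=0.5)
print(f"proxy/clinical N for equal power (small beta): {ratio:.2f}")

grid = heterogeneity_power_loss(mu=0.08, tau2_grid=[0.0, 0.002, 0.01],
                                k=5, n_cases=12_000, n_controls=12_000,
                                reps=4000, seed=5)
print("\ntau^2    fixed-effects power   random-effects power")
for _, row in grid.iterrows():
    print(f"{row.tau2:<8g} {row.power_fixed:<21.3f} {row.power_random:.3f}")
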