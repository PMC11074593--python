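"""Pool two study effects and read off the heterogeneity statistics.

Two studies report log odds ratios 0.1 and 0.3, each with standard error
0.1.  Fixed-effects IVW pools them to 0.2; Cochran's Q = 2 on 1 df gives
I^2 = 50% (half the variability is between-study) and a DerSimonian-Laird
tau^2 of 0.01, so the random-effects model widens the standard error from
0.071 to 0.100 — the price of admitting that the true effects differ.
"""

from gwashet import CohortEffect, fixed_effects_ivw, random_effects_ivw

studies = [CohortEffect("study_1", x=0.1, s=0.1),
           CohortEffect("study_2", x=0.3, s=0.1)]

fixed = fixed_effects_ivw(studies)
random = random_effects_ivw(studies)

print(f"fixed effects : estimate={fixed.estimate:.4f}  se={fixed.se:.4f}  "
      f"z={fixed.z:.3f}  p={fixed.p:.3e}")
print(f"heterogeneity : Q={fixed.het.q:.3f} (df={fixed.het.df}, "
      f"p={fixed.het.p_q:.3f})  I^2={fixed.het.i2:.1f}%  "
      f"tau^2={fixed.het.tau2:.4f}")
print(f"random effects: estimate={random.estimate:.4f}  se={random.se:.4f}  "
      f"z={random.z:.3f}  p={random.p:.3e}")
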