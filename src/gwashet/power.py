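"""Power analysis for clinical GWAS, proxy GWAX and heterogeneous meta-analyses.

Analytic power uses the Wald noncentrality of the single-variant log-OR
test: NCP = (beta_eff / se)^2, where beta_eff = beta * dilution for a
proxy design and se comes from the expected 2x2 allele-count table at the
given allele frequency and case/control sizes.  Power is the upper tail
of the noncentral chi-square(1, NCP) beyond the central chi-square
quantile at 1 - alpha.

A proxy design dilutes the log-OR, so matching clinical power requires
roughly (1/dilution)^2 times the sample in the small-effect limit — four
times for dilution 0.5 (one affected parent).  ``required_n_ratio``
solves the exact ratio at finite effect size.

``heterogeneity_power_loss`` quantifies by Monte Carlo how between-study
variance tau^2 erodes the power of a fixed-effects meta-analysis at fixed
total sample size, with the random-effects power reported for contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .meta import het_stats_arrays
from .simulate import case_allele_freq
from .sumstats import GENOME_WIDE_ALPHA

__all__ = [
    "PowerQuery",
    "analytic_power",
    "required_n_ratio",
    "heterogeneity_power_loss",
    "expected_se",
]


@dataclass(frozen=True)
class PowerQuery:
    """A single-variant power question."""

    beta: float
    maf: float
    n_cases: int
    n_controls: int
    alpha: float = GENOME_WIDE_ALPHA
    design: Literal["clinical", "proxy"] = "clinical"
    dilution: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")

    @property
    def effective_beta(self) -> float:
        return self.beta * (self.dilution if self.design == "proxy" else 1.0)


def expected_se(beta: float, maf: float, n_cases: float, n_controls: float) -> float:
    """SE of the log-OR from the expected allele-count table.

    sqrt(1/a + 1/b + 1/c + 1/d) with a = 2*n_cases*p1, b = 2*n_cases*(1-p1),
    c = 2*n_controls*maf, d = 2*n_controls*(1-maf), p1 the case allele
    frequency implied by the odds relation.
    """
    p1 = float(case_allele_freq(np.asarray(maf), np.asarray(beta)))
    a = 2 * n_cases * p1
    b = 2 * n_cases * (1 - p1)
    c = 2 * n_controls * maf
    d = 2 * n_controls * (1 - maf)
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def analytic_power(query: PowerQuery) -> float:
    """Wald-test power at the query's significance threshold.

    At beta = 0 this returns exactly alpha (the test's size).
    """
    beta_eff = query.effective_beta
    se = expected_se(beta_eff, query.maf, query.n_cases, query.n_controls)
    ncp = (beta_eff / se) ** 2
    crit = stats.chi2.isf(query.alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else query.alpha


def _power_at_multiplier(m: float, query: PowerQuery) -> float:
    q = PowerQuery(
        beta=query.beta,
        maf=query.maf,
        n_cases=int(round(query.n_cases * m)) or 1,
        n_controls=int(round(query.n_controls * m)) or 1,
        alpha=query.alpha,
        design=query.design,
        dilution=query.dilution,
    )
    return analytic_power(q)


def _solve_n(query: PowerQuery, target_power: float) -> float:
    """Continuous total-N achieving the target power (bisection on log N)."""
    beta_eff = query.effective_beta
    if beta_eff == 0:
        raise ValueError("cannot reach power above alpha with a null effect")
    crit = stats.chi2.isf(query.alpha, 1)

    def deficit(log_m):
        m = math.exp(log_m)
        se = expected_se(beta_eff, query.maf, query.n_cases * m, query.n_controls * m)
        ncp = (beta_eff / se) ** 2
        return stats.ncx2.sf(crit, 1, ncp) - target_power

    lo, hi = -20.0, 40.0
    if deficit(lo) > 0 or deficit(hi) < 0:
        raise RuntimeError(
            f"power target {target_power} not bracketed in N-multiplier "
            f"[e^{lo}, e^{hi}]"
        )
    log_m = optimize.brentq(deficit, lo, hi, xtol=1e-12)
    return math.exp(log_m) * (query.n_cases + query.n_controls)


def required_n_ratio(
    beta: float,
    maf: float = 0.2,
    alpha: float = GENOME_WIDE_ALPHA,
    target_power: float = 0.8,
    dilution: float = 0.5,
    case_fraction: float = 0.5,
) -> float:
    """Ratio of proxy to clinical total N achieving equal power.

    Tends to (1/dilution)^2 as beta -> 0; at large beta the curvature of
    the expected-count SE moves the ratio away from that limit.
    """
    if not alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    base_cases = max(1, int(1000 * case_fraction))
    base_controls = max(1, 1000 - base_cases)
    clin = PowerQuery(beta=beta, maf=maf, n_cases=base_cases, n_controls=base_controls,
                      alpha=alpha, design="clinical", dilution=dilution)
    prox = PowerQuery(beta=beta, maf=maf, n_cases=base_cases, n_controls=base_controls,
                      alpha=alpha, design="proxy", dilution=dilution)
    return _solve_n(prox, target_power) / _solve_n(clin, target_power)


def heterogeneity_power_loss(
    mu: float,
    tau2_grid: Sequence[float],
    k: int = 5,
    n_cases: int = 10_000,
    n_controls: int = 10_000,
    maf: float = 0.2,
    alpha: float = GENOME_WIDE_ALPHA,
    reps: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo power of fixed- and random-effects meta Z tests per tau^2.

    Each replicate draws k true effects mu + N(0, tau2), then observed
    effects x_i ~ N(true_i, s^2) with s from the expected allele-count
    table at mu; the per-cohort sample size is held fixed across the grid
    so the contrast isolates the heterogeneity effect.  Returns a frame
    with columns (tau2, power_fixed, power_random, reps).
    """
    if reps < 100:
        raise ValueError("need at least 100 Monte-Carlo replicates")
    if k < 2:
        raise ValueError("meta-analysis power needs k >= 2 cohorts")
    rng = np.random.default_rng(seed)
    s = expected_se(mu, maf, n_cases, n_controls)
    z_crit = stats.norm.isf(alpha / 2.0)
    rows = []
    for tau2 in tau2_grid:
        true = mu + math.sqrt(tau2) * rng.standard_normal((reps, k))
        x = true + s * rng.standard_normal((reps, k))
        s_mat = np.full_like(x, s)
        # fixed effects: equal weights here, but keep the general form
        w = 1.0 / s_mat**2
        est = (w * x).sum(axis=1) / w.sum(axis=1)
        se_fix = 1.0 / np.sqrt(w.sum(axis=1))
        z_fix = est / se_fix
        _, _, tau2_hat = het_stats_arrays(x, s_mat)
        wr = 1.0 / (s_mat**2 + tau2_hat[:, None])
        est_r = (wr * x).sum(axis=1) / wr.sum(axis=1)
        se_r = 1.0 / np.sqrt(wr.sum(axis=1))
        z_ran = est_r / se_r
        rows.append(
            dict(
                tau2=float(tau2),
                power_fixed=float(np.mean(np.abs(z_fix) > z_crit)),
                power_random=float(np.mean(np.abs(z_ran) > z_crit)),
                reps=reps,
            )
        )
    return pd.DataFrame(rows)
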