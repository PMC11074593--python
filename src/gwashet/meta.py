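"""Inverse-variance-weighted meta-analysis and heterogeneity statistics.

Implements the classical toolkit for pooling per-study log odds ratios
x_i with standard errors s_i and fixed-effects weights w_i = 1/s_i^2:

* fixed-effects IVW pooling, X = sum(w_i x_i) / sum(w_i), SE = 1/sqrt(sum w_i)
* Cochran's Q = sum w_i (x_i - X)^2, chi-square with k-1 df under homogeneity
* I^2 = 100 * max{0, (Q - (k-1)) / Q} percent (0 by convention at Q = 0)
* the DerSimonian-Laird moment estimator of the between-study variance,
  tau^2 = max{0, (Q - (k-1)) / (sum w_i - sum w_i^2 / sum w_i)}
* random-effects IVW with weights 1/(s_i^2 + tau^2)
* a sqrt(N)-weighted Z-score combination (the documented approximation to
  sample-size-weighted meta-analysis; no sample-overlap correction)

Scalar entry points operate on :class:`CohortEffect` collections; the
``*_arrays`` functions are vectorised over a (variants x studies) matrix
for simulation-scale work.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CohortEffect",
    "HetStats",
    "MetaResult",
    "fixed_effects_ivw",
    "cochran_q",
    "i_squared",
    "tau_squared_dl",
    "random_effects_ivw",
    "samplesize_weighted_z",
    "het_stats_arrays",
    "fixed_effects_arrays",
    "meta_analyze",
]


@dataclass(frozen=True)
class CohortEffect:
    """An (estimate, standard error) pair entering a meta-analysis."""

    cohort_id: str
    x: float
    s: float

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError(f"{self.cohort_id}: standard error must be > 0, got {self.s}")
        if not math.isfinite(self.x):
            raise ValueError(f"{self.cohort_id}: effect must be finite")

    @property
    def w(self) -> float:
        """Fixed-effects weight 1/s^2."""
        return 1.0 / (self.s * self.s)


@dataclass(frozen=True)
class HetStats:
    """Cochran's Q with its chi-square tail, I^2 (percent) and DL tau^2."""

    q: float
    df: int
    p_q: float
    i2: float
    tau2: float


@dataclass(frozen=True)
class MetaResult:
    model: str  # "fixed" | "random" | "samplesize_z"
    estimate: float
    se: float
    z: float
    p: float
    k: int
    het: HetStats | None


def _as_arrays(effects: Iterable[CohortEffect]) -> tuple[np.ndarray, np.ndarray]:
    effects = list(effects)
    if not effects:
        raise ValueError("empty study collection")
    x = np.array([e.x for e in effects], dtype=float)
    s = np.array([e.s for e in effects], dtype=float)
    return x, s


def _two_sided_p(z: float) -> float:
    return 2.0 * stats.norm.sf(abs(z))


def fixed_effects_ivw(effects: Iterable[CohortEffect]) -> MetaResult:
    """Fixed-effects inverse-variance-weighted pooled estimate.

    With a single study the study itself is returned and the heterogeneity
    block is ``None`` (heterogeneity is undefined at k = 1).
    """
    x, s = _as_arrays(effects)
    k = x.size
    w = 1.0 / s**2
    est = float(np.sum(w * x) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = est / se
    het = None
    if k >= 2:
        q, df, p_q = _cochran_q(x, w)
        het = HetStats(q=q, df=df, p_q=p_q, i2=i_squared(q, k), tau2=_tau2_dl(q, k, w))
    return MetaResult("fixed", est, se, z, _two_sided_p(z), k, het)


def _cochran_q(x: np.ndarray, w: np.ndarray) -> tuple[float, int, float]:
    xbar = np.sum(w * x) / np.sum(w)
    q = float(np.sum(w * (x - xbar) ** 2))
    df = x.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def cochran_q(effects: Iterable[CohortEffect]) -> tuple[float, int, float]:
    """Cochran's Q, its degrees of freedom k-1, and the upper chi-square tail."""
    x, s = _as_arrays(effects)
    if x.size < 2:
        raise ValueError("heterogeneity undefined for fewer than 2 studies")
    return _cochran_q(x, 1.0 / s**2)


def i_squared(q: float, k: int) -> float:
    """I^2 in percent: 100 * max{0, (Q - (k-1)) / Q}; 0 at Q = 0 by convention."""
    if q < 0:
        raise ValueError(f"Q must be non-negative, got {q}")
    if k < 2:
        raise ValueError("I^2 undefined for fewer than 2 studies")
    if q == 0.0:
        return 0.0
    return 100.0 * max(0.0, (q - (k - 1)) / q)


def _tau2_dl(q: float, k: int, w: np.ndarray) -> float:
    sw = float(np.sum(w))
    denom = sw - float(np.sum(w**2)) / sw
    if denom <= 0:
        warnings.warn("degenerate DL denominator (all weight in one study); tau^2 = 0",
                      stacklevel=3)
        return 0.0
    return max(0.0, (q - (k - 1)) / denom)


def tau_squared_dl(effects: Iterable[CohortEffect]) -> float:
    """DerSimonian-Laird moment estimator of the between-study variance."""
    x, s = _as_arrays(effects)
    if x.size < 2:
        raise ValueError("tau^2 undefined for fewer than 2 studies")
    w = 1.0 / s**2
    q, _, _ = _cochran_q(x, w)
    return _tau2_dl(q, x.size, w)


def random_effects_ivw(effects: Iterable[CohortEffect]) -> MetaResult:
    """Random-effects IVW with DL tau^2; reduces to fixed effects at tau^2 = 0."""
    effects = list(effects)
    x, s = _as_arrays(effects)
    if x.size < 2:
        raise ValueError("random-effects model needs at least 2 studies")
    w = 1.0 / s**2
    q, df, p_q = _cochran_q(x, w)
    tau2 = _tau2_dl(q, x.size, w)
    het = HetStats(q=q, df=df, p_q=p_q, i2=i_squared(q, x.size), tau2=tau2)
    wr = 1.0 / (s**2 + tau2)
    est = float(np.sum(wr * x) / np.sum(wr))
    se = float(1.0 / math.sqrt(np.sum(wr)))
    z = est / se
    return MetaResult("random", est, se, z, _two_sided_p(z), x.size, het)


def samplesize_weighted_z(
    z_scores: Sequence[float],
    weights: Sequence[float],
    directions: Sequence[int] | None = None,
) -> tuple[float, float]:
    """sqrt(N)-weighted Z-score meta-analysis.

    Z = sum(sqrt(N_i) z_i d_i) / sqrt(sum N_i).  This is the standard
    approximation to sample-size-weighted meta-analysis of Z statistics;
    it does not correct for sample overlap between the input studies.
    """
    z = np.asarray(z_scores, dtype=float)
    n = np.asarray(weights, dtype=float)
    d = np.ones_like(z) if directions is None else np.asarray(directions, dtype=float)
    if not (z.shape == n.shape == d.shape):
        raise ValueError("z_scores, weights and directions must have equal length")
    if np.any(n <= 0):
        raise ValueError("effective sample sizes must be positive")
    pooled = float(np.sum(np.sqrt(n) * z * d) / math.sqrt(np.sum(n)))
    return pooled, _two_sided_p(pooled)


# ---------------------------------------------------------------------------
# Vectorised forms over a (variants x studies) matrix


def fixed_effects_arrays(x: np.ndarray, s: np.ndarray):
    """Row-wise fixed-effects pooling; returns (estimate, se, z) arrays."""
    x = np.asarray(x, float)
    s = np.asarray(s, float)
    w = 1.0 / s**2
    sw = w.sum(axis=-1)
    est = (w * x).sum(axis=-1) / sw
    se = 1.0 / np.sqrt(sw)
    return est, se, est / se


def het_stats_arrays(x: np.ndarray, s: np.ndarray):
    """Row-wise Q, I^2 (percent) and DL tau^2 for a (variants x studies) matrix."""
    x = np.asarray(x, float)
    s = np.asarray(s, float)
    k = x.shape[-1]
    w = 1.0 / s**2
    sw = w.sum(axis=-1)
    xbar = (w * x).sum(axis=-1) / sw
    q = (w * (x - xbar[..., None]) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where(q > 0, 100.0 * np.maximum(0.0, (q - (k - 1)) / q), 0.0)
    denom = sw - (w**2).sum(axis=-1) / sw
    tau2 = np.where(denom > 0, np.maximum(0.0, (q - (k - 1)) / denom), 0.0)
    return q, i2, tau2


# ---------------------------------------------------------------------------
# Multi-table orchestration


def meta_analyze(
    tables,
    model: str = "fixed",
    *,
    ambiguous: str = "warn",
) -> "pd.DataFrame":
    """Align variants across harmonized tables and meta-analyse each.

    Variants are matched on snp_id; each record is oriented to the first
    table's allele pair before pooling.  Only variants present with a beta
    and SE in at least two tables are analysed.  Returns one row per
    variant: (snp_id, model, estimate, se, z, p, k, q, p_q, i2, tau2).
    """
    import pandas as pd

    from .sumstats import harmonize_alleles

    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("meta-analysis needs at least 2 input tables")
    index: dict[str, list] = {}
    reference: dict[str, tuple[str, str]] = {}
    for table in tables:
        for rec in table:
            if rec.beta is None or rec.se is None:
                continue
            if rec.snp_id not in reference:
                reference[rec.snp_id] = (rec.effect_allele, rec.other_allele)
            ea, oa = reference[rec.snp_id]
            rec = harmonize_alleles(rec, ea, oa, ambiguous=ambiguous)
            index.setdefault(rec.snp_id, []).append(
                CohortEffect(rec.dataset_id or table.dataset_id, rec.beta, rec.se)
            )
    rows = []
    for snp_id, effects in index.items():
        if len(effects) < 2:
            continue
        res = (fixed_effects_ivw if model == "fixed" else random_effects_ivw)(effects)
        het = res.het
        rows.append(
            dict(
                snp_id=snp_id, model=res.model, estimate=res.estimate, se=res.se,
                z=res.z, p=res.p, k=res.k,
                q=het.q, p_q=het.p_q, i2=het.i2, tau2=het.tau2,
            )
        )
    if not rows:
        raise ValueError("no variant occurs in at least two tables")
    return pd.DataFrame(rows)
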