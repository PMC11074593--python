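"""Synthetic multi-cohort GWAS / GWAS-by-proxy summary statistics.

The generator emulates the statistical structure that heterogeneity
analysis of case-control meta-analyses assumes:

* per-variant, per-cohort true log odds ratios drawn as mu + N(0, tau^2),
  i.e. a random-effects generative model with between-cohort variance tau^2;
* proxy-phenotype (family-history) cohorts whose true effects are
  attenuated by a multiplicative dilution factor (0.5 for a single
  affected first-degree relative, since a child shares half the proband's
  alleles);
* case-group misclassification: a fraction pi of true non-cases inside
  the case group, modelled either as first-order multiplicative
  attenuation of the log-OR by (1 - pi), or exactly, by mixing the
  control allele frequency into the case group;
* sampling noise from multinomial allele counts at the cohort's case and
  control sizes, with the observed log-OR = ln(ad/bc),
  SE = sqrt(1/a + 1/b + 1/c + 1/d) (Haldane +0.5 only on a zero cell) and
  a Wald-test P-value.

The effect-allele frequency is drawn once per variant and shared across
cohorts, so effect-size differences are the only source of Cochran's Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .sumstats import DatasetTable, SummaryRecord

__all__ = [
    "CohortSpec",
    "SimConfig",
    "Panel",
    "simulate_true_effects",
    "simulate_sumstats",
    "simulate_panel",
    "case_allele_freq",
]


@dataclass(frozen=True)
class CohortSpec:
    """One contributing cohort: clinical case-control or proxy design."""

    cohort_id: str
    design: Literal["clinical", "proxy"]
    n_cases: int
    n_controls: int
    misclass_pi: float = 0.0

    def __post_init__(self) -> None:
        if self.design not in ("clinical", "proxy"):
            raise ValueError(f"design must be clinical|proxy, got {self.design!r}")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 0.0 <= self.misclass_pi < 1.0:
            raise ValueError("misclass_pi must lie in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    ``mu`` is the mean true log-OR shared by all cohorts; ``tau2`` the
    between-cohort variance of true effects.  ``proxy_dilution`` scales
    proxy-cohort effects (default 0.5, one affected parent).  The
    effect-allele frequency of each variant is drawn uniformly from
    ``maf_range`` and shared across cohorts.  ``seed`` is mandatory:
    there is no hidden global RNG state.
    """

    mu: float
    tau2: float
    cohorts: tuple[CohortSpec, ...]
    n_variants: int
    seed: int
    proxy_dilution: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    misclass_mode: Literal["attenuate", "mixture"] = "attenuate"

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not 0.0 < self.proxy_dilution <= 1.0:
            raise ValueError("proxy_dilution must lie in (0, 1]")
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not self.cohorts:
            raise ValueError("at least one cohort required")


def case_allele_freq(maf: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Case-group allele frequency implied by control frequency and log-OR.

    Solves the odds relation: odds_case = exp(beta) * maf/(1-maf).
    """
    odds = np.exp(beta) * maf / (1.0 - maf)
    return odds / (1.0 + odds)


def simulate_true_effects(
    config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """True per-variant, per-cohort log-ORs, shape (n_variants, k).

    Effects are mu + N(0, tau2) independently per variant and cohort;
    proxy cohorts are then multiplied by the dilution factor and, in
    "attenuate" mode, cohorts with misclassification by (1 - pi).
    In "mixture" mode misclassification is applied later, at the allele
    frequencies, so the true effect matrix is left undiluted by pi.
    """
    rng = rng or np.random.default_rng(config.seed)
    k = len(config.cohorts)
    eff = config.mu + math.sqrt(config.tau2) * rng.standard_normal(
        (config.n_variants, k)
    )
    for j, spec in enumerate(config.cohorts):
        if spec.design == "proxy":
            eff[:, j] *= config.proxy_dilution
        if spec.misclass_pi > 0 and config.misclass_mode == "attenuate":
            eff[:, j] *= 1.0 - spec.misclass_pi
    return eff


def simulate_sumstats(
    true_effects: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[DatasetTable]:
    """Observed summary statistics per cohort from true effect matrix.

    For each variant and cohort an expected 2x2 allele-count table is
    formed from the shared control-allele frequency and the cohort's true
    log-OR, counts are drawn multinomially at 2*(n_cases + n_controls)
    alleles, and the observed log-OR, SE and Wald P are recorded.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n_var, k = true_effects.shape
    if k != len(config.cohorts):
        raise ValueError("true_effects column count != number of cohorts")
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=n_var)

    chroms = (np.arange(n_var) % 22 + 1).astype(str)
    positions = (np.arange(n_var) // 22 + 1) * 1_000_000
    tables = []
    for j, spec in enumerate(config.cohorts):
        beta_true = true_effects[:, j]
        p1 = case_allele_freq(maf, beta_true)
        if spec.misclass_pi > 0 and config.misclass_mode == "mixture":
            # exact mixture: pi of the case group are really controls
            p1 = (1.0 - spec.misclass_pi) * p1 + spec.misclass_pi * maf
        if np.any((p1 <= 0) | (p1 >= 1)):
            raise ValueError("case allele frequency outside (0, 1); "
                             "check maf_range and effect sizes")
        f_case = spec.n_cases / (spec.n_cases + spec.n_controls)
        pvals = np.column_stack(
            [f_case * p1, f_case * (1 - p1), (1 - f_case) * maf, (1 - f_case) * (1 - maf)]
        )
        n_alleles = 2 * (spec.n_cases + spec.n_controls)
        counts = rng.multinomial(n_alleles, pvals).astype(float)
        zero = (counts == 0).any(axis=1)
        counts[zero] += 0.5  # Haldane correction only where a cell is empty
        a, b, c, d = counts.T
        logor = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = logor / se
        pv = 2.0 * stats.norm.sf(np.abs(z))
        records = [
            SummaryRecord(
                snp_id=f"rs{900000000 + i}",
                chrom=chroms[i],
                pos=int(positions[i]),
                effect_allele="A",
                other_allele="G",
                p=float(pv[i]),
                beta=float(logor[i]),
                se=float(se[i]),
                n_cases=spec.n_cases,
                n_controls=spec.n_controls,
                dataset_id=spec.cohort_id,
            )
            for i in range(n_var)
        ]
        tables.append(
            DatasetTable(
                dataset_id=spec.cohort_id,
                records=records,
                provenance=f"simulated ({spec.design}, seed={config.seed})",
            )
        )
    return tables


@dataclass
class Panel:
    """A simulated multi-dataset panel with design grouping metadata."""

    tables: list[DatasetTable]
    groups: dict[str, list[str]]  # "gwas" / "gwax" / "combined" -> cohort ids
    config: SimConfig = field(repr=False, default=None)

    def subset(self, group: str) -> list[DatasetTable]:
        ids = set(self.groups[group])
        return [t for t in self.tables if t.dataset_id in ids]


def simulate_panel(config: SimConfig) -> Panel:
    """Full panel: per-cohort tables plus clinical/proxy/combined grouping.

    Requires at least one clinical and one proxy cohort so the clinical-only
    ("gwas"), proxy-only ("gwax") and combined ("gwas+gwax") meta-analyses
    of the same variants can all be formed downstream.
    """
    designs = {s.design for s in config.cohorts}
    if designs != {"clinical", "proxy"}:
        raise ValueError("panel needs at least one clinical and one proxy cohort")
    rng = np.random.default_rng(config.seed)
    eff = simulate_true_effects(config, rng)
    tables = simulate_sumstats(eff, config, rng)
    groups = {
        "gwas": [s.cohort_id for s in config.cohorts if s.design == "clinical"],
        "gwax": [s.cohort_id for s in config.cohorts if s.design == "proxy"],
        "combined": [s.cohort_id for s in config.cohorts],
    }
    return Panel(tables=tables, groups=groups, config=config)
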