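"""Per-dataset I-squared heterogeneity profiles and contingency comparisons.

Per-variant I^2 values (percent) are classified into four conventional
bins — [0-25] low, (25-50] moderate, (50-75] large, (75-100] extreme —
and datasets are compared against a reference by dichotomising each
profile at I^2 = 25% and forming a 2x2 table:

        I^2 > 25%   I^2 <= 25%
dataset     a           b
reference   c           d

with odds ratio (a*d)/(b*c), a 95% Woolf (log-normal) confidence interval
exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)), and a Yates
continuity-corrected chi-square statistic in which each cell contributes
(max{0, |O - E| - 0.5})^2 / E, referred to the upper tail of chi-square
with 1 degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BIN_LABELS",
    "HetProfile",
    "ContingencyComparison",
    "bin_i2",
    "profile_dataset",
    "evidence_summary",
    "compare_datasets",
    "profile_report",
]

#: Bin labels in increasing heterogeneity order.
BIN_LABELS = ("low", "moderate", "large", "extreme")

_Z95 = 1.96  # conventional two-sided 95% multiplier (as used in the printed tables)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (python's round() is half-even)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def bin_i2(i2: float) -> str:
    """Classify an I^2 percentage: [0,25] low, (25,50] moderate,
    (50,75] large, (75,100] extreme.  The first bin is closed at 25."""
    if not 0.0 <= i2 <= 100.0:
        raise ValueError(f"I^2={i2} outside [0, 100]")
    if i2 <= 25.0:
        return "low"
    if i2 <= 50.0:
        return "moderate"
    if i2 <= 75.0:
        return "large"
    return "extreme"


@dataclass(frozen=True)
class HetProfile:
    """Per-dataset counts of variants in the four I^2 bins."""

    dataset_id: str
    bin_counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.bin_counts) != 4 or any(c < 0 for c in self.bin_counts):
            raise ValueError("bin_counts must be four non-negative integers")

    @property
    def n_variants(self) -> int:
        return sum(self.bin_counts)

    def above(self, threshold: float) -> int:
        """Number of variants with I^2 strictly above a bin edge (25/50/75)."""
        edges = {0.0: 0, 25.0: 1, 50.0: 2, 75.0: 3}
        if float(threshold) not in edges:
            raise ValueError(f"threshold {threshold} is not a bin edge")
        return sum(self.bin_counts[edges[float(threshold)] :])

    def dichotomize(self, threshold: float = 25.0) -> tuple[int, int]:
        """(count above, count at-or-below) the threshold."""
        above = self.above(threshold)
        return above, self.n_variants - above


def profile_dataset(i2_values: Iterable[float], dataset_id: str) -> HetProfile:
    """Count per-variant I^2 values (percent) into the four bins."""
    counts = [0, 0, 0, 0]
    for v in i2_values:
        counts[BIN_LABELS.index(bin_i2(v))] += 1
    return HetProfile(dataset_id=dataset_id, bin_counts=tuple(counts))


def evidence_summary(
    values: "HetProfile | Iterable[float]",
    thresholds: Sequence[float] = (25.0, 50.0, 75.0),
) -> dict[float, tuple[int, int]]:
    """Count and integer percentage (half-up) of variants with I^2 strictly
    above each threshold.  Accepts raw I^2 values or an already-binned
    profile (thresholds must then be bin edges)."""
    if isinstance(values, HetProfile):
        n = values.n_variants
        counts = {float(t): values.above(t) for t in thresholds}
    else:
        vals = [float(v) for v in values]
        for v in vals:
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"I^2={v} outside [0, 100]")
        n = len(vals)
        counts = {float(t): sum(v > t for v in vals) for t in thresholds}
    return {
        t: (c, int(round_half_up(100.0 * c / n)) if n else 0)
        for t, c in counts.items()
    }


@dataclass(frozen=True)
class ContingencyComparison:
    """2x2 comparison of two heterogeneity profiles dichotomised at I^2=25%."""

    dataset_id: str
    reference_id: str
    table: tuple[tuple[int, int], tuple[int, int]]  # [[a, b], [c, d]]
    or_: float | None
    ci_low: float | None
    ci_high: float | None
    chi2: float
    p: float

    @property
    def defined(self) -> bool:
        return self.or_ is not None


def compare_datasets(
    profile: HetProfile,
    reference: HetProfile,
    *,
    threshold: float = 25.0,
    haldane: bool = False,
) -> ContingencyComparison:
    """Compare a dataset against a reference by the odds of I^2 > 25%.

    OR = (a*d)/(b*c) with a 95% Woolf CI; the P-value comes from the
    Yates-corrected chi-square (always computed from the raw cells).  With
    a zero cell the OR/CI are reported as undefined unless ``haldane=True``
    adds 0.5 to every cell for the OR/CI only.
    """
    if profile.n_variants == 0 or reference.n_variants == 0:
        raise ValueError("both profiles must be non-empty")
    a, b = profile.dichotomize(threshold)
    c, d = reference.dichotomize(threshold)

    or_ = ci_low = ci_high = None
    aa, bb, cc, dd = (a, b, c, d)
    if 0 in (a, b, c, d) and haldane:
        aa, bb, cc, dd = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    if 0 not in (aa, bb, cc, dd):
        or_ = (aa * dd) / (bb * cc)
        half = _Z95 * math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        ci_low = or_ * math.exp(-half)
        ci_high = or_ * math.exp(half)

    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.maximum(0.0, np.abs(obs - expected) - 0.5) ** 2 / expected
    chi2 = float(np.nansum(contrib))
    p = min(1.0, float(stats.chi2.sf(chi2, 1)))
    return ContingencyComparison(
        dataset_id=profile.dataset_id,
        reference_id=reference.dataset_id,
        table=((a, b), (c, d)),
        or_=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        chi2=chi2,
        p=p,
    )


def profile_report(
    profiles: Sequence[HetProfile],
    reference_id: str,
    *,
    threshold: float = 25.0,
) -> pd.DataFrame:
    """Tabular heterogeneity report: one row per dataset with its bin counts
    and, for non-reference rows, the 2x2 comparison against the reference.

    Display columns round the OR and CI to 2 decimals (half-up) and format
    P to 3 significant figures; full-precision columns are kept alongside.
    """
    ref = next((p for p in profiles if p.dataset_id == reference_id), None)
    if ref is None:
        raise ValueError(f"reference {reference_id!r} not among profiles")
    rows = []
    for prof in profiles:
        row: dict = {
            "dataset": prof.dataset_id,
            "n_variants": prof.n_variants,
            **{f"i2_{lab}": c for lab, c in zip(BIN_LABELS, prof.bin_counts)},
        }
        if prof.dataset_id != reference_id:
            cmp_ = compare_datasets(prof, ref, threshold=threshold)
            row.update(
                or_=cmp_.or_, ci_low=cmp_.ci_low, ci_high=cmp_.ci_high,
                chi2=cmp_.chi2, p=cmp_.p,
                or_display="NA" if cmp_.or_ is None else _fmt2(cmp_.or_),
                ci_display="NA" if cmp_.or_ is None
                else f"{_fmt2(cmp_.ci_low)}-{_fmt2(cmp_.ci_high)}",
                p_display="1" if cmp_.p == 1.0 else f"{cmp_.p:.2E}",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _fmt2(x: float) -> str:
    return f"{round_half_up(x, 2):.2f}"
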