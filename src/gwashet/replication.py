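"""Locus-level replication census across association datasets.

Builds a locus x dataset matrix of genome-wide significant hits from
harmonized summary records, then counts how many loci are significant in
a single dataset, in at least two, or in every dataset, and attributes
each locus's best (smallest-P) signal to the dataset that produced it.

Locus identity comes from record labels where provided (the packaged
82-locus fixture carries the printed locus grouping); for generic inputs,
:func:`assign_loci` merges same-chromosome records by single-linkage
within a base-pair window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sumstats import GENOME_WIDE_ALPHA, DatasetTable, SummaryRecord

__all__ = [
    "SignificanceMatrix",
    "ReplicationCensus",
    "assign_loci",
    "build_matrix",
    "replication_counts",
    "best_signal_attribution",
]


def _pct(count: int, total: int) -> int:
    """Integer percentage, round half-up."""
    if total == 0:
        return 0
    frac = Decimal(100 * count) / Decimal(total)
    return int(frac.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def assign_loci(
    tables: Iterable[DatasetTable],
    window: int = 500_000,
) -> list[DatasetTable]:
    """Label records with loci by single-linkage clustering of positions.

    Records on the same chromosome are merged into one locus whenever a
    chain of records links them with consecutive gaps <= ``window``
    (default 500 kb).  Records that already carry a locus label keep it.
    Labels are ``"<chrom>:<megabase of leftmost member>Mb"``.
    """
    tables = [t for t in tables]
    labelled: list[tuple[SummaryRecord, DatasetTable]] = []
    unlabelled: list[tuple[SummaryRecord, DatasetTable]] = []
    for t in tables:
        for rec in t:
            (labelled if rec.locus_label else unlabelled).append((rec, t))

    by_chrom: dict[str, list[tuple[SummaryRecord, DatasetTable]]] = {}
    for rec, t in unlabelled:
        by_chrom.setdefault(rec.chrom, []).append((rec, t))

    assignment: dict[int, str] = {}  # id(record) -> label
    for chrom, members in by_chrom.items():
        members.sort(key=lambda pair: pair[0].pos)
        cluster_start = None
        prev_pos = None
        cluster: list[SummaryRecord] = []

        def flush():
            if cluster:
                label = f"{chrom}:{cluster[0].pos / 1e6:.1f}Mb"
                for r in cluster:
                    assignment[id(r)] = label

        for rec, _ in members:
            if prev_pos is not None and rec.pos - prev_pos > window:
                flush()
                cluster = []
            cluster.append(rec)
            prev_pos = rec.pos
        flush()

    import dataclasses

    out = []
    for t in tables:
        recs = [
            r if r.locus_label else dataclasses.replace(r, locus_label=assignment[id(r)])
            for r in t
        ]
        out.append(DatasetTable(dataset_id=t.dataset_id, records=recs,
                                provenance=t.provenance))
    return out


@dataclass
class SignificanceMatrix:
    """Locus x dataset matrix of genome-wide-significant hits.

    ``hit.loc[locus, dataset]`` is True iff at least one qualifying record
    exists; ``best_p`` holds the smallest P among them (NaN elsewhere) and
    ``best_record`` the corresponding record.
    """

    loci: list[str]
    datasets: list[str]
    hit: pd.DataFrame
    best_p: pd.DataFrame
    best_record: dict[tuple[str, str], SummaryRecord] = field(repr=False, default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.loci), len(self.datasets)

    def to_wide_table(self) -> pd.DataFrame:
        """Loci as rows, datasets as columns, cell = best P (NaN if no hit)."""
        return self.best_p.copy()


def build_matrix(
    tables: Iterable[DatasetTable],
    alpha: float | None = GENOME_WIDE_ALPHA,
) -> SignificanceMatrix:
    """Assemble the significance matrix over the union of loci and datasets.

    A (locus, dataset) cell is a hit iff some record has p < ``alpha``
    (strict).  ``alpha=None`` counts every record — appropriate when the
    input is an already-curated table of significant findings, where the
    printed membership, not a re-applied threshold, defines the hits.
    Loci with no hit in any dataset are dropped.
    """
    records: list[SummaryRecord] = []
    datasets: list[str] = []
    for t in tables:
        if t.dataset_id not in datasets:
            datasets.append(t.dataset_id)
        for rec in t:
            if not rec.locus_label:
                raise ValueError(
                    f"record {rec.snp_id} lacks a locus label; run assign_loci first"
                )
            records.append(rec)

    def sort_key(label: str):
        head = label.split(":", 1)[0]
        return (0, int(head), label) if head.isdigit() else (1, 0, label)

    best: dict[tuple[str, str], SummaryRecord] = {}
    for rec in records:
        if alpha is not None and not rec.p < alpha:
            continue
        key = (rec.locus_label, rec.dataset_id)
        if key not in best or rec.p < best[key].p:
            best[key] = rec

    loci = sorted({locus for locus, _ in best}, key=sort_key)
    hit = pd.DataFrame(False, index=loci, columns=datasets)
    best_p = pd.DataFrame(math.nan, index=loci, columns=datasets)
    for (locus, ds), rec in best.items():
        hit.loc[locus, ds] = True
        best_p.loc[locus, ds] = rec.p
    return SignificanceMatrix(
        loci=loci, datasets=datasets, hit=hit, best_p=best_p, best_record=best
    )


@dataclass(frozen=True)
class ReplicationCensus:
    total: int
    n_single: int
    pct_single: int
    n_at_least_2: int
    pct_at_least_2: int
    n_all: int
    pct_all: int
    per_locus_counts: Mapping[str, int]


def replication_counts(matrix: SignificanceMatrix) -> ReplicationCensus:
    """Census of locus replication: single-dataset, >=2 datasets, all datasets.

    Percentages are integer, rounded half-up.
    """
    if not matrix.loci:
        raise ValueError("empty significance matrix")
    counts = matrix.hit.sum(axis=1).astype(int)
    total = len(matrix.loci)
    n_single = int((counts == 1).sum())
    n_ge2 = int((counts >= 2).sum())
    n_all = int((counts == len(matrix.datasets)).sum())
    return ReplicationCensus(
        total=total,
        n_single=n_single,
        pct_single=_pct(n_single, total),
        n_at_least_2=n_ge2,
        pct_at_least_2=_pct(n_ge2, total),
        n_all=n_all,
        pct_all=_pct(n_all, total),
        per_locus_counts=dict(counts),
    )


def best_signal_attribution(
    matrix: SignificanceMatrix,
) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Per locus, the dataset(s) achieving the smallest best P.

    Ties are reported in full, not broken.  The per-dataset tally credits
    each winning dataset once per locus it wins (shared for ties).
    Returns (winners per locus, loci-won tally per dataset).
    """
    if not matrix.loci:
        raise ValueError("empty significance matrix")
    winners: dict[str, list[str]] = {}
    tally: dict[str, int] = {ds: 0 for ds in matrix.datasets}
    for locus in matrix.loci:
        row = matrix.best_p.loc[locus].dropna()
        best = row.min()
        tied = sorted(row.index[row == best])
        winners[locus] = tied
        for ds in tied:
            tally[ds] += 1
    return winners, tally
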