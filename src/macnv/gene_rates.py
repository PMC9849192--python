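"""Gene-level CNV classification and mutation-rate estimation.

A gene fully contained in a CNV is a *complete* gene deletion/duplication;
a gene overlapping a CNV by >= 1 bp without being contained is *partial*.
Per-line rates use the standard mutation-accumulation estimator

    mu = m / (n * T)

with m the number of observed gene mutations in the line, n the number of
protein-coding genes in the genome, and T the generations elapsed for that
line. Per-line rates are averaged with equal line weights (zero-mutation
lines included); a pooled estimator sum(m) / (n * sum(T)) is also reported
because the two line sets ran for different numbers of generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .consensus_filter import ConsensusCNV
from .genome_model import GeneRecord

__all__ = [
    "GeneCNVEvent",
    "RateRecord",
    "RateSummary",
    "LengthSummary",
    "CATEGORIES",
    "classify_gene_overlaps",
    "per_line_rate",
    "summarize_rates",
    "genome_event_rate",
    "summarize_lengths",
    "pearson_correlation",
]

CATEGORIES = (
    "gene_del_complete",
    "gene_del_partial",
    "gene_dup_complete",
    "gene_dup_partial",
    "gene_del_all",
    "gene_dup_all",
    "gene_cnv_all",
)


@dataclass(frozen=True)
class GeneCNVEvent:
    """One gene x CNV overlap, classified complete or partial."""

    gene_id: str
    line_id: str
    svtype: str
    overlap_class: str  # "complete" | "partial"

    def __post_init__(self) -> None:
        if self.overlap_class not in ("complete", "partial"):
            raise ValueError(f"bad overlap_class {self.overlap_class!r}")


@dataclass(frozen=True)
class RateRecord:
    """Per-line observed count and rate for one mutation category."""

    line_id: str
    m: int
    n: int
    T: float
    mu: float


@dataclass
class RateSummary:
    """Per-category rate table: per-line records plus their equal-weight mean."""

    category: str
    records: list[RateRecord]
    mean_mu: float
    pooled_mu: float


@dataclass(frozen=True)
class LengthSummary:
    mean_len_del: float  # NaN when no deletion
    mean_len_dup: float  # NaN when no duplication
    n_del: int
    n_dup: int


def classify_gene_overlaps(
    cnvs: Iterable[ConsensusCNV],
    genes: Sequence[GeneRecord],
    protein_coding_only: bool = True,
) -> list[GeneCNVEvent]:
    """One event per (gene, CNV) pair sharing >= 1 bp.

    A gene hit by two CNVs in the same line yields two events (one per
    pair); callers wanting per-gene deduplication can collapse on
    (gene_id, line_id, svtype) afterwards.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if protein_coding_only and g.biotype != "protein_coding":
            continue
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g
        )
    events: list[GeneCNVEvent] = []
    for cnv in cnvs:
        tree = trees.get(cnv.interval.chrom)
        if tree is None:
            continue
        hits = sorted(
            tree.overlap(cnv.interval.start, cnv.interval.end),
            key=lambda h: (h.begin, h.end, h.data.gene_id),
        )
        for hit in hits:
            gene: GeneRecord = hit.data
            cls = "complete" if cnv.interval.contains(gene.interval) else "partial"
            events.append(
                GeneCNVEvent(
                    gene_id=gene.gene_id,
                    line_id=cnv.line_id,
                    svtype=cnv.svtype,
                    overlap_class=cls,
                )
            )
    return events


def per_line_rate(m: int, n: int, T: float) -> float:
    """mu = m / (n T), the per-gene per-generation mutation rate."""
    if n <= 0 or T <= 0:
        raise ValueError(f"n and T must be positive (got n={n}, T={T})")
    if m < 0:
        raise ValueError(f"m must be nonnegative (got {m})")
    return m / (n * T)


def _category_matches(category: str, ev: GeneCNVEvent) -> bool:
    if category == "gene_cnv_all":
        return True
    sv = "DEL" if "_del" in category else "DUP"
    if ev.svtype != sv:
        return False
    if category.endswith("_all"):
        return True
    return ev.overlap_class == category.rsplit("_", 1)[1]


def summarize_rates(
    events: Iterable[GeneCNVEvent],
    line_roster: Sequence[tuple[str, float]],
    n: int,
    categories: Sequence[str] = CATEGORIES,
) -> list[RateSummary]:
    """Per-category per-line rates averaged over the full line roster.

    The roster must list every sequenced line (including lines with zero
    mutations) with its generation count T; an event attributed to a line
    absent from the roster is an error.
    """
    events = list(events)
    roster_ids = {lid for lid, _ in line_roster}
    if len(roster_ids) != len(line_roster):
        raise ValueError("duplicate line_id in roster")
    orphan = sorted({e.line_id for e in events} - roster_ids)
    if orphan:
        raise ValueError(f"events attributed to lines absent from roster: {orphan}")

    out: list[RateSummary] = []
    for cat in categories:
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
        records = []
        for lid, T in line_roster:
            m = sum(
                1 for e in events if e.line_id == lid and _category_matches(cat, e)
            )
            records.append(RateRecord(lid, m, n, T, per_line_rate(m, n, T)))
        mean_mu = float(np.mean([r.mu for r in records]))
        pooled_mu = sum(r.m for r in records) / (n * sum(r.T for r in records))
        out.append(RateSummary(cat, records, mean_mu, pooled_mu))
    return out


def genome_event_rate(
    cnvs: Iterable[ConsensusCNV],
    line_roster: Sequence[tuple[str, float]],
) -> dict[str, RateSummary]:
    """Per-genome per-generation event rates: per line (#events)/T, averaged."""
    cnvs = list(cnvs)
    roster_ids = {lid for lid, _ in line_roster}
    orphan = sorted({c.line_id for c in cnvs} - roster_ids)
    if orphan:
        raise ValueError(f"events attributed to lines absent from roster: {orphan}")
    out: dict[str, RateSummary] = {}
    for svtype, label in (("DEL", "genome_del"), ("DUP", "genome_dup")):
        records = []
        for lid, T in line_roster:
            m = sum(1 for c in cnvs if c.line_id == lid and c.svtype == svtype)
            records.append(RateRecord(lid, m, 1, T, m / T))
        mean_mu = float(np.mean([r.mu for r in records]))
        pooled_mu = sum(r.m for r in records) / sum(r.T for r in records)
        out[label] = RateSummary(label, records, mean_mu, pooled_mu)
    return out


def summarize_lengths(cnvs: Iterable[ConsensusCNV]) -> LengthSummary:
    """Mean event length by type (NaN for an absent type) and counts."""
    dels = [c.interval.length for c in cnvs if c.svtype == "DEL"]
    dups = [c.interval.length for c in cnvs if c.svtype == "DUP"]
    return LengthSummary(
        mean_len_del=float(np.mean(dels)) if dels else math.nan,
        mean_len_dup=float(np.mean(dups)) if dups else math.nan,
        n_del=len(dels),
        n_dup=len(dups),
    )


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
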