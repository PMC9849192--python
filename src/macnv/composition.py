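"""Nucleotide-composition comparisons between CNVs, genes and background.

Compares %AT distributions of CNV intervals, CNV breakpoint windows
(+/- 50 bp or +/- 2 kb around each breakpoint), genes, and the genomic
background, with Mann-Whitney rank-sum tests. The background is computed
two ways because the "background unit" is genuinely a modelling choice:
per chromosome, and as non-overlapping windows whose width matches the
median CNV length (the default for tests, as it matches the CNV sample
unit in scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .consensus_filter import ConsensusCNV
from .genome_model import GeneRecord, GenomeIndex, GenomicInterval, at_fraction

__all__ = [
    "CompositionSet",
    "breakpoint_windows",
    "build_composition_sets",
    "rank_sum_test",
]

LABELS = (
    "cnv",
    "breakpoint_50",
    "breakpoint_2000",
    "gene",
    "background_chromosome",
    "background_window",
)


@dataclass
class CompositionSet:
    """A labelled sample of %AT values with their source intervals."""

    label: str
    values: np.ndarray
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown composition label {self.label!r}")


def breakpoint_windows(
    cnv: ConsensusCNV | GenomicInterval,
    flank: int,
    genome: GenomeIndex,
) -> list[GenomicInterval]:
    """Windows of +/- flank bp around each breakpoint, clipped to the chromosome.

    Windows that are empty after clipping are dropped.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    iv = cnv if isinstance(cnv, GenomicInterval) else cnv.interval
    chrom_len = genome.chrom_length(iv.chrom)
    out = []
    for bp in (iv.start, iv.end):
        lo = max(0, bp - flank)
        hi = min(chrom_len, bp + flank)
        if hi > lo:
            out.append(GenomicInterval(iv.chrom, lo, hi))
    return out


def _at_values(
    genome: GenomeIndex, intervals: Iterable[GenomicInterval]
) -> tuple[np.ndarray, list[GenomicInterval]]:
    intervals = list(intervals)
    values = np.array([at_fraction(genome, iv) for iv in intervals], dtype=float)
    keep = ~np.isnan(values)
    return values[keep], [iv for iv, k in zip(intervals, keep) if k]


def background_windows(genome: GenomeIndex, width: int) -> list[GenomicInterval]:
    """Non-overlapping windows of the given width tiling every chromosome.

    The terminal partial window of each chromosome is dropped, so coverage
    is total_length - sum(len_c mod width).
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    out = []
    for chrom, length in genome.chromosomes:
        for start in range(0, length - width + 1, width):
            out.append(GenomicInterval(chrom, start, start + width))
    return out


def build_composition_sets(
    cnvs: Sequence[ConsensusCNV],
    genes: Sequence[GeneRecord],
    genome: GenomeIndex,
    flanks: tuple[int, ...] = (50, 2000),
    background_width: int | None = None,
) -> dict[str, CompositionSet]:
    """%AT sample sets for CNVs, breakpoint windows, genes and background.

    ``background_width`` defaults to the median CNV length (min 100 bp).
    """
    sets: dict[str, CompositionSet] = {}

    vals, ivs = _at_values(genome, (c.interval for c in cnvs))
    sets["cnv"] = CompositionSet("cnv", vals, ivs)

    for flank in flanks:
        label = f"breakpoint_{flank}"
        if label not in LABELS:
            raise ValueError(f"unsupported flank {flank}")
        wins: list[GenomicInterval] = []
        for c in cnvs:
            wins.extend(breakpoint_windows(c, flank, genome))
        vals, ivs = _at_values(genome, wins)
        sets[label] = CompositionSet(label, vals, ivs)

    vals, ivs = _at_values(genome, (g.interval for g in genes))
    sets["gene"] = CompositionSet("gene", vals, ivs)

    chrom_ivs = [GenomicInterval(c, 0, n) for c, n in genome.chromosomes]
    vals, ivs = _at_values(genome, chrom_ivs)
    sets["background_chromosome"] = CompositionSet("background_chromosome", vals, ivs)

    if background_width is None:
        lengths = [c.interval.length for c in cnvs]
        background_width = max(100, int(np.median(lengths))) if lengths else 1000
    vals, ivs = _at_values(genome, background_windows(genome, background_width))
    sets["background_window"] = CompositionSet("background_window", vals, ivs)
    return sets


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for sample a, p).

    Uses the exact null distribution when there are no ties and
    |a| * |b| <= 10,000; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and a.size * b.size <= 10_000) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)
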