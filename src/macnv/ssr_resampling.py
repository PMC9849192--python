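"""Simple-sequence-repeat detection and permutation tests of interval overlap.

``detect_ssrs`` scans for maximal perfect tandem repeats of 1-6 bp motifs
above per-motif-length minimum copy numbers (MISA-style defaults
10/6/5/5/5/5 for mono- through hexanucleotides). ``permutation_test``
builds a null distribution for an overlap statistic by re-placing the
observed intervals (same length multiset) uniformly at random across the
genome, the standard randomization used to ask whether CNVs hit genes or
SSRs more or less often than chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .composition import breakpoint_windows
from .genome_model import GenomeIndex, GenomicInterval

__all__ = [
    "SSRLocus",
    "PermutationResult",
    "DEFAULT_MIN_COPIES",
    "detect_ssrs",
    "count_interval_overlaps",
    "random_placement",
    "permutation_test",
    "breakpoint_ssr_overlap",
    "write_ssr_bed",
]

#: Minimum copy numbers for motif lengths 1..6.
DEFAULT_MIN_COPIES = (10, 6, 5, 5, 5, 5)

OVERLAP_MODES = ("any_feature", "features_contained", "features_touched")


@dataclass(frozen=True)
class SSRLocus:
    """A maximal perfect tandem repeat: motif (canonical rotation) x copies."""

    interval: GenomicInterval
    motif: str
    copies: float


@dataclass
class PermutationResult:
    """Observed statistic vs a randomization null.

    percentile uses midranks for ties; empirical p-values use the
    (1 + k) / (N + 1) estimator on each side so p is never zero.
    """

    statistic_name: str
    observed: float
    null_values: np.ndarray
    percentile: float
    p_lower: float
    p_upper: float
    seed: int
    N: int


def _is_primitive(motif: str) -> bool:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def _canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def detect_ssrs(
    genome: GenomeIndex,
    min_copies: Sequence[float] = DEFAULT_MIN_COPIES,
) -> list[SSRLocus]:
    """Greedy left-to-right scan for maximal perfect tandem repeats.

    Only primitive motifs are reported (an AC-run is never also reported
    as an ACAC-run); overlapping runs of *different* motifs are all
    reported. Trailing partial copies count fractionally, so the interval
    length is floor(copies * motif length). Output order is
    (chromosome, start, motif length).
    """
    loci: list[SSRLocus] = []
    for chrom, length in genome.chromosomes:
        seq = genome.fetch(chrom, 0, length)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        clean = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        n = len(seq)
        for k, min_c in enumerate(min_copies, start=1):
            if n < k + 1:
                continue
            # match[i] == True iff seq[i + k] continues a period-k repeat at i;
            # a maximal True-run [a, b) is a maximal tandem run [a, b + k)
            match = (arr[k:] == arr[:-k]) & clean[k:] & clean[:-k]
            padded = np.concatenate(([False], match, [False]))
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            starts, stops = edges[::2], edges[1::2]
            for a, b in zip(starts, stops):
                run_len = (b - a) + k
                copies = run_len / k
                if copies < min_c:
                    continue
                motif = seq[a : a + k]
                if not _is_primitive(motif):
                    continue
                loci.append(
                    SSRLocus(
                        interval=GenomicInterval(chrom, int(a), int(a) + run_len),
                        motif=_canonical_rotation(motif),
                        copies=copies,
                    )
                )
    loci.sort(key=lambda s: (s.interval.chrom, s.interval.start, len(s.motif)))
    return loci


def write_ssr_bed(loci: Iterable[SSRLocus], path) -> None:
    with open(path, "w") as fh:
        for s in loci:
            iv = s.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.motif}\t{s.copies:g}\n")


def count_interval_overlaps(
    queries: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    mode: str = "any_feature",
) -> int:
    """Overlap counting in one of three modes.

    any_feature: queries with >= 1 bp overlap to >= 1 feature.
    features_contained: features fully inside some single query.
    features_touched: features with >= 1 bp overlap to any query.
    """
    if mode not in OVERLAP_MODES:
        raise ValueError(f"unknown mode {mode!r} (choose from {OVERLAP_MODES})")
    return _count_overlaps(queries, _feature_trees(features), mode)


def _feature_trees(features: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    return trees


def _count_overlaps(
    queries: Sequence[GenomicInterval],
    trees: dict[str, IntervalTree],
    mode: str,
) -> int:
    if mode == "any_feature":
        return sum(
            1
            for q in queries
            if q.chrom in trees and trees[q.chrom].overlaps(q.start, q.end)
        )
    hit: set[GenomicInterval] = set()
    for q in queries:
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for h in tree.overlap(q.start, q.end):
            f: GenomicInterval = h.data
            if mode == "features_touched" or q.contains(f):
                hit.add(f)
    return len(hit)


def random_placement(
    lengths: Sequence[int],
    genome: GenomeIndex,
    rng: np.random.Generator | int,
) -> list[GenomicInterval]:
    """Place each length independently, uniformly over all valid genome positions.

    The chromosome is sampled with probability proportional to its number
    of valid start positions (chrom length - interval length + 1), then the
    start uniformly among them. Placed intervals may overlap one another.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    names = genome.names
    chrom_lens = np.array([n for _, n in genome.chromosomes], dtype=np.int64)
    out = []
    for length in lengths:
        valid = chrom_lens - length + 1
        valid = np.maximum(valid, 0)
        total = valid.sum()
        if total <= 0:
            raise ValueError(f"interval length {length} exceeds every chromosome")
        ci = rng.choice(len(names), p=valid / total)
        start = int(rng.integers(0, valid[ci]))
        out.append(GenomicInterval(names[ci], start, start + length))
    return out


def permutation_test(
    observed_intervals: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    mode: str = "any_feature",
    N: int = 1000,
    seed: int = 0,
    genome: GenomeIndex | None = None,
    statistic_name: str | None = None,
) -> PermutationResult:
    """Randomization test of an overlap statistic against random placement.

    The observed intervals' length multiset is re-placed N times; the
    statistic is computed identically on the observed set and each draw.
    """
    if genome is None:
        raise ValueError("permutation_test requires a genome for placement")
    if N < 100:
        raise ValueError("N must be >= 100 for a meaningful null")
    if mode not in OVERLAP_MODES:
        raise ValueError(f"unknown mode {mode!r} (choose from {OVERLAP_MODES})")
    trees = _feature_trees(features)
    observed = _count_overlaps(observed_intervals, trees, mode)
    lengths = [iv.length for iv in observed_intervals]
    rng = np.random.default_rng(seed)
    null = np.empty(N, dtype=float)
    for i in range(N):
        placed = random_placement(lengths, genome, rng)
        null[i] = _count_overlaps(placed, trees, mode)
    below = int(np.sum(null < observed))
    equal = int(np.sum(null == observed))
    at_most = int(np.sum(null <= observed))
    at_least = int(np.sum(null >= observed))
    return PermutationResult(
        statistic_name=statistic_name or f"{mode}_overlap",
        observed=float(observed),
        null_values=null,
        percentile=(below + 0.5 * equal) / N,
        p_lower=(1 + at_most) / (N + 1),
        p_upper=(1 + at_least) / (N + 1),
        seed=seed,
        N=N,
    )


def breakpoint_ssr_overlap(
    cnvs,
    ssrs: Sequence[SSRLocus],
    genome: GenomeIndex,
    flank: int = 50,
) -> int:
    """Number of CNV breakpoint windows (+/- flank) overlapping >= 1 SSR."""
    windows: list[GenomicInterval] = []
    for c in cnvs:
        windows.extend(breakpoint_windows(c, flank, genome))
    return count_interval_overlaps(
        windows, [s.interval for s in ssrs], mode="any_feature"
    )
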