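"""Multi-caller, multi-line consensus filtering of CNV calls.

The filtering pipeline mirrors post-hoc curation of structural-variant
calls from a haploid mutation-accumulation (MA) experiment:

1. **Intersection** — calls from all programs and all lines are clustered
   by >= 1 bp overlap (transitive closure), separately for deletions and
   duplications, the same semantics as ``bedtools multiinter``.
2. **Single-line uniqueness** — clusters spanning more than one MA line are
   discarded as recurrent artifacts (regions prone to mismapping produce
   the same spurious call in many lines, whereas a spontaneous mutation
   arises in exactly one line).
3. **Haploid depth thresholds** — in a haploid genome a real deletion has
   ~0x and a real duplication ~2x relative depth, so read-depth calls are
   kept only below 0.5x (deletions) or above 1.5x (duplications), strict
   inequalities.
4. **Cohort verification** — an automated, quantitative stand-in for visual
   inspection of coverage tracks: the focal line must satisfy the depth
   threshold over the candidate interval, every other line must be
   copy-neutral there, and the focal line's flanking regions (one CNV
   length on each side) must also be copy-neutral.
5. **Coordinate selection** — when several programs call the same event,
   the coordinates whose depth signature best matches expectation
   (0x inside a deletion, 2x inside a duplication, 1x in the flanks) win.

A ``prefilter`` mode reproduces the permissive alternative used for
robustness checks: intersection and uniqueness only, plus a length cap,
with no depth verification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .cnv_io import CNVCall, DepthProfile
from .genome_model import GenomicInterval

__all__ = [
    "FilterParams",
    "CallCluster",
    "VerificationResult",
    "ConsensusCNV",
    "multi_intersect",
    "uniqueness_filter",
    "depth_threshold_filter",
    "verify_against_cohort",
    "select_coordinates",
    "length_filter",
    "run_filter_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Tunable thresholds of the filtering pipeline.

    Defaults: depth evidence restricted to MAPQ >= 20 alignments, deletion
    kept below 0.5x and duplication above 1.5x relative depth, copy-neutral
    band 1 +/- 0.3, 20 kb length cap in prefilter mode, and caller priority
    cnvnator > manta > delly for exact coordinate ties.
    """

    min_mapq: int = 20
    del_ratio_max: float = 0.5
    dup_ratio_min: float = 1.5
    neutral_band_delta: float = 0.3
    max_len_prefilter: int = 20_000
    caller_priority: tuple[str, ...] = ("cnvnator", "manta", "delly")
    missing_depth_policy: str = "recompute"  # or "reject"

    def neutral(self, ratio: float) -> bool:
        return (1 - self.neutral_band_delta) <= ratio <= (1 + self.neutral_band_delta)

    def depth_ok(self, svtype: str, ratio: float) -> bool:
        if svtype == "DEL":
            return ratio < self.del_ratio_max
        return ratio > self.dup_ratio_min


@dataclass
class CallCluster:
    """Overlap-connected component of same-type calls across programs and lines."""

    svtype: str
    members: list[CNVCall]

    def __post_init__(self) -> None:
        chroms = {m.interval.chrom for m in self.members}
        if len(chroms) != 1:
            raise ValueError("cluster members must share one chromosome")
        if any(m.svtype != self.svtype for m in self.members):
            raise ValueError("cluster members must share the svtype")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.members[0].interval.chrom,
            min(m.interval.start for m in self.members),
            max(m.interval.end for m in self.members),
        )

    @property
    def lines(self) -> frozenset[str]:
        return frozenset(m.line_id for m in self.members)

    @property
    def callers(self) -> frozenset[str]:
        return frozenset(m.caller for m in self.members)


@dataclass(frozen=True)
class VerificationResult:
    """Outcome of automated cohort-wide depth verification for one candidate."""

    focal_ratio: float
    other_ratios: dict[str, float]
    flank_ok: bool
    pass_: bool
    reason: str
    orientation_ok: bool | None = None


@dataclass(frozen=True)
class ConsensusCNV:
    """A verified single-line mutation event with its chosen coordinates."""

    line_id: str
    interval: GenomicInterval
    svtype: str
    callers: frozenset[str] = frozenset()
    verification: VerificationResult | None = None

    @property
    def length(self) -> int:
        return self.interval.length

    def to_call(self, caller: str | None = None) -> CNVCall:
        """Re-express as a CNVCall (for round-trips through the pipeline)."""
        pick = caller or sorted(self.callers)[0] if self.callers else "other"
        return CNVCall(
            line_id=self.line_id,
            interval=self.interval,
            svtype=self.svtype,
            caller=pick if pick in ("cnvnator", "manta", "delly") else "other",
        )


def multi_intersect(calls: Iterable[CNVCall]) -> list[CallCluster]:
    """Cluster calls by >= 1 bp overlap, deletions and duplications separately.

    Two calls join the same cluster iff their intervals overlap (transitive
    closure), regardless of which program or MA line produced them. Output
    is ordered by (svtype, chromosome, start).
    """
    groups: dict[tuple[str, str], list[CNVCall]] = {}
    for c in calls:
        groups.setdefault((c.svtype, c.interval.chrom), []).append(c)

    clusters: list[CallCluster] = []
    for (svtype, _chrom), members in sorted(groups.items()):
        members.sort(key=lambda c: (c.interval.start, c.interval.end, c.line_id, c.caller))
        current: list[CNVCall] = []
        reach = -1
        for c in members:
            if current and c.interval.start < reach:
                current.append(c)
                reach = max(reach, c.interval.end)
            else:
                if current:
                    clusters.append(CallCluster(svtype, current))
                current = [c]
                reach = c.interval.end
        if current:
            clusters.append(CallCluster(svtype, current))
    clusters.sort(key=lambda cl: (cl.span.chrom, cl.span.start, cl.svtype))
    return clusters


def uniqueness_filter(
    clusters: Sequence[CallCluster],
) -> tuple[list[CallCluster], list[CallCluster]]:
    """Partition clusters into single-line (kept) and recurrent (removed)."""
    kept = [cl for cl in clusters if len(cl.lines) == 1]
    removed = [cl for cl in clusters if len(cl.lines) > 1]
    for cl in removed:
        logger.info(
            "recurrent cluster removed: %s %s lines=%s",
            cl.svtype, cl.span, sorted(cl.lines),
        )
    return kept, removed


def depth_threshold_filter(
    call: CNVCall,
    params: FilterParams = FilterParams(),
    profile: DepthProfile | None = None,
) -> bool:
    """Haploid depth-ratio rule: DEL < 0.5x, DUP > 1.5x (strict; boundaries fail).

    When the call carries no normalized depth, the ratio is recomputed from
    the line's depth profile (policy ``recompute``) or the call is rejected
    (policy ``reject``).
    """
    ratio = call.depth_ratio
    if ratio is None:
        if params.missing_depth_policy == "recompute" and profile is not None:
            ratio = profile.depth_ratio(call.interval)
        elif params.missing_depth_policy == "reject":
            return False
        else:
            raise ValueError(
                f"call {call.interval} has no depth_ratio and no profile was given"
            )
    return params.depth_ok(call.svtype, ratio)


def _flank_intervals(
    interval: GenomicInterval, chrom_len: int | None
) -> list[GenomicInterval]:
    """One CNV-length on each side, clipped to chromosome bounds."""
    width = interval.length
    out = []
    left_start = max(0, interval.start - width)
    if left_start < interval.start:
        out.append(GenomicInterval(interval.chrom, left_start, interval.start))
    right_end = interval.end + width
    if chrom_len is not None:
        right_end = min(right_end, chrom_len)
    if right_end > interval.end:
        out.append(GenomicInterval(interval.chrom, interval.end, right_end))
    return out


def _informative_flanks(
    interval: GenomicInterval,
    profile: DepthProfile,
    chrom_len: int | None,
) -> list[GenomicInterval]:
    """Flank intervals wide enough to carry depth signal.

    A flank clipped at a chromosome end can degenerate to a stub narrower
    than one depth window; the only window overlapping such a stub mostly
    measures the CNV itself, so stubs below one window width are dropped.
    """
    window = 1
    if interval.chrom in profile.windows:
        w = profile.windows[interval.chrom]
        window = int(np.median(w[:, 1] - w[:, 0]))
    return [
        f
        for f in _flank_intervals(interval, chrom_len)
        if f.length >= window
    ]


def verify_against_cohort(
    cnv: CNVCall | ConsensusCNV,
    profiles: dict[str, DepthProfile],
    params: FilterParams = FilterParams(),
) -> VerificationResult:
    """Automated cohort check replacing visual coverage-track inspection.

    Passes iff (a) the focal line's depth ratio over the CNV satisfies the
    haploid threshold for its type, (b) every other line is copy-neutral
    (ratio within 1 +/- delta) over the same interval, and (c) the focal
    line's flanking regions (one CNV length each side, clipped at
    chromosome ends) are copy-neutral.
    """
    if cnv.line_id not in profiles:
        raise ValueError(f"no depth profile for focal line {cnv.line_id!r}")
    focal = profiles[cnv.line_id]
    if any(p.mapq_floor < params.min_mapq for p in profiles.values()):
        low = sorted(
            lid for lid, p in profiles.items() if p.mapq_floor < params.min_mapq
        )
        raise ValueError(
            f"profiles {low} built below the MAPQ floor {params.min_mapq}"
        )
    interval = cnv.interval
    focal_ratio = focal.depth_ratio(interval)
    other_ratios = {
        lid: p.depth_ratio(interval)
        for lid, p in profiles.items()
        if lid != cnv.line_id
    }

    chrom_len = None
    if interval.chrom in focal.windows:
        chrom_len = int(focal.windows[interval.chrom][-1, 1])
    flanks = _informative_flanks(interval, focal, chrom_len)
    flank_ok = all(params.neutral(focal.depth_ratio(f)) for f in flanks)

    if not params.depth_ok(cnv.svtype, focal_ratio):
        pass_, reason = False, (
            f"focal depth ratio {focal_ratio:.3g} fails {cnv.svtype} threshold"
        )
    elif any(params.depth_ok(cnv.svtype, r) for r in other_ratios.values()):
        bad = sorted(
            lid for lid, r in other_ratios.items() if params.depth_ok(cnv.svtype, r)
        )
        pass_, reason = False, f"recurrent depth signal in lines {bad}"
    elif not all(params.neutral(r) for r in other_ratios.values()):
        bad = sorted(
            lid for lid, r in other_ratios.items() if not params.neutral(r)
        )
        pass_, reason = False, f"non-neutral depth in other lines {bad}"
    elif not flank_ok:
        pass_, reason = False, "flank anomaly"
    else:
        pass_, reason = True, "ok"
    return VerificationResult(
        focal_ratio=focal_ratio,
        other_ratios=other_ratios,
        flank_ok=flank_ok,
        pass_=pass_,
        reason=reason,
    )


def _concordance_score(
    call: CNVCall, profile: DepthProfile, params: FilterParams
) -> float:
    """|inside ratio - expected(svtype)| + |flank ratio - 1| (lower is better)."""
    expected = 0.0 if call.svtype == "DEL" else 2.0
    inside = profile.depth_ratio(call.interval)
    chrom_len = None
    if call.interval.chrom in profile.windows:
        chrom_len = int(profile.windows[call.interval.chrom][-1, 1])
    flanks = _informative_flanks(call.interval, profile, chrom_len)
    if flanks:
        flank = sum(profile.depth_ratio(f) for f in flanks) / len(flanks)
    else:
        flank = 1.0
    return abs(inside - expected) + abs(flank - 1.0)


def select_coordinates(
    cluster: CallCluster,
    profiles: dict[str, DepthProfile],
    params: FilterParams = FilterParams(),
) -> GenomicInterval:
    """Choose, among a cluster's member calls, the coordinates whose depth
    signature matches the expected copy number best; ties broken by caller
    priority, then smaller start."""
    (line_id,) = cluster.lines  # single-line rule enforced upstream
    profile = profiles[line_id]
    prio = {c: i for i, c in enumerate(params.caller_priority)}

    def key(call: CNVCall):
        return (
            _concordance_score(call, profile, params),
            prio.get(call.caller, len(prio)),
            call.interval.start,
            call.interval.end,
        )

    return min(cluster.members, key=key).interval


def length_filter(
    cnvs: Sequence, max_len: int = 20_000
) -> list:
    """Keep events strictly shorter than max_len bp."""
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    return [c for c in cnvs if c.interval.length < max_len]


def run_filter_pipeline(
    calls: Iterable[CNVCall],
    profiles: dict[str, DepthProfile] | None = None,
    mode: str = "verified",
    params: FilterParams = FilterParams(),
) -> list[ConsensusCNV]:
    """Run the full pipeline and return consensus single-line events.

    ``verified`` mode: intersect -> uniqueness -> depth thresholds ->
    cohort verification -> coordinate selection. ``prefilter`` mode:
    intersect -> uniqueness -> length cap (no depth evidence used).
    """
    if mode not in ("verified", "prefilter"):
        raise ValueError(f"unknown mode {mode!r}")
    clusters = multi_intersect(calls)
    kept, _removed = uniqueness_filter(clusters)

    out: list[ConsensusCNV] = []
    if mode == "prefilter":
        for cl in kept:
            if cl.span.length < params.max_len_prefilter:
                (line_id,) = cl.lines
                out.append(
                    ConsensusCNV(
                        line_id=line_id,
                        interval=cl.span,
                        svtype=cl.svtype,
                        callers=cl.callers,
                    )
                )
        out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.svtype))
        return out

    if profiles is None:
        raise ValueError("verified mode requires depth profiles for every line")
    for cl in kept:
        (line_id,) = cl.lines
        profile = profiles.get(line_id)
        members = [
            m for m in cl.members if depth_threshold_filter(m, params, profile)
        ]
        if not members:
            logger.info("cluster %s %s rejected by depth thresholds", cl.svtype, cl.span)
            continue
        sub = CallCluster(cl.svtype, members)
        interval = select_coordinates(sub, profiles, params)
        candidate = ConsensusCNV(
            line_id=line_id,
            interval=interval,
            svtype=cl.svtype,
            callers=sub.callers,
        )
        verdict = verify_against_cohort(candidate, profiles, params)
        if verdict.pass_:
            out.append(replace(candidate, verification=verdict))
        else:
            logger.info(
                "cluster %s %s failed verification: %s", cl.svtype, cl.span, verdict.reason
            )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.svtype))
    return out
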