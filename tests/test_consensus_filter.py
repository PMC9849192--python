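import numpy as np
import pytest

from macnv.cnv_io import CNVCall, DepthProfile
from macnv.consensus_filter import (
    CallCluster,
    FilterParams,
    depth_threshold_filter,
    length_filter,
    multi_intersect,
    run_filter_pipeline,
    select_coordinates,
    uniqueness_filter,
    verify_against_cohort,
)
from macnv.genome_model import GenomicInterval


def make_call(chrom, start, end, svtype="DEL", line="L1", caller="cnvnator", ratio=None):
    return CNVCall(
        line_id=line,
        interval=GenomicInterval(chrom, start, end),
        svtype=svtype,
        caller=caller,
        depth_ratio=ratio,
    )


def flat_profile(line_id, chrom_len=100_000, window=500, depth=40.0,
                 shifts=(), chrom="chr1"):
    """Uniform-depth profile with optional (start, end, factor) depth shifts."""
    starts = np.arange(0, chrom_len, window)
    ends = np.minimum(starts + window, chrom_len)
    d = np.full(len(starts), depth)
    for s, e, factor in shifts:
        lo = np.clip(starts, s, e)
        hi = np.clip(ends, s, e)
        frac = (hi - lo) / (ends - starts)
        d = d * (1 + frac * (factor - 1))
    return DepthProfile(line_id, {chrom: np.column_stack([starts, ends, d])})


class TestMultiIntersect:
    def test_cross_caller_overlap_forms_one_cluster(self):
        a = make_call("2", 7_186_805, 7_193_382, line="L54", caller="delly")
        b = make_call("2", 7_187_000, 7_192_000, line="L54", caller="cnvnator")
        (cluster,) = multi_intersect([a, b])
        assert cluster.callers == {"delly", "cnvnator"}
        assert cluster.span == GenomicInterval("2", 7_186_805, 7_193_382)

    def test_identical_interval_two_lines_one_cluster(self):
        a = make_call("1", 100, 200, line="A")
        b = make_call("1", 100, 200, line="B")
        (cluster,) = multi_intersect([a, b])
        assert cluster.lines == {"A", "B"}

    def test_del_and_dup_never_merge(self):
        a = make_call("1", 100, 200, svtype="DEL")
        b = make_call("1", 100, 200, svtype="DUP")
        clusters = multi_intersect([a, b])
        assert len(clusters) == 2
        assert {c.svtype for c in clusters} == {"DEL", "DUP"}

    def test_touching_intervals_do_not_merge(self):
        clusters = multi_intersect(
            [make_call("1", 100, 200), make_call("1", 200, 300)]
        )
        assert len(clusters) == 2

    def test_empty_input(self):
        assert multi_intersect([]) == []

    def test_transitive_closure_matches_union_find_oracle(self):
        """Sweep clustering equals brute-force connected components."""
        rng = np.random.default_rng(5)
        calls = [
            make_call("1", s := int(rng.integers(0, 5000)), s + int(rng.integers(1, 400)),
                      line=f"L{rng.integers(4)}", caller="manta")
            for _ in range(60)
        ]
        clusters = multi_intersect(calls)
        # oracle: union-find over all overlapping pairs
        parent = list(range(len(calls)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(calls)):
            for j in range(i + 1, len(calls)):
                if calls[i].interval.overlaps(calls[j].interval):
                    parent[find(i)] = find(j)
        oracle = {}
        for i, c in enumerate(calls):
            oracle.setdefault(find(i), set()).add(id(c))
        ours = [{id(m) for m in cl.members} for cl in clusters]
        assert sorted(map(sorted, oracle.values())) == sorted(map(sorted, ours))
        assert sum(len(cl.members) for cl in clusters) == len(calls)


class TestUniqueness:
    def test_partition_law(self):
        calls = [
            make_call("1", 0, 100, line="A"),
            make_call("1", 50, 150, line="B"),
            make_call("1", 500, 600, line="A"),
        ]
        clusters = multi_intersect(calls)
        kept, removed = uniqueness_filter(clusters)
        assert len(kept) == 1 and len(removed) == 1
        assert sorted(kept + removed, key=lambda c: c.span.start) == sorted(
            clusters, key=lambda c: c.span.start
        )
        assert all(len(c.lines) == 1 for c in kept)


class TestDepthThreshold:
    @pytest.mark.parametrize(
        "svtype,ratio,expected",
        [
            ("DEL", 0.0, True),    # zero coverage: the haploid deletion signature
            ("DEL", 0.49, True),
            ("DEL", 0.5, False),   # boundary excluded (strict inequality)
            ("DEL", 0.7, False),
            ("DUP", 2.1, True),    # ~double coverage for a haploid duplication
            ("DUP", 1.51, True),
            ("DUP", 1.5, False),
            ("DUP", 1.2, False),
        ],
    )
    def test_strict_thresholds(self, svtype, ratio, expected):
        call = make_call("1", 0, 100, svtype=svtype, ratio=ratio)
        assert depth_threshold_filter(call) is expected

    def test_missing_ratio_recomputed_from_profile(self):
        profile = flat_profile("L1", shifts=[(2000, 3000, 0.0)])
        call = make_call("chr1", 2000, 3000, ratio=None, caller="manta")
        assert depth_threshold_filter(call, profile=profile)

    def test_missing_ratio_reject_policy(self):
        params = FilterParams(missing_depth_policy="reject")
        call = make_call("chr1", 2000, 3000, ratio=None, caller="manta")
        assert depth_threshold_filter(call, params) is False


class TestVerifyAgainstCohort:
    def test_clean_single_line_deletion_passes(self):
        rng = np.random.default_rng(9)
        profiles = {}
        for i in range(10):
            lid = f"L{i}"
            noise = 40.0 + rng.normal(0, 1)
            shifts = [(4000, 5000, 0.02)] if i == 5 else []
            profiles[lid] = flat_profile(lid, depth=noise, shifts=shifts)
        call = make_call("chr1", 4000, 5000, line="L5", ratio=0.02)
        verdict = verify_against_cohort(call, profiles)
        assert verdict.pass_
        assert verdict.focal_ratio < 0.1
        assert all(0.9 < r < 1.1 for r in verdict.other_ratios.values())

    def test_recurrent_depth_signal_fails(self):
        profiles = {
            lid: flat_profile(lid, shifts=[(4000, 5000, 0.4)] if lid in ("L1", "L2") else [])
            for lid in ("L1", "L2", "L3")
        }
        call = make_call("chr1", 4000, 5000, line="L1", ratio=0.4)
        verdict = verify_against_cohort(call, profiles)
        assert not verdict.pass_
        assert "recurrent" in verdict.reason

    def test_flank_anomaly_fails(self):
        profiles = {
            "L1": flat_profile("L1", shifts=[(4000, 5000, 1.9), (3000, 4000, 1.8)]),
            "L2": flat_profile("L2"),
        }
        call = make_call("chr1", 4000, 5000, svtype="DUP", line="L1", ratio=1.9)
        verdict = verify_against_cohort(call, profiles)
        assert not verdict.pass_
        assert verdict.reason == "flank anomaly"

    def test_profile_below_mapq_floor_rejected(self):
        profiles = {"L1": flat_profile("L1")}
        profiles["L1"].mapq_floor = 10
        call = make_call("chr1", 4000, 5000, line="L1", ratio=0.1)
        with pytest.raises(ValueError, match="MAPQ"):
            verify_against_cohort(call, profiles)


class TestSelectCoordinates:
    def test_tighter_interval_wins(self):
        """A call padding the true event with normal-depth sequence scores worse."""
        profile = flat_profile("L1", shifts=[(4000, 5000, 0.0)])
        tight = make_call("chr1", 4000, 5000, caller="manta")
        loose = make_call("chr1", 3000, 5500, caller="delly")
        cluster = CallCluster("DEL", [tight, loose])
        assert select_coordinates(cluster, {"L1": profile}) == tight.interval

    def test_single_member(self):
        profile = flat_profile("L1", shifts=[(4000, 5000, 0.0)])
        only = make_call("chr1", 4000, 5000)
        assert (
            select_coordinates(CallCluster("DEL", [only]), {"L1": profile})
            == only.interval
        )

    def test_exact_tie_uses_caller_priority(self):
        # flat profile: every candidate interval scores identically
        profile = flat_profile("L1")
        a = make_call("chr1", 4500, 5500, caller="delly")
        b = make_call("chr1", 4000, 5000, caller="cnvnator")
        cluster = CallCluster("DEL", [a, b])
        params = FilterParams(caller_priority=("delly", "cnvnator", "manta"))
        assert select_coordinates(cluster, {"L1": profile}, params) == a.interval
        params2 = FilterParams(caller_priority=("cnvnator", "delly", "manta"))
        assert select_coordinates(cluster, {"L1": profile}, params2) == b.interval


class TestLengthFilter:
    def test_strictly_below_cap(self):
        short = make_call("1", 0, 11_000)
        exact = make_call("1", 0, 20_000)
        assert length_filter([short, exact], 20_000) == [short]

    def test_empty(self):
        assert length_filter([], 20_000) == []


class TestPipeline:
    @pytest.fixture
    def cohort(self):
        """Ten lines; true DEL in L3, true DUP in L7, recurrent artifact in 3 lines."""
        profiles = {}
        for i in range(10):
            lid = f"L{i}"
            shifts = []
            if i == 3:
                shifts.append((2000, 3000, 0.0))
            if i == 7:
                shifts.append((6000, 7000, 2.0))
            if i in (1, 4, 8):
                shifts.append((8000, 8800, 0.4))
            profiles[lid] = flat_profile(lid, shifts=shifts)
        calls = [
            make_call("chr1", 2000, 3000, line="L3", ratio=0.0),
            make_call("chr1", 2050, 3000, line="L3", caller="delly"),
            make_call("chr1", 6000, 7000, svtype="DUP", line="L7", ratio=2.05),
        ]
        for lid in ("L1", "L4", "L8"):
            calls.append(make_call("chr1", 8000, 8800, line=lid, ratio=0.4))
        return calls, profiles

    def test_verified_mode_keeps_true_events_only(self, cohort):
        calls, profiles = cohort
        out = run_filter_pipeline(calls, profiles, mode="verified")
        assert {(c.line_id, c.svtype) for c in out} == {("L3", "DEL"), ("L7", "DUP")}
        del_event = next(c for c in out if c.svtype == "DEL")
        assert del_event.interval == GenomicInterval("chr1", 2000, 3000)
        assert del_event.callers == {"cnvnator", "delly"}
        assert del_event.verification.pass_

    def test_idempotent_on_own_output(self, cohort):
        calls, profiles = cohort
        out = run_filter_pipeline(calls, profiles, mode="verified")
        again = run_filter_pipeline([c.to_call() for c in out], profiles, mode="verified")
        assert {(c.line_id, c.interval, c.svtype) for c in again} == {
            (c.line_id, c.interval, c.svtype) for c in out
        }

    def test_all_noise_input_yields_empty_output(self):
        profiles = {f"L{i}": flat_profile(f"L{i}") for i in range(5)}
        calls = [
            make_call("chr1", 1000, 2000, line=lid, ratio=0.3)
            for lid in ("L0", "L1", "L2")
        ]
        assert run_filter_pipeline(calls, profiles, mode="verified") == []

    def test_tightening_neutral_band_never_grows_output(self, cohort):
        calls, profiles = cohort
        loose = run_filter_pipeline(
            calls, profiles, params=FilterParams(neutral_band_delta=0.4)
        )
        tight = run_filter_pipeline(
            calls, profiles, params=FilterParams(neutral_band_delta=0.1)
        )
        keyset = lambda out: {(c.line_id, c.interval, c.svtype) for c in out}
        assert keyset(tight) <= keyset(loose)

    def test_prefilter_mode_skips_depth_evidence(self, cohort):
        calls, _profiles = cohort
        out = run_filter_pipeline(calls, None, mode="prefilter")
        # the recurrent artifact is still removed (multi-line), true events kept
        assert {(c.line_id, c.svtype) for c in out} == {("L3", "DEL"), ("L7", "DUP")}

    def test_unknown_mode_rejected(self, cohort):
        calls, profiles = cohort
        with pytest.raises(ValueError, match="mode"):
            run_filter_pipeline(calls, profiles, mode="igv")
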