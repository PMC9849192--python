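import numpy as np
import pytest

from macnv.genome_model import GenomicInterval, load_genome
from macnv.ssr_resampling import (
    DEFAULT_MIN_COPIES,
    count_interval_overlaps,
    detect_ssrs,
    permutation_test,
    random_placement,
)


def brute_force_ssrs(seq: str, min_copies=DEFAULT_MIN_COPIES):
    """Independent quadratic scan: for every (position, motif length) extend
    the tandem run directly and keep left-maximal primitive runs."""

    def primitive(m):
        return all(
            not (len(m) % d == 0 and m == m[: d] * (len(m) // d))
            for d in range(1, len(m))
        )

    def canon(m):
        return min(m[i:] + m[:i] for i in range(len(m)))

    found = set()
    n = len(seq)
    for k, min_c in enumerate(min_copies, start=1):
        for i in range(n - k):
            motif = seq[i : i + k]
            if any(b not in "ACGT" for b in motif) or not primitive(motif):
                continue
            if i > 0 and seq[i - 1] == seq[i + k - 1] and seq[i - 1] in "ACGT":
                continue  # extendable left: not maximal
            j = i + k
            while j < n and seq[j] == seq[j - k] and seq[j] in "ACGT":
                j += 1
            if (j - i) / k >= min_c:
                found.add((i, j, canon(motif)))
    return found


class TestDetectSsrs:
    def test_mononucleotide_run(self, fasta_factory):
        genome = load_genome(fasta_factory({"c": "GC" + "A" * 10 + "GC"}))
        (locus,) = detect_ssrs(genome)
        assert locus.motif == "A" and locus.copies == 10
        assert locus.interval == GenomicInterval("c", 2, 12)

    def test_dinucleotide_run_without_inner_mono_locus(self, fasta_factory):
        genome = load_genome(fasta_factory({"c": "G" + "AC" * 6 + "G"}))
        (locus,) = detect_ssrs(genome)
        assert locus.motif == "AC" and locus.copies == 6
        assert locus.interval.length == 12

    def test_motif_reported_in_canonical_rotation(self, fasta_factory):
        genome = load_genome(fasta_factory({"c": "G" + "CA" * 6 + "G"}))
        (locus,) = detect_ssrs(genome)
        assert locus.motif == "AC"

    def test_below_threshold_not_reported(self, fasta_factory):
        genome = load_genome(fasta_factory({"c": "G" + "A" * 9 + "G" + "AT" * 5 + "G"}))
        assert detect_ssrs(genome) == []

    def test_fractional_trailing_copies(self, fasta_factory):
        genome = load_genome(fasta_factory({"c": "G" + "AC" * 6 + "A" + "G"}))
        (locus,) = detect_ssrs(genome)
        assert locus.copies == pytest.approx(6.5)
        assert locus.interval.length == 13

    def test_matches_brute_force_on_random_sequence(self, fasta_factory):
        rng = np.random.default_rng(21)
        # AT-rich with injected repeats so loci of several motif lengths occur
        parts = []
        for _ in range(200):
            parts.append("".join(rng.choice(list("ATATGC"), rng.integers(20, 120))))
            motif = ["A", "T", "AT", "AAC", "AGAT"][rng.integers(5)]
            parts.append(motif * int(rng.integers(4, 15)))
        seq = "".join(parts)[:100_000]
        genome = load_genome(fasta_factory({"c": seq}))
        ours = {
            (s.interval.start, s.interval.end, s.motif) for s in detect_ssrs(genome)
        }
        assert ours == brute_force_ssrs(seq)

    def test_invariant_to_case_and_line_wrapping(self, fasta_factory, tmp_path):
        seq = "GCGC" + "ACT" * 8 + "T" * 15 + "GC"
        g1 = load_genome(fasta_factory({"c": seq}, wrap=60, name="a.fa"))
        g2 = load_genome(fasta_factory({"c": seq.lower()}, wrap=7, name="b.fa"))
        assert detect_ssrs(g1) == detect_ssrs(g2)


class TestCountIntervalOverlaps:
    Q = [GenomicInterval("c", 0, 100), GenomicInterval("c", 500, 600),
         GenomicInterval("d", 0, 50)]
    F = [GenomicInterval("c", 50, 80), GenomicInterval("c", 90, 550),
         GenomicInterval("d", 100, 200)]

    def test_modes(self):
        assert count_interval_overlaps(self.Q, self.F, "any_feature") == 2
        assert count_interval_overlaps(self.Q, self.F, "features_touched") == 2
        assert count_interval_overlaps(self.Q, self.F, "features_contained") == 1

    def test_no_features(self):
        for mode in ("any_feature", "features_contained", "features_touched"):
            assert count_interval_overlaps(self.Q, [], mode) == 0

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            count_interval_overlaps(self.Q, self.F, "jaccard")

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(13)

        def rand_ivs(n, max_len):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 10_000))
                out.append(
                    GenomicInterval(f"chr{rng.integers(2)}", s, s + int(rng.integers(1, max_len)))
                )
            return out

        for _ in range(5):
            q, f = rand_ivs(50, 500), rand_ivs(200, 100)
            assert count_interval_overlaps(q, f, "any_feature") == sum(
                1 for x in q if any(x.overlaps(y) for y in f)
            )
            assert count_interval_overlaps(q, f, "features_touched") == sum(
                1 for y in f if any(x.overlaps(y) for x in q)
            )
            assert count_interval_overlaps(q, f, "features_contained") == sum(
                1 for y in f if any(x.contains(y) for x in q)
            )


class TestRandomPlacement:
    def test_full_chromosome_length_forces_start_zero(self, small_genome):
        genome, _ = small_genome
        rng = np.random.default_rng(0)
        for _ in range(20):
            (iv,) = random_placement([10_000], genome, rng)
            if iv.chrom == "chrB":
                assert iv.start == 0

    def test_chromosome_sampling_proportional_to_valid_positions(self, fasta_factory):
        genome = load_genome(
            fasta_factory({"big": "A" * 9000, "small": "A" * 1000})
        )
        rng = np.random.default_rng(1)
        draws = random_placement([1] * 20_000, genome, rng)
        frac_big = sum(iv.chrom == "big" for iv in draws) / 20_000
        # binomial 3 sigma around p = 0.9 at n = 20,000
        assert abs(frac_big - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 20_000)

    def test_same_seed_reproduces(self, small_genome):
        genome, _ = small_genome
        a = random_placement([100, 200, 300], genome, 99)
        b = random_placement([100, 200, 300], genome, 99)
        assert a == b

    def test_oversized_interval_rejected(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(ValueError):
            random_placement([50_000], genome, 0)


class TestBreakpointSsrOverlap:
    def test_window_covering_ssr_counts(self, small_genome):
        from macnv.consensus_filter import ConsensusCNV
        from macnv.ssr_resampling import SSRLocus, breakpoint_ssr_overlap

        genome, _ = small_genome
        # one tract just upstream of position 1020 (a CNV start breakpoint)
        ssrs = [SSRLocus(GenomicInterval("chrA", 1000, 1012), "A", 12)]
        near = ConsensusCNV("L1", GenomicInterval("chrA", 1020, 2020), "DEL")
        far = ConsensusCNV("L1", GenomicInterval("chrA", 3000, 4000), "DEL")
        assert breakpoint_ssr_overlap([near], ssrs, genome, flank=50) == 1
        assert breakpoint_ssr_overlap([far], ssrs, genome, flank=50) == 0
        # widening the flank brings the distant CNV's window onto the tract
        assert breakpoint_ssr_overlap([far], ssrs, genome, flank=2000) == 1

    def test_matches_quadratic_oracle(self, small_genome):
        from macnv.composition import breakpoint_windows
        from macnv.consensus_filter import ConsensusCNV
        from macnv.ssr_resampling import breakpoint_ssr_overlap

        genome, _ = small_genome
        rng = np.random.default_rng(77)
        cnvs = []
        for _ in range(20):
            s = int(rng.integers(100, 18_000))
            cnvs.append(ConsensusCNV("L1", GenomicInterval("chrA", s, s + 500), "DEL"))
        from macnv.ssr_resampling import SSRLocus

        ssrs = []
        for _ in range(60):
            s = int(rng.integers(0, 19_900))
            ssrs.append(SSRLocus(GenomicInterval("chrA", s, s + 12), "A", 12))
        got = breakpoint_ssr_overlap(cnvs, ssrs, genome, flank=50)
        wins = [w for c in cnvs for w in breakpoint_windows(c, 50, genome)]
        want = sum(1 for w in wins if any(w.overlaps(s.interval) for s in ssrs))
        assert got == want


class TestPermutationTest:
    def test_features_covering_genome_degenerate(self, small_genome):
        genome, _ = small_genome
        features = [GenomicInterval(c, 0, n) for c, n in genome.chromosomes]
        queries = [GenomicInterval("chrA", 100, 200)]
        res = permutation_test(queries, features, N=100, seed=0, genome=genome)
        assert res.observed == 1
        assert res.percentile == pytest.approx(0.5)  # all null values tie
        assert res.p_lower == res.p_upper == 1.0

    def test_null_draw_sits_mid_distribution(self, small_genome):
        genome, _ = small_genome
        rng = np.random.default_rng(2)
        features = random_placement([200] * 100, genome, rng)
        queries = random_placement([300] * 20, genome, rng)
        res = permutation_test(queries, features, N=400, seed=3, genome=genome)
        assert 0.02 < res.percentile < 0.98
        assert min(res.p_lower, res.p_upper) > 0.005

    def test_calibration_under_null(self, small_genome):
        """Observed data simulated from the placement null itself: the midrank
        percentile is mean-0.5, the empirical p is valid (super-uniform, i.e.
        never anti-conservative) and lives on the (N+1)-point grid."""
        genome, _ = small_genome
        rng = np.random.default_rng(4)
        features = random_placement([150] * 120, genome, rng)
        ps, percentiles = [], []
        N = 100
        for rep in range(120):
            queries = random_placement([250] * 12, genome, rng)
            res = permutation_test(queries, features, N=N, seed=1000 + rep,
                                   genome=genome)
            ps.append(res.p_lower)
            percentiles.append(res.percentile)
        ps = np.asarray(ps)
        # E[midrank percentile] = 1/2 exactly, even for a discrete statistic
        assert abs(np.mean(percentiles) - 0.5) < 0.08  # ~3 sigma, n=120
        # validity: P(p <= alpha) <= alpha up to binomial noise
        for alpha in (0.05, 0.1):
            assert np.mean(ps <= alpha) <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 120)
        # every p on the grid k/(N+1)
        scaled = ps * (N + 1)
        assert np.allclose(scaled, np.round(scaled), atol=1e-9)

    def test_increasing_N_does_not_shift_percentile(self, small_genome):
        genome, _ = small_genome
        rng = np.random.default_rng(6)
        features = random_placement([150] * 150, genome, rng)
        queries = random_placement([250] * 15, genome, rng)
        p100 = permutation_test(queries, features, N=100, seed=7, genome=genome)
        p1000 = permutation_test(queries, features, N=1000, seed=8, genome=genome)
        assert abs(p100.percentile - p1000.percentile) < 0.2

    def test_small_N_rejected(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(ValueError):
            permutation_test([], [], N=10, seed=0, genome=genome)
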