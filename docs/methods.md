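# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; a touch at a boundary
(`end == start'`) is not an overlap. GFF3 input (1-based inclusive) is
converted on load; BED and the per-event summary TSV are used as-is, with
`Length = End - Start` throughout. VCF `POS` becomes `start = POS - 1`; a
CNVnator region `chrom:start-end` (1-based inclusive) becomes
`(start - 1, end)`. Strand is carried on gene records but ignored
everywhere: deletions and duplications are unstranded.

## Consensus filtering

Calls from all programs and lines are clustered by ≥1 bp overlap with
transitive closure, deletions and duplications separately (the
`bedtools multiinter` notion of "the same region"); reciprocal-overlap
clustering is deliberately not the default because the published procedure
used plain intersection. Clusters spanning more than one MA line are
removed (single-line uniqueness): a spontaneous mutation arises in exactly
one lineage, whereas regions prone to mismapping generate the same call in
many lines.

Depth evidence is the ratio of mean read depth in a region to the line's
genome-wide mean, computed from windowed depth tracks built from
MAPQ ≥ 20 alignments (`mapq_floor` is recorded on every profile and
verified against the configured floor). In a haploid genome a real
deletion is ~0× and a real duplication ~2×; read-depth calls are kept only
**below 0.5×** (deletions) or **above 1.5×** (duplications), strict
inequalities, boundary values rejected.

Manual inspection of coverage tracks is replaced by a quantitative
contract, `verify_against_cohort`. A candidate passes iff

* the focal line's ratio over the candidate interval satisfies the
  threshold for its type;
* every other line's ratio over the same interval lies in the copy-neutral
  band `[1 − δ, 1 + δ]` (δ = 0.3 by default — the published criteria are
  verbal, so the band is a package choice, configurable and echoed into
  run logs);
* the focal line's flanking regions, one CNV length on each side clipped
  at chromosome ends, are copy-neutral. Flank stubs narrower than one
  depth window (possible after clipping at a chromosome end) are excluded:
  the only window overlapping such a stub mostly measures the CNV itself,
  so it carries no independent flank signal.

When several programs call one event, coordinates are chosen by the
concordance score `|inside_ratio − expected| + |mean_flank_ratio − 1|`
(expected 0 for deletions, 2 for duplications); ties break by configured
caller priority (default cnvnator, manta, delly), then smaller start. The
verification verdict attached to each reported event is computed on the
chosen coordinates. Base-quality inspection is not modeled independently;
profiles are assumed built from quality-filtered alignments.

`prefilter` mode reproduces the permissive robustness variant: clustering
and uniqueness only, plus a strict `< 20 kb` length cap, no depth
evidence. Its output is a superset of verified mode on any input where
verified mode's extra filters bind, so rates from prefilter output bound
the verified rates from above.

## Rate estimation

A gene entirely contained in a CNV is a *complete* gene deletion or
duplication; ≥1 bp overlap without containment is *partial*. tRNA and
other non-coding biotypes are retained by the annotation reader but
excluded from rate categories (`protein_coding_only=True`). A gene hit by
two CNVs in one line contributes one event per (gene, CNV) pair.

Per line, μ = m/(n·T). Summaries average per-line μ with equal line
weights, including zero-mutation lines — the two line sets ran for
different T (≈1000 vs ≈2000 generations), so equal-line weighting and
pooling (`sum(m) / (n · sum(T))`) differ; both are reported. n is an
input (annotation-derived by default) because the study's genome release
is not pinned down by its text. Per-genome per-generation rates are
`mean over lines of (#events / T)` by type.

Pearson correlations (coverage vs event count, CNV rate vs small-mutation
rates) use the sample statistic with the t-distribution p-value on n − 2
degrees of freedom; zero-variance input is a named error.

## Composition and SSR statistics

%AT = (#A + #T)/(#A + #T + #G + #C), ambiguity codes excluded from both
numerator and denominator (assembly gaps must not bias composition);
an interval of only ambiguous bases yields NaN and is dropped from sample
sets. Breakpoint windows are ±flank around each CNV edge (50 bp and 2 kb
defaults), clipped to chromosomes, degenerate windows dropped. The genomic
background is computed two ways — per chromosome, and as non-overlapping
windows of width equal to the median CNV length — because the background
unit is a genuine modelling choice; the window variant is the default
comparator since it matches the CNV sample unit in scale.

The rank-sum test is two-sided Mann–Whitney: exact null distribution when
the samples are tie-free and |a|·|b| ≤ 10,000, otherwise the normal
approximation with tie and continuity corrections (scipy's
implementation; the test suite checks it against full enumeration on
small cases and against an independent reference on shifted normals).

SSR detection reports maximal perfect tandem runs of primitive 1–6 bp
motifs above per-length minimum copies (10/6/5/5/5/5 — MISA-style minima,
configurable, since the scripts cited by the study do not publish their
thresholds). Motifs are reported in canonical (lexicographically minimal)
rotation; trailing partial copies count fractionally; overlapping runs of
different motifs are all reported; runs containing ambiguous bases are
split at those bases.

Permutation tests re-place the observed intervals' length multiset
uniformly over the genome: chromosome sampled proportionally to its valid
start positions, start uniform, placements independent (no exclusion
rule — the study states none; chromosome-preserving placement is a config
option, off by default). The overlap statistic (queries overlapping ≥1
feature, features contained in queries, or features touched) is computed
identically on the observed set and each of N ≥ 100 draws (default
1,000; resolving p < 0.001 needs N ≥ 999). The percentile uses midrank
tie handling; empirical p-values use (1 + k)/(N + 1) on each side so p is
never 0. With a discrete counting statistic this estimator is
conservative under ties: the calibration tests therefore check that the
midrank percentile has mean 1/2, that P(p ≤ α) ≤ α, and that p lies on
the (N+1)-point grid, rather than literal uniformity.

## The synthetic-data generator

The generator emulates the study system at test scale. Defaults: 37 lines
(19 at T = 1000, 18 at T = 2000), deletion rate 3.9×10⁻⁸ and duplication
rate 1.2×10⁻⁸ per gene per generation, event lengths resampled from the
21 verified event lengths, ~40× mean depth, MAPQ floor 20. The toy genome
defaults to 6 × 200 kb chromosomes at 78% AT, 68% of length in
non-overlapping protein-coding genes (two genes re-labelled tRNA), and
~10% of sequence in perfect SSR tracts; tests and the acceptance script
use 2–4 chromosomes of 100–150 kb so whole-pipeline runs take seconds.
Because SSR motifs are AT-biased, the background base mix is
analytically compensated so the realized genome-wide %AT hits the target
(within ±0.01 at 1 Mb).

Event counts per line are Poisson(rate·n·T). Each event anchors on a
uniformly chosen protein-coding gene (5% are intergenic by default — the
study observed one CNV hitting no gene) and is positioned to overlap its
anchor, with length from the length model. Note the configured rate is
the *event* rate per anchor gene; because one event typically overlaps
more than one gene in a 68%-gene-dense genome, realized gene × CNV event
counts exceed Poisson(rate·n·T) by the mean genes-per-event factor.
Estimator-recovery checks therefore compare the estimator against the
count-level generative law directly.

Events and artifact regions are mutually separated by at least one CNV
length. At the study's rates on a 34 Mb genome, two events falling within
one CNV length of each other is a probability-~0 coincidence; on a
sub-megabase test genome it would otherwise occur and make the flank and
cohort-neutrality checks ill-posed on inputs that are, by construction,
meant to be clean.

Caller emulation emits each true event per caller with configurable
sensitivity (default 1) and coordinate jitter (default 0); CNVnator-style
records carry the realized depth ratio. Depth tracks are
Poisson(mean_depth × copy number) per 100 bp window; 100 bp (not larger)
because the shortest real events (~450 bp) would otherwise lose their
depth contrast to window averaging — real coverage tracks are
base-resolution. Two artifact classes are injected: *recurrent* regions
with a genuine intermediate depth shift (0.35×/1.8×) and identical calls
in ≥2 lines (removed by uniqueness), and *spurious* single-line calls
claiming a passing depth ratio but with no signal in the track (removed
by cohort verification; retained by prefilter mode). Overdispersed
(negative binomial) depth is available as a config option, off by
default.

What the simulator does **not** model: read-level data (no FASTQ, no
mapping), sequencing error, GC-coverage bias, real caller behavior
(breakpoint uncertainty beyond uniform jitter, caller-specific length
biases), imperfect/compound SSRs, and chromosome-scale heterogeneity.
Passing the recovery tests therefore shows the *filtering logic* is
correct on signals with the stated geometry and noise — not that the
upstream callers would behave this way on real reads.

## The packaged fixture

The 21 verified events of the motivating study are shipped as code
(chromosome, start, end, type, line, calling programs), together with a
37-line roster: the 14 event-bearing lines named by the study plus 23
synthetic placeholder ids (the study names only lines with events but
sequenced 37). Per-line generation counts are nominal set-level values
(L-prefixed lines 2000, QS-prefixed 1000, placeholders filling the sets
to 19/18); exact per-line T and n live in the study's supplementary
material, so exact reproduction of its averaged gene rates is out of
desk-scale scope — the fixture supports the count, length, and per-genome
summaries plus all formula-level checks.

## Numerical and degenerate-input choices

Empty call sets flow through every stage (empty reports, no crash). An
all-ambiguous interval has undefined %AT (NaN, dropped). Mean lengths of
an absent event type are NaN and rendered as gaps. Depth profiles must
tile chromosomes contiguously; overlap or gap errors name the first
offending window. Interval containment and overlap are closed under the
half-open convention (`contains` allows shared endpoints; touch is not
overlap). All generators and tests derive randomness from explicit seeds;
reports embed the seed, config snapshot and input hashes in a manifest.
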