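"""Synthetic mutation-accumulation (MA) data generator and packaged fixture.

Generates everything the pipeline consumes, scaled down from the real
study system (a haploid, AT-rich, gene-dense amoeba genome) to sizes a
test suite can run in seconds:

* a multi-chromosome genome with ~78% AT, ~68% of its length covered by
  non-overlapping protein-coding genes, and injected simple-sequence-repeat
  tracts;
* 37 haploid MA lines, one set propagated ~1000 and the other ~2000
  generations, accumulating gene deletion/duplication events as a Poisson
  process with per-gene per-generation rates of order 1e-8;
* emulated caller outputs (read-depth caller text, breakpoint-caller VCFs)
  and windowed depth profiles, optionally with recurrent multi-line
  artifacts and spurious single-line calls lacking depth support;
* the packaged fixture of the 21 verified deletion/duplication events of
  the source study's per-event table, with a 37-line roster.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .cnv_io import CNVCall, DepthProfile, write_depth_profile
from .consensus_filter import ConsensusCNV
from .genome_model import (
    GeneRecord,
    GenomeIndex,
    GenomicInterval,
    load_genome,
    write_annotation_bed,
)

__all__ = [
    "GenomeConfig",
    "ArtifactConfig",
    "MASimConfig",
    "TrueEvent",
    "SimTruth",
    "TABLE1_LENGTHS",
    "generate_genome",
    "simulate_ma",
    "simulate_event_counts",
    "emulate_outputs",
    "table1_fixture",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class GenomeConfig:
    """Scaled-down genome emulating an AT-rich, gene-dense haploid assembly."""

    n_chroms: int = 6
    chrom_length: int = 200_000
    at_fraction: float = 0.78
    gene_coverage: float = 0.68
    gene_length_mean: int = 1_500
    gene_length_min: int = 300
    gene_length_max: int = 6_000
    ssr_fraction: float = 0.10
    ssr_tract_mean: int = 30
    n_trna: int = 2

    def __post_init__(self) -> None:
        if self.gene_coverage > 0.95:
            raise ValueError("gene coverage target > 0.95 is infeasible")


@dataclass(frozen=True)
class ArtifactConfig:
    """Caller artifacts layered on top of true events."""

    n_recurrent: int = 2          # identical calls + depth dips in several lines
    lines_affected: int = 3       # >= 2 so the uniqueness rule removes them
    n_spurious_single_line: int = 2  # single-line calls with no depth support
    artifact_length: int = 3_000


@dataclass(frozen=True)
class MASimConfig:
    """Study conditions of the simulated MA experiment.

    Defaults mirror the study design: 37 lines (19 at T=1000, 18 at
    T=2000), deletion and duplication rates of order 1e-8 per gene per
    generation, event lengths resampled from the 21 verified events, ~40x
    sequencing depth and depth evidence at MAPQ >= 20.
    """

    n_lines: int = 37
    generations: tuple[int, ...] = tuple([1000] * 19 + [2000] * 18)
    rate_del: float = 3.9e-8
    rate_dup: float = 1.2e-8
    n_genes: int | None = None          # default: count protein-coding genes
    genome: GenomeConfig = GenomeConfig()
    length_model: str | tuple = "empirical_table1"  # or ("lognormal", mu, sigma)
    intergenic_fraction: float = 0.05
    artifact: ArtifactConfig = ArtifactConfig()
    caller_sensitivity: dict | None = None  # default 1.0 per caller
    coord_jitter: int = 0
    depth_window: int = 100  # base-pair resolution of emulated coverage tracks
    mean_depth: float = 40.0
    mapq_floor: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.generations) != self.n_lines:
            raise ValueError("generations must list one T per line")
        if self.rate_del < 0 or self.rate_dup < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def line_ids(self) -> list[str]:
        return [f"S{i:02d}" for i in range(1, self.n_lines + 1)]

    @property
    def roster(self) -> list[tuple[str, int]]:
        return list(zip(self.line_ids, self.generations))

    def sensitivity(self, caller: str) -> float:
        if self.caller_sensitivity is None:
            return 1.0
        return float(self.caller_sensitivity.get(caller, 1.0))


@dataclass(frozen=True)
class TrueEvent:
    line_id: str
    interval: GenomicInterval
    svtype: str
    genes_complete: tuple[str, ...] = ()
    genes_partial: tuple[str, ...] = ()


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    events: list[TrueEvent]
    artifact_calls: list[CNVCall]
    artifact_regions: list[tuple[GenomicInterval, str, tuple[str, ...], str]]
    roster: list[tuple[str, int]]

    def per_line_counts(self) -> dict[str, dict[str, int]]:
        out = {lid: {"DEL": 0, "DUP": 0} for lid, _ in self.roster}
        for e in self.events:
            out[e.line_id][e.svtype] += 1
        return out


# ---------------------------------------------------------------------------
# genome generation

_BASES = np.frombuffer(b"ATGC", dtype=np.uint8)
_SSR_MOTIFS = ("A", "T", "AT", "AC", "AAT", "AAC", "AGAT", "AATAT")


def _random_sequence(n: int, at: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
    return rng.choice(_BASES, size=n, p=p)


def generate_genome(
    config: GenomeConfig,
    outdir: str | Path,
    seed: int = 0,
) -> tuple[GenomeIndex, list[GeneRecord]]:
    """Write genome.fa and genes.bed under *outdir*; return index and genes.

    Chromosome sequences are iid draws at the target %AT with perfect SSR
    tracts overwritten at the configured density. Genes are laid down left
    to right with exponential intergenic gaps tuned so realized coverage
    matches the target.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # SSR motifs are AT-biased; compensate the background base mix so the
    # realized genome-wide %AT still hits the target
    motif_at = float(
        np.mean([sum(b in "AT" for b in m) / len(m) for m in _SSR_MOTIFS])
    )
    f_ssr = config.ssr_fraction
    bg_at = (config.at_fraction - f_ssr * motif_at) / (1 - f_ssr)
    bg_at = float(np.clip(bg_at, 0.0, 1.0))

    genes: list[GeneRecord] = []
    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for ci in range(config.n_chroms):
            chrom = f"chr{ci + 1}"
            arr = _random_sequence(config.chrom_length, bg_at, rng)
            # SSR tracts: overwrite segments with perfect tandem repeats
            n_tracts = int(config.ssr_fraction * config.chrom_length / config.ssr_tract_mean)
            for _ in range(n_tracts):
                motif = _SSR_MOTIFS[rng.integers(len(_SSR_MOTIFS))]
                tract_len = max(
                    len(motif) * 6,
                    int(rng.exponential(config.ssr_tract_mean)),
                )
                start = int(rng.integers(0, config.chrom_length - tract_len))
                tract = (motif * (tract_len // len(motif) + 1))[:tract_len]
                arr[start : start + tract_len] = np.frombuffer(
                    tract.encode(), dtype=np.uint8
                )
            seq = arr.tobytes().decode()
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

            # gene placement: draw lengths to an explicit coverage budget,
            # then distribute the remaining sequence as intergenic gaps
            budget = config.gene_coverage * config.chrom_length
            lengths: list[int] = []
            total = 0
            while total < budget:
                length = int(
                    np.clip(
                        rng.lognormal(
                            math.log(config.gene_length_mean) - 0.125, 0.5
                        ),
                        config.gene_length_min,
                        config.gene_length_max,
                    )
                )
                if total + length > budget:
                    length = max(config.gene_length_min, int(budget - total))
                lengths.append(length)
                total += length
            gaps = rng.exponential(1.0, size=len(lengths) + 1)
            gaps = np.maximum(
                1, (gaps / gaps.sum() * (config.chrom_length - total)).astype(int)
            )
            pos = int(gaps[0])
            for gi, length in enumerate(lengths, start=1):
                if pos + length > config.chrom_length:
                    break
                genes.append(
                    GeneRecord(
                        gene_id=f"{chrom}_g{gi:04d}",
                        interval=GenomicInterval(chrom, pos, pos + length),
                        strand="+" if rng.random() < 0.5 else "-",
                        biotype="protein_coding",
                    )
                )
                pos += length + int(gaps[gi])

    # re-label a few genes as tRNA (kept by annotation, excluded from rates)
    if config.n_trna and genes:
        idx = rng.choice(len(genes), size=min(config.n_trna, len(genes)), replace=False)
        for i in sorted(int(j) for j in idx):
            genes[i] = replace(genes[i], biotype="tRNA")

    write_annotation_bed(genes, outdir / "genes.bed")
    return load_genome(fasta_path), genes


# ---------------------------------------------------------------------------
# MA simulation

#: Lengths (bp) of the 21 verified events in the study's per-event table.
TABLE1_LENGTHS = (
    500, 8000, 2000, 6000, 436, 727, 1803, 6577, 901, 11000, 4500,
    3500, 2000, 4000, 6062, 1181, 2573, 1297, 4500, 498, 4000,
)


def _draw_length(config: MASimConfig, rng: np.random.Generator) -> int:
    if config.length_model == "empirical_table1":
        return int(TABLE1_LENGTHS[rng.integers(len(TABLE1_LENGTHS))])
    kind, mu, sigma = config.length_model
    if kind != "lognormal":
        raise ValueError(f"unknown length model {config.length_model!r}")
    return max(50, int(rng.lognormal(mu, sigma)))


def _classify(
    interval: GenomicInterval, genes: list[GeneRecord]
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    comp, part = [], []
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        if not interval.overlaps(g.interval):
            continue
        (comp if interval.contains(g.interval) else part).append(g.gene_id)
    return tuple(comp), tuple(part)


def simulate_event_counts(
    config: MASimConfig, n_genes: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Per-line Poisson event counts, shape (n_lines, 2) for (DEL, DUP).

    This is the generative law of the experiment marginalized over event
    placement: the expected count in a line is rate * n_genes * T.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    T = np.asarray(config.generations, dtype=float)
    lam_del = config.rate_del * n_genes * T
    lam_dup = config.rate_dup * n_genes * T
    return np.column_stack([rng.poisson(lam_del), rng.poisson(lam_dup)])


def simulate_ma(
    config: MASimConfig,
    genome: GenomeIndex,
    genes: list[GeneRecord],
    seed: int | None = None,
) -> SimTruth:
    """Simulate spontaneous deletion/duplication accumulation across lines.

    Event counts per line are Poisson(rate * n_genes * T); each event
    anchors on a uniformly chosen protein-coding gene (or is intergenic
    with the configured probability) with its length drawn from the length
    model. Same-type events are redrawn if they would overlap an existing
    event or artifact region, keeping truth recovery well-defined (real
    spontaneous events at these rates essentially never collide).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    coding = [g for g in genes if g.biotype == "protein_coding"]
    n_genes = config.n_genes or len(coding)

    # events and artifacts never co-localize, regardless of type, and keep a
    # one-CNV-length separation: at realistic rates on a full-size genome two
    # spontaneous events essentially never fall that close, and proximity
    # would make depth verification (flanks of one CNV length) ill-posed
    occupied: list[GenomicInterval] = []

    def collides(iv: GenomicInterval, svtype: str) -> bool:
        for o in occupied:
            if o.chrom != iv.chrom:
                continue
            pad = max(iv.length, o.length)
            if iv.start - pad < o.end and o.start < iv.end + pad:
                return True
        return False

    # reserve artifact regions first so no true event overlaps them
    artifact_regions: list[tuple[GenomicInterval, str, tuple[str, ...], str]] = []
    art = config.artifact
    line_ids = config.line_ids
    for kind, count in (("recurrent", art.n_recurrent),
                        ("spurious", art.n_spurious_single_line)):
        for _ in range(count):
            svtype = "DEL" if rng.random() < 0.7 else "DUP"
            for _attempt in range(1000):
                chrom, clen = genome.chromosomes[rng.integers(len(genome.chromosomes))]
                start = int(rng.integers(0, clen - art.artifact_length))
                iv = GenomicInterval(chrom, start, start + art.artifact_length)
                if not collides(iv, svtype):
                    break
            occupied.append(iv)
            if kind == "recurrent":
                lines = tuple(
                    line_ids[int(i)]
                    for i in rng.choice(len(line_ids), art.lines_affected, replace=False)
                )
            else:
                lines = (line_ids[int(rng.integers(len(line_ids)))],)
            artifact_regions.append((iv, svtype, lines, kind))

    counts = simulate_event_counts(config, n_genes, rng)
    events: list[TrueEvent] = []
    for li, (lid, _T) in enumerate(config.roster):
        for svtype, k in (("DEL", counts[li, 0]), ("DUP", counts[li, 1])):
            for _ in range(int(k)):
                for _attempt in range(1000):
                    length = _draw_length(config, rng)
                    if rng.random() < config.intergenic_fraction or not coding:
                        chrom, clen = genome.chromosomes[
                            rng.integers(len(genome.chromosomes))
                        ]
                        start = int(rng.integers(0, max(1, clen - length)))
                    else:
                        g = coding[rng.integers(len(coding))]
                        chrom = g.interval.chrom
                        clen = genome.chrom_length(chrom)
                        lo = max(0, g.interval.start - length + 1)
                        hi = min(g.interval.end - 1, clen - length)
                        start = int(rng.integers(lo, max(lo + 1, hi + 1)))
                    iv = GenomicInterval(chrom, start, min(clen, start + length))
                    if not collides(iv, svtype):
                        break
                occupied.append(iv)
                comp, part = _classify(iv, genes)
                events.append(TrueEvent(lid, iv, svtype, comp, part))

    artifact_calls: list[CNVCall] = []
    for iv, svtype, lines, kind in artifact_regions:
        claimed = 0.30 if svtype == "DEL" else 1.90
        for lid in lines:
            for caller in ("cnvnator", "delly"):
                artifact_calls.append(
                    CNVCall(
                        line_id=lid,
                        interval=iv,
                        svtype=svtype,
                        caller=caller,
                        depth_ratio=claimed if caller == "cnvnator" else None,
                    )
                )
    return SimTruth(
        events=events,
        artifact_calls=artifact_calls,
        artifact_regions=artifact_regions,
        roster=config.roster,
    )


# ---------------------------------------------------------------------------
# caller-output and depth emulation

def _copy_number_track(
    chrom_len: int,
    window: int,
    regions: list[tuple[GenomicInterval, float]],
) -> np.ndarray:
    """Per-window mean copy number for one chromosome (windows of `window` bp)."""
    starts = np.arange(0, chrom_len, window)
    ends = np.minimum(starts + window, chrom_len)
    cn = np.ones(len(starts), dtype=float)
    for iv, value in regions:
        lo = np.clip(iv.start, starts, ends)
        hi = np.clip(iv.end, starts, ends)
        frac = (hi - lo) / (ends - starts)
        cn += frac * (value - 1.0)
    return np.column_stack([starts, ends, cn])


def emulate_outputs(
    truth: SimTruth,
    config: MASimConfig,
    genome: GenomeIndex,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> tuple[list[CNVCall], dict[str, DepthProfile]]:
    """Emit caller-style calls and Poisson depth profiles for every line.

    True events appear in each caller's output with that caller's
    sensitivity (coordinates jittered by up to ``coord_jitter`` bp).
    Recurrent artifact regions receive a genuine intermediate depth shift
    (0.35x / 1.8x) in their affected lines; spurious single-line artifact
    calls get no depth support at all, so depth verification can reject
    them. Windowed depth is Poisson(mean_depth * copy number) per window.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    jitter = config.coord_jitter

    events_by_line: dict[str, list[TrueEvent]] = {lid: [] for lid, _ in truth.roster}
    for e in truth.events:
        events_by_line[e.line_id].append(e)

    artifact_cn: dict[str, list[tuple[GenomicInterval, float]]] = {
        lid: [] for lid, _ in truth.roster
    }
    for iv, svtype, lines, kind in truth.artifact_regions:
        if kind != "recurrent":
            continue  # spurious calls get no depth signal
        value = 0.35 if svtype == "DEL" else 1.80
        for lid in lines:
            artifact_cn[lid].append((iv, value))

    profiles: dict[str, DepthProfile] = {}
    calls: list[CNVCall] = []
    for lid, _T in truth.roster:
        regions = [
            (e.interval, 0.0 if e.svtype == "DEL" else 2.0)
            for e in events_by_line[lid]
        ] + artifact_cn[lid]
        windows: dict[str, np.ndarray] = {}
        for chrom, clen in genome.chromosomes:
            track = _copy_number_track(clen, config.depth_window, [
                (iv, v) for iv, v in regions if iv.chrom == chrom
            ])
            depth = rng.poisson(np.maximum(track[:, 2], 0.0) * config.mean_depth)
            windows[chrom] = np.column_stack([track[:, 0], track[:, 1], depth])
        profiles[lid] = DepthProfile(lid, windows, mapq_floor=config.mapq_floor)

        for e in events_by_line[lid]:
            for caller in ("cnvnator", "manta", "delly"):
                if rng.random() >= config.sensitivity(caller):
                    continue
                iv = e.interval
                if jitter:
                    clen = genome.chrom_length(iv.chrom)
                    start = int(np.clip(iv.start + rng.integers(-jitter, jitter + 1),
                                        0, clen - 1))
                    end = int(np.clip(iv.end + rng.integers(-jitter, jitter + 1),
                                      start + 1, clen))
                    iv = GenomicInterval(iv.chrom, start, end)
                ratio = None
                if caller == "cnvnator":
                    ratio = profiles[lid].depth_ratio(iv)
                calls.append(
                    CNVCall(
                        line_id=lid,
                        interval=iv,
                        svtype=e.svtype,
                        caller=caller,
                        depth_ratio=ratio,
                        read_support=(10, 12) if caller != "cnvnator" else None,
                    )
                )
    calls.extend(truth.artifact_calls)
    calls.sort(key=lambda c: (c.line_id, c.interval.chrom, c.interval.start, c.caller))

    if outdir is not None:
        _write_emulated(calls, profiles, genome, Path(outdir))
    return calls, profiles


def _write_emulated(
    calls: list[CNVCall],
    profiles: dict[str, DepthProfile],
    genome: GenomeIndex,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = "".join(
        f"##contig=<ID={c},length={n}>\n" for c, n in genome.chromosomes
    )
    header = (
        "##fileformat=VCFv4.2\n"
        + contigs
        + '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n'
        '##INFO=<ID=PE,Number=1,Type=Integer,Description="Discordant pairs">\n'
        '##INFO=<ID=SR,Number=1,Type=Integer,Description="Split reads">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    )
    for lid, profile in profiles.items():
        write_depth_profile(profile, outdir / f"{lid}.depth.tsv")
        by_caller: dict[str, list[CNVCall]] = {"cnvnator": [], "manta": [], "delly": []}
        for c in calls:
            if c.line_id == lid:
                by_caller.setdefault(c.caller, []).append(c)
        with open(outdir / f"{lid}.cnvnator.txt", "w") as fh:
            for c in by_caller["cnvnator"]:
                iv = c.interval
                kind = "deletion" if c.svtype == "DEL" else "duplication"
                fh.write(
                    f"{kind}\t{iv.chrom}:{iv.start + 1}-{iv.end}\t{iv.length}\t"
                    f"{0.0 if c.depth_ratio is None else c.depth_ratio:.4g}\n"
                )
        for caller in ("manta", "delly"):
            with open(outdir / f"{lid}.{caller}.vcf", "w") as fh:
                fh.write(header)
                fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                         f"{lid}\n")
                for i, c in enumerate(by_caller[caller]):
                    iv = c.interval
                    sr, pe = c.read_support or (0, 0)
                    fh.write(
                        f"{iv.chrom}\t{iv.start + 1}\t{caller}_{i}\tN\t<{c.svtype}>\t"
                        f"60\tPASS\tSVTYPE={c.svtype};END={iv.end};SR={sr};PE={pe}"
                        "\tGT\t1\n"
                    )


# ---------------------------------------------------------------------------
# packaged fixture

# (chrom, start, end, svtype, line, callers) for the 21 verified events.
_TABLE1_ROWS = (
    ("1", 1_047_500, 1_048_000, "DEL", "L14", ("cnvnator",)),
    ("1", 4_777_500, 4_785_500, "DUP", "QS50", ("cnvnator",)),
    ("1", 4_922_000, 4_924_000, "DUP", "QS50", ("cnvnator",)),
    ("2", 693_500, 699_500, "DEL", "L56", ("cnvnator",)),
    ("2", 1_555_860, 1_556_296, "DEL", "QS84", ("delly",)),
    ("2", 4_200_443, 4_201_170, "DEL", "L1", ("delly",)),
    ("2", 7_157_472, 7_159_275, "DEL", "L17", ("manta",)),
    ("2", 7_186_805, 7_193_382, "DEL", "L54", ("delly", "cnvnator")),
    ("2", 7_258_904, 7_259_805, "DEL", "L54", ("delly",)),
    ("3", 6_346_000, 6_357_000, "DEL", "L25", ("cnvnator",)),
    ("3", 2_931_000, 2_935_500, "DEL", "L3", ("cnvnator",)),
    ("3", 1_978_500, 1_982_000, "DEL", "L54", ("cnvnator",)),
    ("4", 5_439_500, 5_441_500, "DEL", "QS14", ("cnvnator",)),
    ("5", 849_500, 853_500, "DEL", "L54", ("cnvnator",)),
    ("5", 3_273_782, 3_279_844, "DEL", "QS40", ("manta",)),
    ("5", 2_608_997, 2_610_178, "DEL", "L1", ("manta",)),
    ("5", 4_803_015, 4_805_588, "DUP", "QS40", ("manta",)),
    ("5", 4_276_322, 4_277_619, "DEL", "L52", ("manta",)),
    ("5", 4_920_500, 4_925_000, "DEL", "L53", ("cnvnator",)),
    ("6", 2_886_768, 2_887_266, "DEL", "L1", ("delly", "manta")),
    ("6", 3_586_000, 3_590_000, "DEL", "QS74", ("cnvnator",)),
)


def table1_fixture() -> tuple[list[ConsensusCNV], list[tuple[str, int]]]:
    """The 21 verified events of the study plus a 37-line roster.

    The roster pairs the 14 event-bearing lines with 23 synthetic
    placeholder line ids (the study names only lines carrying events but
    sequenced 37). L-prefixed lines are assigned T=2000 and QS-prefixed
    lines T=1000, with placeholders filling the two sets to 18 and 19
    lines respectively; per-line generation numbers are not printed in the
    study's main text, so these are nominal set-level values.
    """
    events = [
        ConsensusCNV(
            line_id=line,
            interval=GenomicInterval(chrom, start, end),
            svtype=svtype,
            callers=frozenset(callers),
        )
        for chrom, start, end, svtype, line, callers in _TABLE1_ROWS
    ]
    named = []
    for _, _, _, _, line, _ in _TABLE1_ROWS:
        if line not in named:
            named.append(line)
    roster = [(lid, 2000 if lid.startswith("L") else 1000) for lid in named]
    n_named_l = sum(1 for lid, T in roster if T == 2000)   # 9
    n_named_qs = len(roster) - n_named_l                   # 5
    placeholders = [f"U{i:02d}" for i in range(1, 37 - len(roster) + 1)]
    # fill the T=1000 set to 19 lines and the T=2000 set to 18
    need_1000 = 19 - n_named_qs
    for i, lid in enumerate(placeholders):
        roster.append((lid, 1000 if i < need_1000 else 2000))
    return events, roster
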