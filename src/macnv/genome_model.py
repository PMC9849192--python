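"""Reference genome and gene annotation model.

All coordinates inside the package are 0-based half-open. GFF3 input
(1-based, inclusive) is converted on load; BED input is taken as-is.
Strand is carried on gene records but ignored by every computation:
deletions and duplications are unstranded events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pyfaidx
import pyranges

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "GenomeIndex",
    "GenomeModelError",
    "load_genome",
    "load_annotation",
    "at_fraction",
    "write_annotation_bed",
]

#: IUPAC nucleotide alphabet (upper case); anything else is rejected on load.
IUPAC = set("ACGTRYSWKMBDHVN")

#: Unambiguous bases counted by composition statistics.
_AT = set("AT")
_GC = set("GC")

BIOTYPES = ("protein_coding", "tRNA", "other")


class GenomeModelError(ValueError):
    """Raised for malformed genomes, annotations or out-of-bounds queries."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise GenomeModelError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open touch is not overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its interval, strand and coarse biotype."""

    gene_id: str
    interval: GenomicInterval
    strand: str = "."
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise GenomeModelError(
                f"gene {self.gene_id}: biotype {self.biotype!r} not in {BIOTYPES}"
            )
        if self.strand not in ("+", "-", "."):
            raise GenomeModelError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class GenomeIndex:
    """Indexed random access to a multi-record FASTA.

    Wraps :class:`pyfaidx.Fasta`; sequence is returned upper-cased so
    composition statistics are case-insensitive.
    """

    def __init__(self, fasta: pyfaidx.Fasta):
        self._fasta = fasta
        self.chromosomes: list[tuple[str, int]] = [
            (name, len(rec)) for name, rec in fasta.items()
        ]
        self._lengths = dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def chrom_length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise GenomeModelError(f"unknown chromosome {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end), upper case; exactly end - start characters."""
        n = self.chrom_length(chrom)
        if not (0 <= start < end <= n):
            raise GenomeModelError(
                f"query {chrom}:{start}-{end} outside chromosome bounds (length {n})"
            )
        return str(self._fasta[chrom][start:end]).upper()

    def fetch_interval(self, interval: GenomicInterval) -> str:
        return self.fetch(interval.chrom, interval.start, interval.end)

    def bounds_check(self, interval: GenomicInterval) -> None:
        if interval.end > self.chrom_length(interval.chrom):
            raise GenomeModelError(
                f"interval {interval} exceeds chromosome length "
                f"{self.chrom_length(interval.chrom)}"
            )


def load_genome(fasta_path: str | Path) -> GenomeIndex:
    """Load and index a FASTA file.

    Rejects empty files, duplicated sequence names and non-IUPAC characters
    with :class:`GenomeModelError`.
    """
    path = Path(fasta_path)
    names: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                names.append(line[1:].split()[0])
    if not names:
        raise GenomeModelError(f"{path}: no FASTA records found")
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise GenomeModelError(f"{path}: duplicate sequence name(s): {dup}")
    fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True, rebuild=True)
    for name, rec in fasta.items():
        bad = set(str(rec[:])) - IUPAC
        if bad:
            raise GenomeModelError(
                f"{path}: sequence {name} contains non-IUPAC characters {sorted(bad)}"
            )
    return GenomeIndex(fasta)


def _biotype_of(raw: object) -> str:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return "protein_coding"
    raw = str(raw)
    if raw in ("protein_coding", "mRNA", "CDS", "."):
        return "protein_coding"
    if raw in ("tRNA", "trna"):
        return "tRNA"
    return "other"


def load_annotation(
    path: str | Path,
    fmt: str | None = None,
    genome: GenomeIndex | None = None,
) -> list[GeneRecord]:
    """Read gene records from GFF3 (gene features) or BED6(+biotype).

    GFF3 coordinates (1-based inclusive) become 0-based half-open; BED is
    used unchanged. A BED line may carry the biotype in column 7. When a
    *genome* is given, genes extending beyond their chromosome are rejected.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    if fmt == "gff3":
        df = pyranges.read_gff3(str(path)).df
        df = df[df.Feature == "gene"]
        bio_col = next(
            (c for c in ("biotype", "gene_biotype", "gene_type") if c in df.columns),
            None,
        )
        genes = []
        for row in df.itertuples(index=False):
            gene_id = getattr(row, "ID", None) or getattr(row, "gene_id", None)
            genes.append(
                GeneRecord(
                    gene_id=str(gene_id),
                    interval=GenomicInterval(str(row.Chromosome), int(row.Start), int(row.End)),
                    strand=str(row.Strand) if str(row.Strand) in "+-" else ".",
                    biotype=_biotype_of(getattr(row, bio_col) if bio_col else None),
                )
            )
    elif fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 4:
            raise GenomeModelError(f"{path}: BED needs at least 4 columns")
        for col in range(df.shape[1], 7):  # pad optional score/strand/biotype
            df[col] = "." if col < 6 else None
        genes = [
            GeneRecord(
                gene_id=str(row[3]),
                interval=GenomicInterval(str(row[0]), int(row[1]), int(row[2])),
                strand=str(row[5]) if str(row[5]) in "+-" else ".",
                biotype=_biotype_of(row[6]),
            )
            for row in df.itertuples(index=False, name=None)
        ]
    else:
        raise GenomeModelError(f"unknown annotation format {fmt!r}")

    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise GenomeModelError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
        if genome is not None:
            genome.bounds_check(g.interval)
    return genes


def write_annotation_bed(genes: list[GeneRecord], path: str | Path) -> None:
    """Write genes as BED6 + biotype column (the format load_annotation reads)."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t.\t{g.strand}\t{g.biotype}\n"
            )


def at_fraction(genome: GenomeIndex, interval: GenomicInterval) -> float:
    """%AT of an interval: (#A + #T) / (#A + #T + #G + #C).

    Ambiguity codes (N etc.) are excluded from both numerator and
    denominator so assembly gaps do not bias composition. Returns NaN when
    the interval contains no unambiguous base.
    """
    genome.bounds_check(interval)
    seq = genome.fetch_interval(interval)
    at = sum(seq.count(b) for b in _AT)
    gc = sum(seq.count(b) for b in _GC)
    if at + gc == 0:
        return math.nan
    return at / (at + gc)
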