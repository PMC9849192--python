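"""Ingestion of heterogeneous CNV-caller outputs and result serialization.

Three caller dialects are supported: VCF 4.x with SVTYPE/END INFO keys
(Manta- and Delly-style structural variant output, read through pysam) and
CNVnator's tab-delimited text (canonical 9-column or a minimal 4-column
variant). Everything is normalized to :class:`CNVCall` with 0-based
half-open coordinates: VCF POS (1-based) becomes start = POS - 1, and a
CNVnator ``chrom:start-end`` region (1-based inclusive) becomes
(start - 1, end).

Only deletions and duplications are retained; calls of any other SV type
(INS, INV, BND, ...) are dropped at ingestion with a logged warning, since
the downstream analysis is defined for copy-number losses and gains only.
One caller file corresponds to one mutation-accumulation (MA) line;
multi-sample VCFs are rejected.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome_model import GenomicInterval

__all__ = [
    "CNVCall",
    "DepthProfile",
    "CnvIOError",
    "read_caller_output",
    "read_depth_profile",
    "write_depth_profile",
    "write_calls",
    "read_calls_tsv",
]

logger = logging.getLogger(__name__)

CALLERS = ("cnvnator", "manta", "delly", "other")
SVTYPES = ("DEL", "DUP")

_MUTATION_LABEL = {"DEL": "Deletion", "DUP": "Duplication"}
_LABEL_MUTATION = {v: k for k, v in _MUTATION_LABEL.items()}


class CnvIOError(ValueError):
    """Raised for malformed caller output or depth profiles."""


@dataclass(frozen=True)
class CNVCall:
    """One caller's deletion or duplication call in one MA line."""

    line_id: str
    interval: GenomicInterval
    svtype: str
    caller: str
    depth_ratio: float | None = None
    qual: float | None = None
    read_support: tuple[int, int] | None = None  # (n_split, n_discordant)

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise CnvIOError(f"svtype {self.svtype!r} not in {SVTYPES}")
        if self.caller not in CALLERS:
            raise CnvIOError(f"caller {self.caller!r} not in {CALLERS}")
        if self.depth_ratio is not None and self.depth_ratio < 0:
            raise CnvIOError(f"negative depth_ratio {self.depth_ratio}")

    @property
    def length(self) -> int:
        return self.interval.length


class DepthProfile:
    """Windowed read-depth track for one MA line.

    Windows must tile each chromosome contiguously (no overlap, no gap);
    the line mean is the length-weighted mean depth over all windows.
    ``mapq_floor`` records the mapping-quality threshold the alignments
    were filtered at before counting depth.
    """

    def __init__(
        self,
        line_id: str,
        windows: dict[str, np.ndarray],
        mapq_floor: int = 20,
    ):
        self.line_id = line_id
        self.windows = {c: np.asarray(w, dtype=float) for c, w in windows.items()}
        self.mapq_floor = mapq_floor
        total = 0.0
        weight = 0.0
        for chrom, w in self.windows.items():
            if w.ndim != 2 or w.shape[1] != 3:
                raise CnvIOError(f"{line_id}/{chrom}: windows must be (start, end, depth)")
            self._check_tiling(chrom, w)
            spans = w[:, 1] - w[:, 0]
            total += float(np.sum(spans * w[:, 2]))
            weight += float(np.sum(spans))
        if weight == 0:
            raise CnvIOError(f"{line_id}: empty depth profile")
        self.line_mean_depth = total / weight
        if self.line_mean_depth <= 0:
            raise CnvIOError(f"{line_id}: line mean depth must be positive")

    @staticmethod
    def _check_tiling(chrom: str, w: np.ndarray) -> None:
        order = np.argsort(w[:, 0], kind="stable")
        w[:] = w[order]
        if np.any(w[:, 1] <= w[:, 0]):
            i = int(np.argmax(w[:, 1] <= w[:, 0]))
            raise CnvIOError(f"{chrom}: empty window at index {i}: {w[i, :2]}")
        gaps = w[1:, 0] - w[:-1, 1]
        if np.any(gaps < 0):
            i = int(np.argmax(gaps < 0)) + 1
            raise CnvIOError(
                f"{chrom}: overlapping windows at {int(w[i, 0])}-{int(w[i, 1])}"
            )
        if np.any(gaps > 0):
            i = int(np.argmax(gaps > 0)) + 1
            raise CnvIOError(f"{chrom}: gap before window {int(w[i, 0])}-{int(w[i, 1])}")

    def mean_depth(self, interval: GenomicInterval) -> float:
        """Length-weighted mean depth of windows overlapping *interval*."""
        if interval.chrom not in self.windows:
            raise CnvIOError(
                f"{self.line_id}: no depth windows on chromosome {interval.chrom}"
            )
        w = self.windows[interval.chrom]
        lo = np.clip(w[:, 0], interval.start, interval.end)
        hi = np.clip(w[:, 1], interval.start, interval.end)
        spans = hi - lo
        total_span = float(np.sum(spans))
        if total_span == 0:
            raise CnvIOError(
                f"{self.line_id}: interval {interval} not covered by any window"
            )
        return float(np.sum(spans * w[:, 2]) / total_span)

    def depth_ratio(self, interval: GenomicInterval) -> float:
        """Mean depth in *interval* divided by the line mean (the depth ratio)."""
        return self.mean_depth(interval) / self.line_mean_depth


def read_caller_output(path: str | Path, caller: str, line_id: str) -> list[CNVCall]:
    """Parse one caller's output file for one MA line into normalized calls."""
    if caller not in CALLERS:
        raise CnvIOError(f"caller {caller!r} not in {CALLERS}")
    path = Path(path)
    if caller == "cnvnator":
        return _read_cnvnator(path, line_id)
    return _read_sv_vcf(path, caller, line_id)


def _read_sv_vcf(path: Path, caller: str, line_id: str) -> list[CNVCall]:
    calls: list[CNVCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        if len(vcf.header.samples) > 1:
            raise CnvIOError(
                f"{path}: multi-sample VCF ({len(vcf.header.samples)} samples); "
                "one file must describe one MA line"
            )
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype not in SVTYPES:
                logger.warning(
                    "%s: skipping %s record at %s:%s (SV type out of scope)",
                    path.name, svtype, rec.chrom, rec.pos,
                )
                continue
            # pysam folds END into rec.stop; a symbolic SV record without an
            # explicit END falls back to POS + len(REF), i.e. a 1 bp span.
            if rec.stop - rec.start <= len(rec.ref) and rec.alts and rec.alts[0].startswith("<"):
                raise CnvIOError(
                    f"{path}: record at {rec.chrom}:{rec.pos} lacks INFO/END"
                )
            def _info(key):
                try:  # pysam raises if the key is absent from the header
                    return rec.info.get(key, None)
                except (KeyError, ValueError):
                    return None

            n_split = _info("SR")
            n_disc = _info("PE")
            support = None
            if n_split is not None or n_disc is not None:
                def _first(v):
                    if v is None:
                        return 0
                    return int(v[0]) if isinstance(v, tuple) else int(v)
                support = (_first(n_split), _first(n_disc))
            calls.append(
                CNVCall(
                    line_id=line_id,
                    interval=GenomicInterval(rec.chrom, rec.start, rec.stop),
                    svtype=svtype,
                    caller=caller,
                    qual=float(rec.qual) if rec.qual is not None else None,
                    read_support=support,
                )
            )
    return calls


_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")
_CNVNATOR_TYPE = {"deletion": "DEL", "duplication": "DUP"}


def _read_cnvnator(path: Path, line_id: str) -> list[CNVCall]:
    calls: list[CNVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CnvIOError(
                    f"{path}:{lineno}: expected >= 4 tab-separated columns"
                )
            cnv_type, region, _size, norm_depth = fields[:4]
            if cnv_type not in _CNVNATOR_TYPE:
                logger.warning(
                    "%s:%d: skipping CNV type %r (out of scope)", path.name, lineno, cnv_type
                )
                continue
            m = _REGION_RE.match(region)
            if not m:
                raise CnvIOError(f"{path}:{lineno}: malformed region {region!r}")
            start = int(m["start"]) - 1  # 1-based inclusive -> 0-based half-open
            end = int(m["end"])
            calls.append(
                CNVCall(
                    line_id=line_id,
                    interval=GenomicInterval(m["chrom"], start, end),
                    svtype=_CNVNATOR_TYPE[cnv_type],
                    caller="cnvnator",
                    depth_ratio=float(norm_depth),
                )
            )
    return calls


_TSV_COLUMNS = [
    "Chromosome", "Start", "End", "Length", "Mutation", "MA Line", "Calling Program",
]


def _caller_label(callers) -> str:
    order = {c: i for i, c in enumerate(CALLERS)}
    names = sorted(set(callers), key=lambda c: order.get(c, 99))
    return " & ".join(n.capitalize() if n != "cnvnator" else "CNVnator" for n in names)


def _parse_caller_label(label: str) -> tuple[str, ...]:
    return tuple(part.strip().lower() for part in label.split("&"))


def write_calls(calls, path: str | Path, fmt: str = "tsv") -> None:
    """Serialize calls (CNVCall or ConsensusCNV) as BED or a summary TSV.

    The TSV reproduces the canonical per-event table layout: Chromosome,
    Start, End, Length, Mutation, MA Line, Calling Program (multi-caller
    events joined with " & ").
    """
    rows = []
    for c in calls:
        iv = c.interval
        callers = getattr(c, "callers", None) or (c.caller,)
        rows.append(
            {
                "Chromosome": iv.chrom,
                "Start": iv.start,
                "End": iv.end,
                "Length": iv.length,
                "Mutation": _MUTATION_LABEL[c.svtype],
                "MA Line": c.line_id,
                "Calling Program": _caller_label(callers),
            }
        )
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        bed = df[["Chromosome", "Start", "End"]].copy()
        bed["name"] = [
            f"{r['Mutation']}|{r['MA Line']}|{r['Calling Program']}" for r in rows
        ]
        bed.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise CnvIOError(f"unknown output format {fmt!r}")


def read_calls_tsv(path: str | Path):
    """Read a summary TSV written by :func:`write_calls` back into consensus events."""
    from .consensus_filter import ConsensusCNV  # deferred: avoids import cycle

    df = pd.read_csv(path, sep="\t")
    events = []
    for row in df.to_dict("records"):
        iv = GenomicInterval(str(row["Chromosome"]), int(row["Start"]), int(row["End"]))
        if iv.length != int(row["Length"]):
            raise CnvIOError(
                f"{path}: length column {row['Length']} != end - start {iv.length}"
            )
        events.append(
            ConsensusCNV(
                line_id=str(row["MA Line"]),
                interval=iv,
                svtype=_LABEL_MUTATION[str(row["Mutation"])],
                callers=frozenset(_parse_caller_label(str(row["Calling Program"]))),
            )
        )
    return events


def read_depth_profile(
    path: str | Path, line_id: str, mapq_floor: int = 20
) -> DepthProfile:
    """Read a bedGraph-like TSV (chrom, start, end, depth) into a DepthProfile."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "depth"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        raise CnvIOError(f"{path}: empty depth profile") from None
    if df.empty:
        raise CnvIOError(f"{path}: empty depth profile")
    windows = {
        str(chrom): grp[["start", "end", "depth"]].to_numpy(dtype=float)
        for chrom, grp in df.groupby("chrom", sort=True)
    }
    return DepthProfile(line_id=line_id, windows=windows, mapq_floor=mapq_floor)


def write_depth_profile(profile: DepthProfile, path: str | Path) -> None:
    """Write a DepthProfile as the bedGraph-like TSV read_depth_profile reads."""
    with open(path, "w") as fh:
        for chrom in sorted(profile.windows):
            for start, end, depth in profile.windows[chrom]:
                fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{depth:g}\n")
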