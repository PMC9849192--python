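"""Human-readable result tables, JSON reports and run manifests.

Reports are plain TSV/JSON: the per-event table (chromosome, coordinates,
length, mutation type, MA line, calling program), per-line gene-CNV counts
by class, the rate summary, composition tests and permutation results.
Every report directory carries a manifest (command, config snapshot, input
hashes, seeds, version, timestamp) sufficient to reproduce every number.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .composition import CompositionSet
from .consensus_filter import ConsensusCNV
from .cnv_io import write_calls
from .gene_rates import GeneCNVEvent, RateSummary
from .ssr_resampling import PermutationResult

__all__ = [
    "RunManifest",
    "per_line_gene_counts",
    "rates_table",
    "composition_table",
    "permutation_report",
    "render_report",
]

GENE_CLASS_COLUMNS = [
    "del_complete", "del_partial", "dup_complete", "dup_partial",
]


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None
    input_hashes: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @staticmethod
    def hash_file(path: str | Path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        return h.hexdigest()

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def per_line_gene_counts(
    events: Sequence[GeneCNVEvent],
    line_roster: Sequence[tuple[str, float]],
) -> pd.DataFrame:
    """Per-line counts of complete/partial gene deletions and duplications."""
    rows = []
    for lid, _T in line_roster:
        row = {"line_id": lid}
        for col in GENE_CLASS_COLUMNS:
            sv = "DEL" if col.startswith("del") else "DUP"
            cls = col.split("_")[1]
            row[col] = sum(
                1
                for e in events
                if e.line_id == lid and e.svtype == sv and e.overlap_class == cls
            )
        row["total"] = sum(row[c] for c in GENE_CLASS_COLUMNS)
        rows.append(row)
    return pd.DataFrame(rows)


def rates_table(summaries: Sequence[RateSummary]) -> pd.DataFrame:
    rows = [
        {
            "category": s.category,
            "total_m": sum(r.m for r in s.records),
            "mean_mu": s.mean_mu,
            "pooled_mu": s.pooled_mu,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def composition_table(
    sets: dict[str, CompositionSet],
    tests: dict[tuple[str, str], tuple[float, float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary of each %AT sample and the pairwise rank-sum tests."""
    import numpy as np

    summary = pd.DataFrame(
        [
            {
                "label": s.label,
                "n": len(s.values),
                "mean_at": float(np.mean(s.values)) if len(s.values) else math.nan,
                "median_at": float(np.median(s.values)) if len(s.values) else math.nan,
            }
            for s in sets.values()
        ]
    )
    pairs = pd.DataFrame(
        [
            {"set1": a, "set2": b, "U": U, "p": p}
            for (a, b), (U, p) in tests.items()
        ]
    )
    return summary, pairs


def permutation_report(results: Sequence[PermutationResult]) -> list[dict]:
    import numpy as np

    out = []
    for r in results:
        q = np.quantile(r.null_values, [0.025, 0.25, 0.5, 0.75, 0.975])
        out.append(
            {
                "statistic": r.statistic_name,
                "observed": r.observed,
                "N": r.N,
                "seed": r.seed,
                "percentile": r.percentile,
                "p_lower": r.p_lower,
                "p_upper": r.p_upper,
                "null_quantiles": {
                    "q025": q[0], "q25": q[1], "median": q[2],
                    "q75": q[3], "q975": q[4],
                },
            }
        )
    return out


def render_report(
    outdir: str | Path,
    manifest: RunManifest,
    cnvs: Sequence[ConsensusCNV] | None = None,
    gene_events: Sequence[GeneCNVEvent] | None = None,
    line_roster: Sequence[tuple[str, float]] | None = None,
    rate_summaries: Sequence[RateSummary] | None = None,
    composition_sets: dict[str, CompositionSet] | None = None,
    composition_tests: dict | None = None,
    permutations: Sequence[PermutationResult] | None = None,
) -> dict:
    """Write all available stage outputs under *outdir*; gaps are explicit.

    Returns the combined JSON-serializable report (also written as
    report.json next to the manifest).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "sections": {}}
    # stages accumulate into one report: merge sections already on disk
    existing = outdir / "report.json"
    if existing.exists():
        try:
            report["sections"].update(json.loads(existing.read_text())["sections"])
        except (json.JSONDecodeError, KeyError):
            pass

    if cnvs is not None:
        write_calls(cnvs, outdir / "consensus_cnvs.tsv", fmt="tsv")
        from .gene_rates import summarize_lengths

        ls = summarize_lengths(cnvs)
        report["sections"]["cnvs"] = {
            "n_deletions": ls.n_del,
            "n_duplications": ls.n_dup,
            "mean_deletion_length_bp": None if math.isnan(ls.mean_len_del) else round(ls.mean_len_del),
            "mean_duplication_length_bp": None if math.isnan(ls.mean_len_dup) else round(ls.mean_len_dup),
        }
    else:
        report["sections"].setdefault("cnvs", None)

    if gene_events is not None and line_roster is not None:
        counts = per_line_gene_counts(gene_events, line_roster)
        counts.to_csv(outdir / "per_line_gene_cnv_counts.tsv", sep="\t", index=False)
        report["sections"]["per_line_counts"] = counts.to_dict("records")
    else:
        report["sections"].setdefault("per_line_counts", None)

    if rate_summaries is not None:
        rt = rates_table(rate_summaries)
        rt.to_csv(outdir / "rates.tsv", sep="\t", index=False)
        report["sections"]["rates"] = rt.to_dict("records")
    else:
        report["sections"].setdefault("rates", None)

    if composition_sets is not None:
        summary, pairs = composition_table(composition_sets, composition_tests or {})
        summary.to_csv(outdir / "composition_summary.tsv", sep="\t", index=False)
        pairs.to_csv(outdir / "composition_tests.tsv", sep="\t", index=False)
        report["sections"]["composition"] = {
            "summary": summary.to_dict("records"),
            "tests": pairs.to_dict("records"),
        }
    else:
        report["sections"].setdefault("composition", None)

    if permutations is not None:
        report["sections"]["permutations"] = permutation_report(permutations)
        with open(outdir / "permutations.json", "w") as fh:
            json.dump(report["sections"]["permutations"], fh, indent=2)
            fh.write("\n")
    else:
        report["sections"].setdefault("permutations", None)

    manifest.write(outdir / "manifest.json")
    report["manifest"] = asdict(manifest)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return report
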