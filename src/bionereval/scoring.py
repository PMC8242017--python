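"""Composite scoring and ranking of NER tools.

Each tool has one overlap z-score per reference network and one coincidence
z-score per classification system.  Within every column (reference or
system), z-scores are min–max-normalized across tools; the per-tool mean of
the normalized overlap columns and of the normalized coincidence columns are
averaged, with equal weight by default, into a composite in [0, 1].  Tools
are ranked by descending composite; ties share the minimum rank.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .communities import CoincidenceResult
from .errors import DomainError, ValidationError
from .overlap import OverlapResult
from .significance import minmax_normalize

__all__ = [
    "ToolEvaluation",
    "aggregate_evaluations",
    "render_report",
    "read_report",
]


@dataclass
class ToolEvaluation:
    """Normalized overlap/coincidence scores and composite rank for one tool."""

    tool_id: str
    overlap_z: dict[str, float]
    coincidence_z: dict[str, float]
    norm_overlap: dict[str, float] = field(default_factory=dict)
    norm_coincidence: dict[str, float] = field(default_factory=dict)
    norm_overlap_mean: float = math.nan
    norm_coincidence_mean: float = math.nan
    composite: float = math.nan
    rank: int = 0


def _to_z_table(results: Iterable, kind: str) -> pd.DataFrame:
    """Coerce result objects (or (tool, column, z) triples) to a tidy z table."""
    rows = []
    for r in results:
        if isinstance(r, OverlapResult):
            rows.append((r.phenotypic_id, r.reference_id, r.z.z if r.z else math.nan))
        elif isinstance(r, CoincidenceResult):
            rows.append((r.network_id, r.system_id, r.z.z if r.z else math.nan))
        else:
            tool, column, z = r
            rows.append((str(tool), str(column), float(z)))
    if not rows:
        raise DomainError(f"no {kind} results to aggregate")
    df = pd.DataFrame(rows, columns=["tool", "column", "z"])
    if df.duplicated(["tool", "column"]).any():
        raise ValidationError(f"duplicate {kind} entries per (tool, column)")
    return df


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise min–max normalization of the tool × column z matrix.

    Infinite z sentinels (zero-sd nulls) are clipped to the finite extremes of
    their column before normalizing, so they land exactly on 0 or 1.
    """
    wide = df.pivot(index="tool", columns="column", values="z")
    na = wide.isna()
    if na.any().any():
        missing = [
            f"tool {t!r}, column {c!r}" for (t, c), v in na.stack().items() if v
        ]
        raise ValidationError("missing z-score for " + "; ".join(missing))
    norm = {}
    for col in wide.columns:
        x = wide[col].to_numpy(dtype=float)
        finite = x[np.isfinite(x)]
        if finite.size:
            lo, hi = finite.min(), finite.max()
            x = np.clip(x, lo, hi)
        else:
            x = np.zeros_like(x)
        norm[col] = minmax_normalize(x)
    return pd.DataFrame(norm, index=wide.index)


def aggregate_evaluations(
    overlaps: Iterable,
    coincidences: Iterable,
) -> list[ToolEvaluation]:
    """Combine overlap and coincidence z-scores into ranked composites.

    ``overlaps``/``coincidences`` are :class:`OverlapResult` /
    :class:`CoincidenceResult` objects (or plain ``(tool, column, z)``
    triples).  Every tool must have a z-score for every column; a missing
    cell raises naming the tool and column.
    """
    odf = _to_z_table(overlaps, "overlap")
    cdf = _to_z_table(coincidences, "coincidence")
    tools = sorted(set(odf.tool) | set(cdf.tool))
    for df, kind in ((odf, "overlap"), (cdf, "coincidence")):
        present = set(df.tool)
        if present != set(tools):
            absent = sorted(set(tools) - present)
            raise ValidationError(f"tools missing all {kind} scores: {absent}")
    onorm = _normalize_columns(odf)
    cnorm = _normalize_columns(cdf)
    evals = []
    for tool in tools:
        o_mean = float(onorm.loc[tool].mean())
        c_mean = float(cnorm.loc[tool].mean())
        evals.append(
            ToolEvaluation(
                tool_id=tool,
                overlap_z=dict(odf[odf.tool == tool].set_index("column")["z"]),
                coincidence_z=dict(cdf[cdf.tool == tool].set_index("column")["z"]),
                norm_overlap=dict(onorm.loc[tool]),
                norm_coincidence=dict(cnorm.loc[tool]),
                norm_overlap_mean=o_mean,
                norm_coincidence_mean=c_mean,
                composite=(o_mean + c_mean) / 2.0,
            )
        )
    composites = pd.Series({e.tool_id: e.composite for e in evals})
    ranks = composites.rank(method="min", ascending=False).astype(int)
    for e in evals:
        e.rank = int(ranks[e.tool_id])
    evals.sort(key=lambda e: (e.rank, e.tool_id))
    return evals


def evaluations_to_frame(evals: list[ToolEvaluation]) -> pd.DataFrame:
    rows = []
    for e in evals:
        row: dict[str, object] = {"tool": e.tool_id, "rank": e.rank,
                                  "composite": e.composite,
                                  "norm_overlap_mean": e.norm_overlap_mean,
                                  "norm_coincidence_mean": e.norm_coincidence_mean}
        for col, z in sorted(e.overlap_z.items()):
            row[f"overlap_z[{col}]"] = z
        for col, z in sorted(e.coincidence_z.items()):
            row[f"coincidence_z[{col}]"] = z
        for col, v in sorted(e.norm_overlap.items()):
            row[f"norm_overlap[{col}]"] = v
        for col, v in sorted(e.norm_coincidence.items()):
            row[f"norm_coincidence[{col}]"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(
    evals: list[ToolEvaluation],
    out_dir: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write the evaluation as TSV + JSON (+ scatter data for a score plot).

    The TSV rows follow rank order.  The JSON carries every intermediate
    z-score and normalized score plus run metadata (seeds, n_reps, config),
    enough to reproduce the ranking.  ``scatter.csv`` holds the
    (norm_overlap_mean, norm_coincidence_mean) coordinates per tool.
    """
    if not evals:
        raise DomainError("nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = evaluations_to_frame(evals)
    tsv = out_dir / "evaluation.tsv"
    frame.to_csv(tsv, sep="\t", index=False)
    payload = {
        "metadata": dict(metadata or {}),
        "tools": [
            {
                "tool_id": e.tool_id,
                "rank": e.rank,
                "composite": e.composite,
                "norm_overlap_mean": e.norm_overlap_mean,
                "norm_coincidence_mean": e.norm_coincidence_mean,
                "overlap_z": e.overlap_z,
                "coincidence_z": e.coincidence_z,
                "norm_overlap": e.norm_overlap,
                "norm_coincidence": e.norm_coincidence,
            }
            for e in evals
        ],
    }
    js = out_dir / "evaluation.json"
    js.write_text(json.dumps(payload, indent=2, default=float))
    scatter = out_dir / "scatter.csv"
    frame[["tool", "norm_overlap_mean", "norm_coincidence_mean", "composite"]].to_csv(
        scatter, index=False
    )
    return {"tsv": tsv, "json": js, "scatter": scatter}


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back the TSV written by :func:`render_report`."""
    return pd.read_csv(path, sep="\t")
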