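"""Study-level report assembly from persisted benchmark artifacts.

Aggregates only what is on disk: per-seed metric rows roll up into
mean +/- standard-deviation summaries (the error-bar convention for all
multi-split results), prediction sets are inventoried, and any configured
cell without an artifact surfaces as an explicit gap rather than a silent
omission.  Reports are data-first (JSON/CSV); rendering plots is the
caller's business.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["StudyReport", "build_report", "summarize_metrics"]


@dataclass
class StudyReport:
    """Aggregated tables for one benchmark run."""

    metric_summary: pd.DataFrame  # mean/std/n_seeds per (dataset, model, repr, method, subset, metric)
    prediction_inventory: pd.DataFrame  # one row per persisted prediction set
    gaps: list[dict] = field(default_factory=list)
    ac_summary: Optional[dict] = None
    extras: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "metric_summary": self.metric_summary.to_dict(orient="records"),
            "prediction_inventory": self.prediction_inventory.to_dict(orient="records"),
            "gaps": self.gaps,
            "ac_summary": self.ac_summary,
            "extras": self.extras,
        }
        path.write_text(json.dumps(payload, indent=2))
        self.metric_summary.to_csv(path.with_suffix(".metrics.csv"), index=False)


_GROUP_COLS = ["dataset", "model", "representation", "method", "subset", "metric"]


def summarize_metrics(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Per-seed metric rows -> mean, std (ddof=1), and seed count.

    Undefined metric values (None) are excluded from the aggregation but
    counted, so a metric that was undefined on some seeds is visible.
    """
    df = metric_table.copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    grouped = df.groupby(_GROUP_COLS, dropna=False)["value"]
    out = grouped.agg(
        mean="mean",
        std=lambda v: v.std(ddof=1),
        n_seeds="count",
        n_undefined=lambda v: int(v.isna().sum()),
    ).reset_index()
    return out


def build_report(artifact_dir: str | Path) -> StudyReport:
    """Assemble a report from a benchmark artifact directory.

    Expects the layout written by :func:`molbench.models.run_benchmark`:
    ``metrics.csv`` plus ``pred_*.csv``/``pred_*.json`` pairs, and
    optionally ``*.summary.json`` cliff summaries.  A prediction file whose
    sidecar is missing (or vice versa) is reported as a gap.
    """
    artifact_dir = Path(artifact_dir)
    if not artifact_dir.is_dir() or not any(artifact_dir.iterdir()):
        raise FileNotFoundError(f"no artifacts in {artifact_dir}")

    gaps: list[dict] = []
    inventory_rows: list[dict] = []
    for csv_path in sorted(artifact_dir.glob("pred_*.csv")):
        sidecar = csv_path.with_suffix(".json")
        if not sidecar.exists():
            gaps.append({"artifact": csv_path.name, "problem": "missing provenance sidecar"})
            continue
        meta = json.loads(sidecar.read_text())
        meta["artifact"] = csv_path.name
        meta.pop("provenance", None)
        inventory_rows.append(meta)
    for sidecar in sorted(artifact_dir.glob("pred_*.json")):
        if not sidecar.with_suffix(".csv").exists():
            gaps.append({"artifact": sidecar.name, "problem": "missing prediction CSV"})

    metrics_path = artifact_dir / "metrics.csv"
    if metrics_path.exists():
        metric_table = pd.read_csv(metrics_path)
        summary = summarize_metrics(metric_table)
        # every metric row should trace back to a persisted prediction set
        if inventory_rows:
            have = {
                (r["dataset"], r["model"], r["representation"], r["method"], r["seed"])
                for r in inventory_rows
            }
            for key, _ in metric_table.groupby(
                ["dataset", "model", "representation", "method", "seed"]
            ):
                if key not in have:
                    gaps.append({"cell": list(key), "problem": "metric rows without prediction artifact"})
    else:
        summary = pd.DataFrame(columns=_GROUP_COLS + ["mean", "std", "n_seeds", "n_undefined"])
        gaps.append({"artifact": "metrics.csv", "problem": "missing metric table"})

    ac_summary = None
    for summary_path in sorted(artifact_dir.glob("*.summary.json")):
        ac_summary = json.loads(summary_path.read_text())

    return StudyReport(
        metric_summary=summary,
        prediction_inventory=pd.DataFrame(inventory_rows),
        gaps=gaps,
        ac_summary=ac_summary,
    )
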