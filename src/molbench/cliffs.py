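"""Activity-cliff and edge-case annotation.

An activity cliff is a large potency change between structurally similar
molecules.  Operationally: a scaffold whose member pIC50 values span at
least two orders of magnitude (span >= 2.0 log units, inclusive) is an AC
scaffold, and every molecule bearing it is an AC molecule.  AC status is a
dataset-level property computed on the full curated set; per-split AC
fractions derive from the split manifests afterwards.

Edge cases are molecules whose scaffold group straddles the classification
cutoff inside the 5-7 pIC50 window: binarized labels for such analog series
are fragile, since near-identical molecules get coerced into opposite
classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CuratedDataset

__all__ = [
    "ACAnnotation",
    "annotate_cliffs",
    "find_edge_cases",
    "stratify_ids",
    "ac_burden_correlation",
]


@dataclass
class ACAnnotation:
    """Per-scaffold spans/AC flags and per-molecule AC/edge flags."""

    scaffold_table: pd.DataFrame  # columns: scaffold, size, span, is_ac
    molecule_table: pd.DataFrame  # columns: id, scaffold, is_ac, is_edge
    span_threshold: float
    summary: dict = field(default_factory=dict)

    def is_ac(self, mol_id: str) -> bool:
        row = self.molecule_table.loc[self.molecule_table["id"] == mol_id]
        return bool(row["is_ac"].iloc[0])

    def ac_fraction(self, ids: Sequence[str]) -> float:
        sub = self.molecule_table.set_index("id").loc[list(ids)]
        return float(sub["is_ac"].mean())

    def edge_fraction(self, ids: Sequence[str]) -> float:
        sub = self.molecule_table.set_index("id").loc[list(ids)]
        return float(sub["is_edge"].mean())

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.scaffold_table.to_csv(prefix.with_suffix(".scaffolds.csv"), index=False)
        self.molecule_table.to_csv(prefix.with_suffix(".molecules.csv"), index=False)
        prefix.with_suffix(".summary.json").write_text(json.dumps(self.summary, indent=2))


def annotate_cliffs(
    dataset: CuratedDataset,
    span_threshold: float = 2.0,
    edge_window: tuple[float, float] = (5.0, 7.0),
    cutoff: float = 6.0,
) -> ACAnnotation:
    """Flag AC scaffolds (pIC50 span >= threshold, inclusive) and propagate to
    molecules; also annotate edge cases (see :func:`find_edge_cases`).

    Singleton scaffolds have span 0 and are never AC.  The summary block
    mirrors the usual dataset-level table: counts and percentages of AC
    scaffolds and AC molecules.
    """
    if dataset.task != "regression":
        raise ValueError("activity-cliff spans need regression (pIC50) labels")
    df = pd.DataFrame(
        {"id": dataset.ids, "scaffold": dataset.scaffolds, "pic50": dataset.labels}
    )
    grouped = df.groupby("scaffold", sort=True)["pic50"]
    scaffold_table = pd.DataFrame(
        {
            "scaffold": grouped.size().index,
            "size": grouped.size().to_numpy(),
            "span": (grouped.max() - grouped.min()).to_numpy(),
        }
    )
    scaffold_table["is_ac"] = scaffold_table["span"] >= span_threshold

    ac_scaffolds = set(scaffold_table.loc[scaffold_table["is_ac"], "scaffold"])
    edge_ids = find_edge_cases(dataset, window=edge_window, cutoff=cutoff)
    molecule_table = pd.DataFrame(
        {
            "id": df["id"],
            "scaffold": df["scaffold"],
            "is_ac": df["scaffold"].isin(ac_scaffolds),
            "is_edge": df["id"].isin(edge_ids),
        }
    )
    n_scaffolds = len(scaffold_table)
    n_molecules = len(df)
    n_ac_scaffolds = int(scaffold_table["is_ac"].sum())
    n_ac_molecules = int(molecule_table["is_ac"].sum())
    summary = {
        "n_scaffolds": n_scaffolds,
        "n_molecules": n_molecules,
        "ac_scaffolds": n_ac_scaffolds,
        "ac_scaffolds_pct": 100.0 * n_ac_scaffolds / n_scaffolds,
        "ac_molecules": n_ac_molecules,
        "ac_molecules_pct": 100.0 * n_ac_molecules / n_molecules,
        "edge_molecules": int(molecule_table["is_edge"].sum()),
        "edge_molecules_pct": 100.0 * molecule_table["is_edge"].mean(),
    }
    return ACAnnotation(
        scaffold_table=scaffold_table,
        molecule_table=molecule_table,
        span_threshold=span_threshold,
        summary=summary,
    )


def find_edge_cases(
    dataset: CuratedDataset,
    window: tuple[float, float] = (5.0, 7.0),
    cutoff: float = 6.0,
) -> set[str]:
    """Molecule ids that are edge cases under the cross-cutoff rule.

    A scaffold group is an edge group iff it has at least one member with
    pIC50 in [lo, cutoff) and at least one in [cutoff, hi]; within edge
    groups every molecule with pIC50 in [lo, hi] is flagged.  The window
    must contain the cutoff.
    """
    lo, hi = window
    if not (lo < cutoff <= hi):
        raise ValueError(f"window {window} must contain the cutoff {cutoff}")
    if dataset.task != "regression":
        raise ValueError("edge cases are defined on regression (pIC50) labels")
    df = pd.DataFrame(
        {"id": dataset.ids, "scaffold": dataset.scaffolds, "pic50": dataset.labels}
    )
    edge_ids: set[str] = set()
    for _, group in df.groupby("scaffold", sort=False):
        y = group["pic50"]
        below = ((y >= lo) & (y < cutoff)).any()
        above = ((y >= cutoff) & (y <= hi)).any()
        if below and above:
            in_window = (y >= lo) & (y <= hi)
            edge_ids.update(group.loc[in_window, "id"])
    return edge_ids


def stratify_ids(
    ids: Sequence[str],
    annotation: ACAnnotation,
) -> dict[str, list[str]]:
    """Partition prediction ids into {all, AC, nonAC, edge_removed} views.

    AC + nonAC = all; edge_removed drops edge-flagged molecules.  Unknown
    ids raise with the offending ids listed.
    """
    table = annotation.molecule_table.set_index("id")
    unknown = [i for i in ids if i not in table.index]
    if unknown:
        raise KeyError(f"ids not in annotation: {unknown[:10]}")
    sub = table.loc[list(ids)]
    return {
        "all": list(ids),
        "AC": list(sub.index[sub["is_ac"]]),
        "nonAC": list(sub.index[~sub["is_ac"]]),
        "edge_removed": list(sub.index[~sub["is_edge"]]),
    }


def ac_burden_correlation(per_split_metric, per_split_ac_fraction) -> Optional[float]:
    """Pearson correlation between a per-split metric (e.g. test RMSE) and the
    per-split AC-molecule fraction; None when either vector is constant."""
    x = np.asarray(per_split_metric, dtype=float)
    y = np.asarray(per_split_ac_fraction, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)
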