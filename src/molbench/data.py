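"""Activity-data ingestion, curation, and labelling.

Molecules arrive as SMILES strings with potency measurements in nM
(IC50/EC50/Ki/Kd).  Curation canonicalizes structures, collapses exact
duplicates, resolves or drops molecules with multiple measurements, filters
over-length SMILES, and converts potencies to the pIC50 scale
(pIC50 = 9 - log10(value in nM), so 1 uM -> 6).  Bemis-Murcko scaffolds
(ring systems plus linkers, side chains stripped) group analog series and
drive scaffold-based splitting and activity-cliff analysis downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

VALID_MEASURES = frozenset({"IC50", "EC50", "Ki", "Kd"})

__all__ = [
    "MoleculeRecord",
    "CuratedDataset",
    "CurationError",
    "canonicalize",
    "to_pic50",
    "murcko_scaffold",
    "curate",
    "binarize",
    "load_activity_csv",
]


class CurationError(ValueError):
    """Raised when curation rules cannot produce a usable dataset."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One curated molecule.

    ``smiles_length`` is counted on the raw SMILES as provided (the length
    filter mirrors fixed-width model input limits, which see the raw string).
    ``scaffold`` is the canonical Murcko framework, empty for acyclic
    molecules.
    """

    id: str
    smiles_raw: str
    smiles_canonical: str
    smiles_length: int
    scaffold: str


@dataclass
class CuratedDataset:
    """Deduplicated molecules with pIC50 (regression) or 0/1 labels.

    Invariants: one record per canonical SMILES; ``len(labels) ==
    len(molecules)``; classification labels are exactly 0/1 and ``cutoff``
    records the pIC50 threshold used.
    """

    name: str
    task: Literal["regression", "classification"]
    molecules: list[MoleculeRecord]
    labels: np.ndarray
    cutoff: float | None = None
    curation_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if len(self.labels) != len(self.molecules):
            raise ValueError("labels and molecules length mismatch")

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    @property
    def scaffolds(self) -> list[str]:
        return [m.scaffold for m in self.molecules]

    def label_of(self, mol_id: str) -> float:
        return float(self.labels[self.ids.index(mol_id)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "smiles": [m.smiles_canonical for m in self.molecules],
                "scaffold": self.scaffolds,
                "label": self.labels,
            }
        )

    def save(self, path: str | Path) -> None:
        """Write molecules as CSV plus a JSON sidecar with the curation log."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "name": self.name,
            "task": self.task,
            "cutoff": self.cutoff,
            "curation_log": self.curation_log,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def canonicalize(smiles: str) -> tuple[str, bool]:
    """Return (canonical SMILES, valid flag); never raises on bad chemistry.

    Invalid input yields ``("", False)`` so the caller can decide whether to
    drop, log, or fail.
    """
    if not smiles:
        return "", False
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return "", False
    return Chem.MolToSmiles(mol), True


def to_pic50(value_nM: float) -> float:
    """Convert a potency in nM to pIC50 = 9 - log10(value_nM)."""
    if not value_nM > 0:
        raise CurationError(f"non-positive potency: {value_nM!r}")
    return 9.0 - math.log10(value_nM)


def murcko_scaffold(smiles_canonical: str) -> str:
    """Canonical Bemis-Murcko framework; empty string for acyclic molecules."""
    mol = Chem.MolFromSmiles(smiles_canonical)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles_canonical!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def load_activity_csv(
    path: str | Path,
    value_column: str = "value",
    label_is_pic50: bool = False,
) -> pd.DataFrame:
    """Read an activity table (columns: smiles, value[, target, measure, relation]).

    Rows with a relation other than "=" are rejected at load time.  A
    benchmark-shaped file (smiles,label) loads with ``value_column="label"``
    and ``label_is_pic50=True``.
    """
    df = pd.read_csv(path)
    if "smiles" not in df.columns or value_column not in df.columns:
        raise CurationError(f"required columns missing: smiles, {value_column}")
    if "relation" in df.columns:
        bad = df["relation"] != "="
        if bad.any():
            raise CurationError(
                f"{int(bad.sum())} rows have relation != '='; only exact "
                "measurements are accepted"
            )
    if "measure" in df.columns:
        unknown = set(df["measure"].unique()) - VALID_MEASURES
        if unknown:
            raise CurationError(f"unknown measure types: {sorted(unknown)}")
    out = df.rename(columns={value_column: "value"})[
        [c for c in ("smiles", "value", "target", "measure") if c in df.columns or c in ("smiles", "value")]
    ]
    out["pic50"] = out["value"] if label_is_pic50 else out["value"].map(to_pic50)
    return out


def curate(
    records: pd.DataFrame,
    name: str = "dataset",
    max_len: int = 400,
    contradiction_span: float = 1.0,
    measure: str | None = None,
) -> CuratedDataset:
    """Curate an activity table into a regression dataset.

    ``records`` needs columns ``smiles`` and ``pic50`` (see
    :func:`load_activity_csv`).  Rules, applied in order:

    * rows whose raw SMILES exceeds ``max_len`` characters are removed;
    * unparsable SMILES are removed;
    * exact duplicates (same canonical SMILES, same pIC50) collapse to one row;
    * a molecule whose remaining pIC50 values span more than
      ``contradiction_span`` log units is dropped as contradictory, otherwise
      its values aggregate by median.

    The pinned span/median rule treats one log unit as roughly the
    reproducibility of a binding assay.  ``measure`` restricts to a single
    measure type when the table carries one; by default all types pool into a
    single pIC50 label.  Output ordering is by canonical SMILES, so identical
    inputs in any row order curate to identical datasets.
    """
    required = {"smiles", "pic50"}
    if not required <= set(records.columns):
        raise CurationError(f"records must have columns {sorted(required)}")
    df = records.copy()
    log = {
        "input_rows": int(len(df)),
        "overlength_removed": 0,
        "invalid_removed": 0,
        "duplicates_removed": 0,
        "contradictory_removed": 0,
    }
    if measure is not None:
        if "measure" not in df.columns:
            raise CurationError("measure filter requested but no measure column")
        df = df[df["measure"] == measure]

    lengths = df["smiles"].str.len()
    log["overlength_removed"] = int((lengths > max_len).sum())
    df = df[lengths <= max_len]

    canon = df["smiles"].map(lambda s: canonicalize(s)[0])
    log["invalid_removed"] = int((canon == "").sum())
    df = df.assign(canonical=canon)[canon != ""]

    # exact duplicates: same canonical structure, same label
    before = len(df)
    df = df.drop_duplicates(subset=["canonical", "pic50"])
    log["duplicates_removed"] = before - len(df)

    molecules: list[MoleculeRecord] = []
    labels: list[float] = []
    n_contradictory = 0
    for canonical, group in sorted(df.groupby("canonical"), key=lambda kv: kv[0]):
        values = group["pic50"].to_numpy(dtype=float)
        if values.max() - values.min() > contradiction_span:
            n_contradictory += 1
            continue
        raw = group["smiles"].iloc[0]
        molecules.append(
            MoleculeRecord(
                id=f"M{len(molecules):06d}",
                smiles_raw=raw,
                smiles_canonical=canonical,
                smiles_length=len(raw),
                scaffold=murcko_scaffold(canonical),
            )
        )
        labels.append(float(np.median(values)))
    log["contradictory_removed"] = n_contradictory
    log["output_molecules"] = len(molecules)

    if not molecules:
        raise CurationError("curation removed every molecule")
    return CuratedDataset(
        name=name,
        task="regression",
        molecules=molecules,
        labels=np.array(labels),
        curation_log=log,
    )


def binarize(dataset: CuratedDataset, cutoff: float = 6.0) -> CuratedDataset:
    """Binary activity labels: active (1) iff pIC50 >= cutoff.

    The default cutoff of 6 corresponds to 1 uM potency, the conventional
    active/inactive boundary for screening data.
    """
    if dataset.task != "regression":
        raise ValueError("binarize expects a regression dataset")
    labels = (dataset.labels >= cutoff).astype(float)
    return CuratedDataset(
        name=dataset.name,
        task="classification",
        molecules=list(dataset.molecules),
        labels=labels,
        cutoff=cutoff,
        curation_log=dict(dataset.curation_log),
    )
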