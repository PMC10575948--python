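"""Fixed molecular representations and Tanimoto similarity.

Six representations are supported: an 11-descriptor drug-likeness PhysChem
block, the full RDKit 2D descriptor set, 166-key MACCS fingerprints, Morgan
(ECFP-like) fingerprints in bit and count form, and hashed atom-pair
fingerprints.  All are deterministic functions of the molecular graph for a
fixed toolkit version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import rdkit
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, MACCSkeys, rdFingerprintGenerator, rdMolDescriptors

from .data import MoleculeRecord

REPRESENTATIONS = (
    "PhysChem",
    "RDKit2D",
    "MACCS",
    "MorganBits",
    "MorganCounts",
    "AtomPairs",
)

#: The 11 drug-likeness descriptors, in fixed column order.
PHYSCHEM_COLUMNS = (
    "MolWt",
    "MolLogP",
    "NumHDonors",
    "NumHAcceptors",
    "NumRotatableBonds",
    "NumAtoms",
    "NumHeavyAtoms",
    "MolMR",
    "PSA",
    "FormalCharge",
    "NumRings",
)

__all__ = [
    "FeatureMatrix",
    "REPRESENTATIONS",
    "PHYSCHEM_COLUMNS",
    "compute_representation",
    "tanimoto",
    "physchem_descriptors",
]


@dataclass
class FeatureMatrix:
    """A rectangular molecules-by-features block with provenance.

    ``column_kind`` is "bit" (0/1), "count" (non-negative integers), or
    "continuous".  ``imputed_rows`` lists molecules whose descriptors failed
    and were filled with column medians.
    """

    representation_name: str
    params: dict
    values: np.ndarray
    row_ids: list[str]
    column_names: list[str]
    column_kind: str
    imputed_rows: list[str] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def rows_for(self, ids: Sequence[str]) -> np.ndarray:
        index = {rid: i for i, rid in enumerate(self.row_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"ids missing from feature matrix: {missing[:5]}")
        return self.values[[index[i] for i in ids]]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(self.values, index=self.row_ids, columns=self.column_names).to_csv(
            path, index_label="id"
        )
        sidecar = {
            "representation_name": self.representation_name,
            "params": self.params,
            "column_kind": self.column_kind,
            "toolkit_version": rdkit.__version__,
            "imputed_rows": self.imputed_rows,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def physchem_descriptors(mol: Chem.Mol) -> np.ndarray:
    """The 11 drug-likeness descriptors in PHYSCHEM_COLUMNS order.

    NumAtoms counts all atoms including implicit hydrogens; NumHeavyAtoms
    excludes hydrogens.
    """
    mol_h = Chem.AddHs(mol)
    return np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcNumHBD(mol),
            rdMolDescriptors.CalcNumHBA(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            mol_h.GetNumAtoms(),
            mol.GetNumHeavyAtoms(),
            Crippen.MolMR(mol),
            rdMolDescriptors.CalcTPSA(mol),
            Chem.GetFormalCharge(mol),
            rdMolDescriptors.CalcNumRings(mol),
        ],
        dtype=float,
    )


def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def _atompair_generator(n_bits: int):
    return rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits)


def compute_representation(
    name: str,
    molecules: Sequence[MoleculeRecord],
    radius: int = 2,
    n_bits: int = 2048,
    normalize: bool = False,
) -> FeatureMatrix:
    """Compute one representation for a list of molecules.

    Row order matches the input.  ``radius``/``n_bits`` apply to the Morgan
    variants (defaults radius 2, 2048 bits — the common ECFP4 configuration)
    and ``n_bits`` to AtomPairs.  ``normalize`` optionally z-scores the
    continuous RDKit2D block (zero-variance columns left at zero).

    A molecule whose descriptor calculation fails is imputed with the column
    median of the successful rows and listed in ``imputed_rows``; matrices
    therefore always stay rectangular with no missing values.
    """
    if name not in REPRESENTATIONS:
        raise ValueError(f"unknown representation {name!r}; choose from {REPRESENTATIONS}")
    mols = []
    for rec in molecules:
        mol = Chem.MolFromSmiles(rec.smiles_canonical)
        if mol is None:
            raise ValueError(f"invalid canonical SMILES for {rec.id}")
        mols.append(mol)

    params: dict = {}
    column_kind = "continuous"
    failed: list[int] = []

    if name == "PhysChem":
        rows = [physchem_descriptors(m) for m in mols]
        columns = list(PHYSCHEM_COLUMNS)
    elif name == "RDKit2D":
        params["normalize"] = normalize
        rows = []
        columns = None
        for m in mols:
            try:
                desc = Descriptors.CalcMolDescriptors(m)
                if columns is None:
                    columns = list(desc)
                row = np.array([desc[c] for c in columns], dtype=float)
                if not np.all(np.isfinite(row)):
                    raise FloatingPointError
            except Exception:
                row = None
            rows.append(row)
        if columns is None:
            raise ValueError("RDKit2D failed for every molecule")
        failed = [i for i, r in enumerate(rows) if r is None]
    elif name == "MACCS":
        # RDKit emits 167 slots with key 0 unused; drop it for a stable 166-key layout.
        rows = [np.array(MACCSkeys.GenMACCSKeys(m), dtype=float)[1:] for m in mols]
        columns = [f"maccs_{i}" for i in range(1, 167)]
        column_kind = "bit"
    elif name in ("MorganBits", "MorganCounts"):
        params = {"radius": radius, "n_bits": n_bits}
        gen = _morgan_generator(radius, n_bits)
        if name == "MorganBits":
            rows = [np.array(gen.GetFingerprint(m), dtype=float) for m in mols]
            column_kind = "bit"
        else:
            rows = [np.array(gen.GetCountFingerprint(m).ToList(), dtype=float) for m in mols]
            column_kind = "count"
        columns = [f"bit_{i}" for i in range(n_bits)]
    else:  # AtomPairs
        params = {"n_bits": n_bits}
        gen = _atompair_generator(n_bits)
        rows = [np.array(gen.GetCountFingerprint(m).ToList(), dtype=float) for m in mols]
        columns = [f"ap_{i}" for i in range(n_bits)]
        column_kind = "count"

    n_cols = len(columns)
    ok_rows = [r for r in rows if r is not None]
    if not ok_rows:
        raise ValueError(f"{name} failed for every molecule")
    median = np.median(np.stack(ok_rows), axis=0)
    values = np.stack([r if r is not None else median for r in rows])

    if name == "RDKit2D" and normalize:
        mean = values.mean(axis=0)
        std = values.std(axis=0)
        std[std == 0] = 1.0
        values = (values - mean) / std

    return FeatureMatrix(
        representation_name=name,
        params=params,
        values=values,
        row_ids=[rec.id for rec in molecules],
        column_names=columns,
        column_kind=column_kind,
        imputed_rows=[molecules[i].id for i in failed],
    )


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| between two bit vectors.

    Two all-zero vectors are identically empty and score 1.0.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
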