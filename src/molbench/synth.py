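"""Synthetic activity datasets with planted structure.

Real bioactivity extracts cannot ship with a test suite, so this module
builds SMILES molecules by attaching small substituents (H, methyl, chloro,
hydroxyl, acetyl, aldehyde, short alkyl chains, ...) to ring-scaffold
templates via string assembly, and assigns pIC50 labels from an explicit
generative model:

    label = scaffold base + substituent effect + planted cliff term + noise

Scaffold bases draw from a skew-normal (right-skewed by default, like
screening potency data where most molecules are weak binders); a chosen
fraction of scaffolds carries a planted activity cliff (one member lifted by
``cliff_magnitude`` log units); another fraction forms edge groups whose
members straddle the pIC50-6 cutoff inside the 5-7 window.  Substituent
effects are clipped to +/-0.8 so that only planted cliffs can reach the
2-log-unit span threshold — the generator's ground truth is therefore an
exact oracle for cliff annotation.

Every emitted SMILES validates, canonicalizes, and has a non-empty Murcko
scaffold by construction.  Everything is a deterministic function of the
spec seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from scipy import stats as sps

from .data import CuratedDataset, MoleculeRecord, canonicalize, murcko_scaffold
from .features import PHYSCHEM_COLUMNS, physchem_descriptors
from rdkit import Chem

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_activity_dataset",
    "generate_descriptor_dataset",
    "add_label_noise",
    "scaffold_library",
    "LADDER_SIZES",
    "SUBSTITUENTS",
]

#: ring templates; each starts with a ring atom so substituents can prefix-attach
_RINGS = (
    "c1ccccc1",
    "c1ccncc1",
    "c1cnccn1",
    "c1cncnc1",
    "c1ccoc1",
    "c1ccsc1",
    "c1cc[nH]c1",
    "c1ccc2ccccc2c1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOCC1",
    "C1CCCC1",
    "C1CCNC1",
    "C1CCOC1",
    "C1CCCCCC1",
)

#: linkers joining two rings into a larger framework
_LINKERS = ("", "C", "CC", "CCC", "O", "N", "CO", "CN", "OC", "C(=O)")

#: substituent SMILES prefixes (attach to the first ring atom) with names
SUBSTITUENTS = (
    ("", "H"),
    ("C", "methyl"),
    ("CC", "ethyl"),
    ("CCC", "propyl"),
    ("CCCC", "butyl"),
    ("O", "hydroxyl"),
    ("OC", "hydroxymethyl"),
    ("COC", "methoxymethyl"),
    ("Cl", "chloro"),
    ("F", "fluoro"),
    ("Br", "bromo"),
    ("N", "amino"),
    ("NC", "aminomethyl"),
    ("CC(=O)", "acetyl"),
    ("O=C", "aldehyde"),
    ("CC(C)", "isopropyl"),
    ("OCC", "hydroxyethyl"),
    ("CN(C)", "dimethylamino"),
)

#: suffix substituents (append after the closing ring atom) for the
#: descriptor-dataset library
_SUFFIXES = ("", "C", "CC", "CCC", "O", "N", "Cl", "F", "CO", "C(C)C")

#: dataset-size ladder; the elided middle of the published list is
#: reconstructed as a regular 1-2-4-6-8 progression
LADDER_SIZES = (
    100, 200, 400, 600, 800, 1000,
    2000, 4000, 6000, 8000, 10000,
    20000, 40000, 60000, 80000, 100000,
)

#: substituent effects are clipped here so non-cliff scaffold spans stay
#: below the 2-log-unit activity-cliff threshold
_EFFECT_CLIP = 0.8


def scaffold_library(n_scaffolds: int) -> list[str]:
    """Deterministic list of ``n_scaffolds`` distinct ring frameworks.

    Single rings come first, then ring-linker-ring assemblies in grid
    order.  Each entry is its own canonical Murcko scaffold.
    """
    seen: set[str] = set()
    out: list[str] = []
    candidates = itertools.chain(
        _RINGS,
        (r1 + link + r2 for r1, link, r2 in itertools.product(_RINGS, _LINKERS, _RINGS)),
    )
    for smi in candidates:
        if len(out) >= n_scaffolds:
            return out
        canon, ok = canonicalize(smi)
        if not ok or canon in seen:
            continue
        scaffold = murcko_scaffold(canon)
        if scaffold != canon or scaffold in seen:
            continue  # template must be exactly its own framework
        seen.add(canon)
        out.append(smi)
    raise ValueError(
        f"scaffold library exhausted at {len(out)} < {n_scaffolds} requested"
    )


@dataclass
class SyntheticSpec:
    """Free parameters of the activity-data generator.

    Defaults emulate the shape of curated screening extracts: scaffold
    bases right-skewed on the pIC50 scale, group sizes heavy-tailed
    (P(size) proportional to size^-size_exponent on the
    ``molecules_per_scaffold`` range — most scaffolds are singletons or
    pairs, a few analog series are large), and ~10% of scaffolds carrying
    activity cliffs, assigned to the largest groups so AC molecules form a
    disproportionate share of the dataset.  ``cliff_magnitude`` is in pIC50
    log units.  ``noise`` is "none", "gaussian" (sd ``noise_sigma``) or
    "heteroscedastic" (sd = noise_sigma + hetero_k * |clean - hetero_y0|).
    """

    n_scaffolds: int = 100
    molecules_per_scaffold: tuple[int, int] = (1, 18)
    size_exponent: float = 1.5
    ac_scaffold_fraction: float = 0.1
    cliff_magnitude: float = 2.5
    base_loc: float = 4.6
    base_scale: float = 1.3
    base_skew: float = 4.0
    substituent_effect_scale: float = 0.3
    noise: Literal["none", "gaussian", "heteroscedastic"] = "none"
    noise_sigma: float = 0.0
    hetero_k: float = 0.0
    hetero_y0: float = 6.0
    edge_group_fraction: float = 0.0
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        for frac in (self.ac_scaffold_fraction, self.edge_group_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.cliff_magnitude < 0:
            raise ValueError("cliff_magnitude must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        lo, hi = self.molecules_per_scaffold
        if lo < 1 or hi < lo:
            raise ValueError("molecules_per_scaffold must be a valid range")
        if self.ac_scaffold_fraction > 0 and hi < 2:
            raise ValueError("activity cliffs need scaffold groups of >= 2 molecules")

    @classmethod
    def for_positive_rate(
        cls,
        rate: float,
        cutoff: float = 6.0,
        n_mc_scaffolds: int = 4000,
        **kwargs,
    ) -> "SyntheticSpec":
        """Spec whose label model yields ~``rate`` positives at ``cutoff``.

        Solves for ``base_loc`` by bisection against a Monte-Carlo replicate
        of the full noiseless label model — heavy-tailed group sizes, role
        assignment, planted cliff lifts, and cutoff-anchored edge groups —
        run on ``n_mc_scaffolds`` scaffolds without any molecule assembly.
        The internal RNG is fixed, so the calibration is deterministic.
        """
        if not 0.0 < rate < 1.0:
            raise ValueError("rate must be in (0, 1)")
        probe = cls(**kwargs)
        rng = np.random.default_rng(12345)
        n_subs = len(SUBSTITUENTS)
        lo_s, hi_s = probe.molecules_per_scaffold
        hi_s = min(hi_s, n_subs)
        support = np.arange(lo_s, hi_s + 1)
        p = support.astype(float) ** -probe.size_exponent
        sizes = rng.choice(support, size=n_mc_scaffolds, p=p / p.sum())
        bases0 = sps.skewnorm.rvs(
            probe.base_skew, loc=0.0, scale=probe.base_scale,
            size=n_mc_scaffolds, random_state=rng,
        )
        eligible = np.flatnonzero(sizes >= 2)
        n_ac = int(round(probe.ac_scaffold_fraction * n_mc_scaffolds))
        n_edge = int(round(probe.edge_group_fraction * n_mc_scaffolds))
        by_size = eligible[np.argsort(-sizes[eligible], kind="stable")]
        ac = set(by_size[:n_ac].tolist())
        edge = set(rng.choice(by_size[n_ac:], size=n_edge, replace=False).tolist()) if n_edge else set()

        # labels that shift with base_loc enter as "critical loc" values
        # (positive iff base_loc >= cutoff - v); edge groups are anchored at
        # the cutoff and contribute a constant positive count
        crit: list[float] = []
        const_pos = 0
        n_total = 0
        for si in range(n_mc_scaffolds):
            size = int(sizes[si])
            n_total += size
            if si in edge:
                offsets = rng.uniform(-0.7, 0.7, size=size)
                base = 6.0 + rng.uniform(-0.2, 0.2)
                labels = base + offsets
                labels[0] = 6.0 - rng.uniform(0.1, 0.9)
                labels[1] = 6.0 + rng.uniform(0.05, 0.9)
                const_pos += int((labels >= cutoff).sum())
                continue
            eff = np.clip(
                rng.normal(0.0, probe.substituent_effect_scale, size=size),
                -_EFFECT_CLIP, _EFFECT_CLIP,
            )
            v = bases0[si] + eff
            if si in ac:
                n_lift = max(1, size // 4)
                v[:n_lift] = v[n_lift:].min() + probe.cliff_magnitude
            crit.extend((cutoff - v).tolist())

        crit_arr = np.sort(np.asarray(crit))
        lo, hi = cutoff - 15.0, cutoff + 15.0
        for _ in range(60):
            mid = (lo + hi) / 2
            mc_rate = (np.searchsorted(crit_arr, mid, side="right") + const_pos) / n_total
            if mc_rate < rate:
                lo = mid
            else:
                hi = mid
        kwargs["base_loc"] = (lo + hi) / 2
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Generator bookkeeping: the oracle for cliff/edge annotation tests."""

    scaffold_base: dict[str, float]
    ac_scaffolds: list[str]
    edge_scaffolds: list[str]
    clean_labels: dict[str, float]
    substituent: dict[str, str]
    cliff_term: dict[str, float]
    edge_flag: dict[str, bool]
    spec: dict = field(default_factory=dict)
    molecule_scaffold: dict[str, str] = field(default_factory=dict)

    @property
    def ac_molecule_ids(self) -> set[str]:
        ac = set(self.ac_scaffolds)
        return {mid for mid, scaf in self.molecule_scaffold.items() if scaf in ac}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def generate_activity_dataset(
    spec: SyntheticSpec,
) -> tuple[CuratedDataset, GroundTruth]:
    """Build a scaffold-grouped activity dataset with planted structure.

    Molecules are substituent-on-template SMILES assemblies; labels follow
    the generative model in the module docstring.  Within an AC scaffold the
    first member is lifted so the group's noiseless span equals exactly
    ``cliff_magnitude``; edge groups are re-based near the cutoff with
    members forced onto both sides within the [5, 7] window.
    """
    rng = np.random.default_rng(spec.seed)
    templates = scaffold_library(spec.n_scaffolds)
    n_subs = len(SUBSTITUENTS)
    lo, hi = spec.molecules_per_scaffold
    hi = min(hi, n_subs)
    # scaffold occupancy is heavy-tailed in curated extracts: most scaffolds
    # are singletons or pairs, a few analog series are large
    support = np.arange(lo, hi + 1)
    p = support.astype(float) ** -spec.size_exponent
    sizes = rng.choice(support, size=spec.n_scaffolds, p=p / p.sum())

    bases = spec.base_loc + sps.skewnorm.rvs(
        spec.base_skew, loc=0.0, scale=spec.base_scale,
        size=spec.n_scaffolds, random_state=rng,
    )

    n_edge = int(round(spec.edge_group_fraction * spec.n_scaffolds))
    n_ac = int(round(spec.ac_scaffold_fraction * spec.n_scaffolds))
    eligible = np.array([i for i in range(spec.n_scaffolds) if sizes[i] >= 2])
    if n_ac + n_edge > eligible.size:
        raise ValueError("not enough multi-molecule scaffolds for requested AC/edge fractions")
    # cliffs surface in the most-explored analog series: the largest groups
    # become AC scaffolds, so they carry a disproportionate molecule share
    shuffled = rng.permutation(eligible)
    by_size = shuffled[np.argsort(-sizes[shuffled], kind="stable")]
    ac_idx = set(by_size[:n_ac].tolist())
    remaining = np.array([i for i in by_size[n_ac:]])
    edge_idx = set(rng.choice(remaining, size=n_edge, replace=False).tolist()) if n_edge else set()

    molecules: list[MoleculeRecord] = []
    labels: list[float] = []
    gt = GroundTruth(
        scaffold_base={}, ac_scaffolds=[], edge_scaffolds=[],
        clean_labels={}, substituent={}, cliff_term={}, edge_flag={},
        spec=asdict(spec), molecule_scaffold={},
    )

    for si, template in enumerate(templates):
        scaffold_canon = murcko_scaffold(canonicalize(template)[0])
        size = int(sizes[si])
        sub_choice = rng.choice(n_subs, size=size, replace=False)
        base = float(bases[si])
        if si in edge_idx:
            base = 6.0 + float(rng.uniform(-0.2, 0.2))
            gt.edge_scaffolds.append(scaffold_canon)
        gt.scaffold_base[scaffold_canon] = base

        # substituent effects are context-dependent: drawn per scaffold
        member_effects = np.clip(
            rng.normal(0.0, spec.substituent_effect_scale, size=size),
            -_EFFECT_CLIP, _EFFECT_CLIP,
        )
        if si in edge_idx:
            # force members onto both sides of the cutoff inside [5, 7]
            member_effects = rng.uniform(-0.7, 0.7, size=size)
            member_effects[0] = (6.0 - float(rng.uniform(0.1, 0.9))) - base
            member_effects[1] = (6.0 + float(rng.uniform(0.05, 0.9))) - base

        clean = base + member_effects
        cliff_terms = np.zeros(size)
        if si in ac_idx:
            gt.ac_scaffolds.append(scaffold_canon)
            # a cliff series has several potent analogs, not a lone outlier:
            # lift a quarter of the group (at least one member) to exactly
            # cliff_magnitude above the weakest remaining analog
            n_lift = max(1, size // 4)
            target = clean[n_lift:].min() + spec.cliff_magnitude
            cliff_terms[:n_lift] = target - clean[:n_lift]
        clean = clean + cliff_terms

        for mi in range(size):
            prefix, sub_name = SUBSTITUENTS[int(sub_choice[mi])]
            smiles = prefix + template
            canon, ok = canonicalize(smiles)
            if not ok:
                raise RuntimeError(f"generator emitted invalid SMILES {smiles!r}")
            mol_id = f"S{si:04d}_{mi:02d}"
            molecules.append(
                MoleculeRecord(
                    id=mol_id,
                    smiles_raw=smiles,
                    smiles_canonical=canon,
                    smiles_length=len(smiles),
                    scaffold=scaffold_canon,
                )
            )
            gt.clean_labels[mol_id] = float(clean[mi])
            gt.substituent[mol_id] = sub_name
            gt.cliff_term[mol_id] = float(cliff_terms[mi])
            gt.edge_flag[mol_id] = si in edge_idx
            gt.molecule_scaffold[mol_id] = scaffold_canon
            labels.append(float(clean[mi]))

    dataset = CuratedDataset(
        name=spec.name,
        task="regression",
        molecules=molecules,
        labels=np.array(labels),
        curation_log={"synthetic": True, "n_scaffolds": spec.n_scaffolds},
    )
    if spec.noise != "none":
        dataset = add_label_noise(
            dataset,
            model=spec.noise,
            sigma=spec.noise_sigma,
            k=spec.hetero_k,
            y0=spec.hetero_y0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return dataset, gt


def add_label_noise(
    dataset: CuratedDataset,
    model: Literal["gaussian", "heteroscedastic"] = "gaussian",
    sigma: float = 0.0,
    k: float = 0.0,
    y0: float = 6.0,
    seed: int = 0,
) -> CuratedDataset:
    """Perturb regression labels i.i.d.; sigma may grow with |y - y0|.

    gaussian: label + N(0, sigma).  heteroscedastic: label + N(0, sigma +
    k * |label - y0|), emulating assay error that grows away from the
    calibration midpoint.  sigma = 0 (and k = 0) returns labels unchanged.
    """
    if dataset.task != "regression":
        raise ValueError("label noise applies to regression labels")
    if sigma < 0 or k < 0:
        raise ValueError("noise parameters must be >= 0")
    rng = np.random.default_rng(seed)
    y = dataset.labels
    if model == "gaussian":
        sd = np.full_like(y, sigma)
    elif model == "heteroscedastic":
        sd = sigma + k * np.abs(y - y0)
    else:
        raise ValueError(f"unknown noise model {model!r}")
    noisy = y + rng.normal(0.0, 1.0, size=y.size) * sd
    return CuratedDataset(
        name=dataset.name,
        task="regression",
        molecules=list(dataset.molecules),
        labels=noisy,
        cutoff=dataset.cutoff,
        curation_log={**dataset.curation_log, "noise_model": model, "noise_sigma": sigma},
    )


def generate_descriptor_dataset(
    size: int,
    property: Literal["MolWt", "NumAtoms"] = "MolWt",
    seed: int = 0,
    smiles: Optional[list[str]] = None,
) -> CuratedDataset:
    """Molecules labelled by one of their own computed descriptors.

    Labels are exactly recomputable from structure, so model error on these
    datasets isolates what a representation can express.  Molecules come
    from the internal prefix x scaffold x suffix assembly grid (sampled
    without replacement, deterministic per seed) or from a user-supplied
    SMILES list.
    """
    if size < 10:
        raise ValueError("size must be >= 10")
    if property not in ("MolWt", "NumAtoms"):
        raise ValueError("property must be MolWt or NumAtoms")
    rng = np.random.default_rng(seed)

    if smiles is None:
        prefixes = [p for p, _ in SUBSTITUENTS]
        rings = scaffold_library(600)
        grid = len(prefixes) * len(rings) * len(_SUFFIXES)
        order = rng.permutation(grid)
        pool_iter = (
            (prefixes[i % len(prefixes)],
             rings[(i // len(prefixes)) % len(rings)],
             _SUFFIXES[i // (len(prefixes) * len(rings))])
            for i in order
        )
        candidates = (p + r + s for p, r, s in pool_iter)
    else:
        candidates = iter(list(rng.permutation(np.array(smiles, dtype=object))))

    molecules: list[MoleculeRecord] = []
    labels: list[float] = []
    seen: set[str] = set()
    mw_col = PHYSCHEM_COLUMNS.index("MolWt")
    na_col = PHYSCHEM_COLUMNS.index("NumAtoms")
    for raw in candidates:
        if len(molecules) >= size:
            break
        canon, ok = canonicalize(raw)
        if not ok or canon in seen:
            continue
        seen.add(canon)
        mol = Chem.MolFromSmiles(canon)
        desc = physchem_descriptors(mol)
        label = desc[mw_col] if property == "MolWt" else desc[na_col]
        molecules.append(
            MoleculeRecord(
                id=f"D{len(molecules):06d}",
                smiles_raw=raw,
                smiles_canonical=canon,
                smiles_length=len(raw),
                scaffold=murcko_scaffold(canon),
            )
        )
        labels.append(float(label))
    if len(molecules) < size:
        raise ValueError(
            f"molecule library exhausted at {len(molecules)} unique structures < {size}"
        )
    return CuratedDataset(
        name=f"descriptor_{property}_{size}",
        task="regression",
        molecules=molecules,
        labels=np.array(labels),
        curation_log={"synthetic": True, "property": property},
    )
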