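"""The synthetic-molecule generator and its ground truth."""

import numpy as np
import pytest

from molbench import (
    SyntheticSpec,
    add_label_noise,
    annotate_cliffs,
    binarize,
    generate_activity_dataset,
    generate_descriptor_dataset,
)
from molbench.data import canonicalize, murcko_scaffold
from molbench.features import PHYSCHEM_COLUMNS, physchem_descriptors
from rdkit import Chem
from scipy import stats


def test_generated_smiles_all_valid_with_ring_scaffolds(small_activity):
    ds, _ = small_activity
    for mol in ds.molecules:
        canon, ok = canonicalize(mol.smiles_raw)
        assert ok and canon == mol.smiles_canonical
        assert mol.scaffold != ""
        assert mol.scaffold == murcko_scaffold(mol.smiles_canonical)


def test_unique_canonical_smiles(small_activity):
    ds, _ = small_activity
    canon = [m.smiles_canonical for m in ds.molecules]
    assert len(set(canon)) == len(canon)


def test_same_seed_reproduces_dataset():
    spec = SyntheticSpec(n_scaffolds=25, seed=13)
    a, gta = generate_activity_dataset(spec)
    b, gtb = generate_activity_dataset(spec)
    assert [m.smiles_canonical for m in a.molecules] == [m.smiles_canonical for m in b.molecules]
    assert np.array_equal(a.labels, b.labels)
    assert gta.ac_scaffolds == gtb.ac_scaffolds


def test_labels_reproduce_from_ground_truth(small_activity):
    ds, gt = small_activity
    for mol, label in zip(ds.molecules, ds.labels):
        base = gt.scaffold_base[mol.scaffold]
        assert label == pytest.approx(gt.clean_labels[mol.id], abs=1e-12)
        # clean label decomposes into base + effect + cliff term
        effect = gt.clean_labels[mol.id] - base - gt.cliff_term[mol.id]
        assert abs(effect) <= 0.8 + 1e-9 or gt.edge_flag[mol.id]


def test_planted_cliffs_have_guaranteed_span(small_activity):
    ds, gt = small_activity
    ann = annotate_cliffs(ds)
    spans = ann.scaffold_table.set_index("scaffold")["span"]
    for s in gt.ac_scaffolds:
        assert spans[s] >= gt.spec["cliff_magnitude"] - 1e-9


def test_cliff_recovery_degrades_gracefully_with_noise():
    recalls = []
    for sigma in (0.0, 0.3, 0.6):
        recovered = 0
        total = 0
        for seed in range(3):
            spec = SyntheticSpec(
                n_scaffolds=60, ac_scaffold_fraction=0.1,
                noise="gaussian" if sigma else "none", noise_sigma=sigma, seed=seed,
            )
            ds, gt = generate_activity_dataset(spec)
            ann = annotate_cliffs(ds)
            found = set(ann.scaffold_table.loc[ann.scaffold_table.is_ac, "scaffold"])
            recovered += len(found & set(gt.ac_scaffolds))
            total += len(gt.ac_scaffolds)
        recalls.append(recovered / total)
    assert recalls[0] == 1.0
    assert recalls[0] >= recalls[1] >= recalls[2] - 1e-9


def test_edge_groups_straddle_cutoff():
    spec = SyntheticSpec(n_scaffolds=50, edge_group_fraction=0.2, seed=21)
    ds, gt = generate_activity_dataset(spec)
    by_scaffold: dict[str, list[float]] = {}
    for mol, label in zip(ds.molecules, ds.labels):
        by_scaffold.setdefault(mol.scaffold, []).append(label)
    assert len(gt.edge_scaffolds) == 10
    for s in gt.edge_scaffolds:
        values = np.array(by_scaffold[s])
        assert ((values >= 5) & (values < 6)).any()
        assert ((values >= 6) & (values <= 7)).any()


def test_positive_rate_calibration():
    spec = SyntheticSpec.for_positive_rate(
        0.3, n_scaffolds=250, molecules_per_scaffold=(6, 12), seed=5,
    )
    ds, _ = generate_activity_dataset(spec)
    assert len(ds) >= 2000
    rate = binarize(ds, 6.0).labels.mean()
    assert rate == pytest.approx(0.3, abs=0.03)


def test_skew_sign_control():
    right = SyntheticSpec(n_scaffolds=200, molecules_per_scaffold=(5, 10), base_skew=4.0, seed=1)
    ds, _ = generate_activity_dataset(right)
    assert len(ds) >= 1000
    assert stats.skew(ds.labels) > 0
    left = SyntheticSpec(n_scaffolds=200, molecules_per_scaffold=(5, 10), base_skew=-4.0, seed=1)
    ds_l, _ = generate_activity_dataset(left)
    assert stats.skew(ds_l.labels) < 0


def test_gaussian_noise_statistics():
    spec = SyntheticSpec(n_scaffolds=300, molecules_per_scaffold=(8, 12), seed=2)
    ds, _ = generate_activity_dataset(spec)
    noisy = add_label_noise(ds, model="gaussian", sigma=0.5, seed=0)
    delta = noisy.labels - ds.labels
    assert delta.size >= 2000
    assert 0.48 <= delta.std() <= 0.52

    unchanged = add_label_noise(ds, model="gaussian", sigma=0.0, seed=0)
    assert np.array_equal(unchanged.labels, ds.labels)


def test_heteroscedastic_noise_grows_with_distance():
    spec = SyntheticSpec(n_scaffolds=300, molecules_per_scaffold=(8, 12), seed=3)
    ds, _ = generate_activity_dataset(spec)
    noisy = add_label_noise(ds, model="heteroscedastic", sigma=0.1, k=0.3, y0=6.0, seed=1)
    dist = np.abs(ds.labels - 6.0)
    spread = np.abs(noisy.labels - ds.labels)
    rho = stats.spearmanr(dist, spread).statistic
    assert rho > 0


def test_noise_parameter_validation(small_activity):
    ds, _ = small_activity
    with pytest.raises(ValueError):
        add_label_noise(ds, sigma=-0.1)
    with pytest.raises(ValueError):
        SyntheticSpec(ac_scaffold_fraction=0.5, molecules_per_scaffold=(1, 1))


def test_descriptor_dataset_labels_exactly_recomputable():
    for prop in ("MolWt", "NumAtoms"):
        ds = generate_descriptor_dataset(50, property=prop, seed=0)
        col = list(PHYSCHEM_COLUMNS).index(prop)
        for mol, label in zip(ds.molecules, ds.labels):
            recomputed = physchem_descriptors(Chem.MolFromSmiles(mol.smiles_canonical))[col]
            assert label == recomputed


def test_descriptor_dataset_unique_and_deterministic():
    a = generate_descriptor_dataset(200, seed=4)
    b = generate_descriptor_dataset(200, seed=4)
    smiles_a = [m.smiles_canonical for m in a.molecules]
    assert smiles_a == [m.smiles_canonical for m in b.molecules]
    assert len(set(smiles_a)) == 200


def test_descriptor_dataset_exhaustion_errors():
    with pytest.raises(ValueError):
        generate_descriptor_dataset(20, smiles=["CCO", "CCN", "CCC"] * 10, seed=0)
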