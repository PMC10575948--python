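"""Dataset and split profiling: label divergence, structural similarity,
descriptor-label correlation.

The Kolmogorov D statistic (sup-distance between two empirical CDFs)
quantifies how far apart label distributions are between partitions —
scaffold splits typically push it higher than random splits because
molecules sharing a scaffold tend to share potency.  Nearest-neighbour
Tanimoto similarity of test molecules against the training set measures
structural train/test overlap the same way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data import CuratedDataset
from .features import FeatureMatrix, PHYSCHEM_COLUMNS
from .splits import SplitManifest

__all__ = [
    "ProfileReport",
    "kolmogorov_d",
    "cross_set_similarity",
    "descriptor_label_correlation",
    "profile_split",
]


def kolmogorov_d(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov D: sup_x |ECDF_a(x) - ECDF_b(x)| in [0, 1]."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def cross_set_similarity(
    features_ref: FeatureMatrix,
    features_query: FeatureMatrix,
) -> np.ndarray:
    """Per-query nearest-neighbour Tanimoto similarity against a reference set.

    For each query molecule, the maximum Tanimoto similarity to any
    reference molecule, computed on bit fingerprints.  Returns the full
    vector (order = query rows); quartiles are for the caller to summarize.
    """
    if features_ref.representation_name != features_query.representation_name or (
        features_ref.params != features_query.params
    ):
        raise ValueError("reference and query feature matrices must share representation/params")
    if features_ref.column_kind != "bit":
        raise ValueError("cross-set similarity requires bit fingerprints")
    ref = features_ref.values.astype(bool)
    query = features_query.values.astype(bool)
    popc_ref = ref.sum(axis=1)
    popc_query = query.sum(axis=1)
    # |a AND b| via boolean matmul; |a OR b| = |a| + |b| - |a AND b|
    inter = query.astype(np.float64) @ ref.T.astype(np.float64)
    union = popc_query[:, None] + popc_ref[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    return sim.max(axis=1)


def descriptor_label_correlation(
    dataset: CuratedDataset,
    physchem: FeatureMatrix,
) -> dict[str, Optional[float]]:
    """Pearson correlation of each descriptor column with the regression label.

    Zero-variance descriptor columns map to None (undefined), never NaN.
    """
    if dataset.task != "regression":
        raise ValueError("descriptor-label correlation needs regression labels")
    if len(dataset) < 3:
        raise ValueError("need at least 3 molecules")
    X = physchem.rows_for(dataset.ids)
    y = dataset.labels
    out: dict[str, Optional[float]] = {}
    for j, col in enumerate(physchem.column_names):
        x = X[:, j]
        if x.std() == 0 or y.std() == 0:
            out[col] = None
        else:
            out[col] = float(stats.pearsonr(x, y).statistic)
    return out


@dataclass
class ProfileReport:
    """Label, divergence, and similarity summary for one split of one dataset."""

    dataset_name: str
    method: str
    seed: int
    label_summary: dict[str, dict]
    kolmogorov: dict[str, float]
    similarity_summary: dict[str, dict]
    descriptor_correlation: dict[str, Optional[float]] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _label_block(values: np.ndarray, task: str, cutoff: Optional[float]) -> dict:
    hist, edges = np.histogram(values, bins=10)
    block = {
        "n": int(values.size),
        "mean": float(values.mean()),
        "skew": float(stats.skew(values, bias=False)) if values.size > 2 and values.std() > 0 else None,
        "histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
    }
    if task == "classification":
        block["positive_rate"] = float(values.mean())
    elif cutoff is not None:
        block["positive_rate"] = float((values >= cutoff).mean())
    return block


def profile_split(
    dataset: CuratedDataset,
    manifest: SplitManifest,
    fingerprints: Optional[FeatureMatrix] = None,
    physchem: Optional[FeatureMatrix] = None,
) -> ProfileReport:
    """Assemble the per-split profile: label summaries and pairwise
    Kolmogorov D for (train,val), (train,test), (val,test); nearest-neighbour
    Tanimoto of val/test molecules against train when fingerprints are given;
    descriptor-label correlations when the PhysChem block is given."""
    id_index = {mid: i for i, mid in enumerate(dataset.ids)}
    parts = {
        name: np.array([dataset.labels[id_index[i]] for i in ids])
        for name, ids in manifest.partitions().items()
    }
    label_summary = {
        name: _label_block(vals, dataset.task, dataset.cutoff) for name, vals in parts.items()
    }
    kolmogorov = {
        f"{a}_vs_{b}": kolmogorov_d(parts[a], parts[b])
        for a, b in (("train", "val"), ("train", "test"), ("val", "test"))
    }
    similarity_summary: dict[str, dict] = {}
    if fingerprints is not None:
        ref = _subset_features(fingerprints, manifest.train_ids)
        for name in ("val", "test"):
            query = _subset_features(fingerprints, manifest.partitions()[name])
            sims = cross_set_similarity(ref, query)
            q1, q2, q3 = np.percentile(sims, [25, 50, 75])
            similarity_summary[f"{name}_vs_train"] = {
                "median": float(q2),
                "q1": float(q1),
                "q3": float(q3),
            }
    corr: dict[str, Optional[float]] = {}
    if physchem is not None and dataset.task == "regression":
        corr = descriptor_label_correlation(dataset, physchem)
    return ProfileReport(
        dataset_name=dataset.name,
        method=manifest.method,
        seed=manifest.seed,
        label_summary=label_summary,
        kolmogorov=kolmogorov,
        similarity_summary=similarity_summary,
        descriptor_correlation=corr,
    )


def _subset_features(fm: FeatureMatrix, ids: Sequence[str]) -> FeatureMatrix:
    return FeatureMatrix(
        representation_name=fm.representation_name,
        params=fm.params,
        values=fm.rows_for(ids),
        row_ids=list(ids),
        column_names=fm.column_names,
        column_kind=fm.column_kind,
    )
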