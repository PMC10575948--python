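"""Baseline model wrappers and benchmark orchestration.

Three traditional baselines train on the fixed representations: random
forest (500 trees), a linear support-vector machine, and gradient-boosted
trees (XGBoost).  An "external" model spec instead ingests a prediction CSV
produced by any outside model, so the statistics layer can compare models
this package never trains.

Models fit on the training partition only; the validation partition is
carried in every manifest for model families that need it, but the
traditional baselines do not.  Test labels are never passed to the fitting
call.  All raw predictions are retained: every metric downstream is
recomputed from the same saved prediction sets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .cliffs import ACAnnotation, annotate_cliffs, stratify_ids
from .data import CuratedDataset, binarize
from .features import FeatureMatrix, compute_representation
from .metrics import MetricResult, classification_metrics, regression_metrics
from .splits import SplitManifest, split_protocol

__all__ = ["ModelSpec", "PredictionSet", "train_and_predict", "run_benchmark", "sweep_cutoffs"]


@dataclass(frozen=True)
class ModelSpec:
    """Which model to train, with serializable hyperparameters.

    RF defaults to 500 trees (max_features="sqrt" — see the methods note);
    SVM uses a linear kernel; XGBoost uses library defaults.  ``seed`` feeds
    every stochastic component of the fit.
    """

    name: Literal["RF", "SVM", "XGBoost", "external"]
    task: Literal["regression", "classification"]
    hyperparameters: tuple = ()
    seed: int = 0

    def hyper_dict(self) -> dict:
        return dict(self.hyperparameters)

    @classmethod
    def make(cls, name: str, task: str, seed: int = 0, **hyper) -> "ModelSpec":
        return cls(name=name, task=task, hyperparameters=tuple(sorted(hyper.items())), seed=seed)


@dataclass
class PredictionSet:
    """Raw per-molecule predictions for one (model, representation, split).

    ``predictions`` are real-valued pIC50 estimates for regression, or
    positive-class scores in [0, 1] for classification.
    """

    dataset: str
    model: str
    representation: str
    method: str
    seed: int
    task: str
    ids: list[str]
    labels: np.ndarray
    predictions: np.ndarray
    partition: str = "test"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        self.predictions = np.asarray(self.predictions, dtype=float)
        if len(self.ids) != self.labels.size or self.labels.size != self.predictions.size:
            raise ValueError("ids, labels, predictions must align")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("prediction ids must be unique")

    def subset(self, ids: Sequence[str], tag: str) -> "PredictionSet":
        index = {i: k for k, i in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return PredictionSet(
            dataset=self.dataset, model=self.model, representation=self.representation,
            method=self.method, seed=self.seed, task=self.task,
            ids=list(ids), labels=self.labels[rows], predictions=self.predictions[rows],
            partition=f"{self.partition}:{tag}", provenance=dict(self.provenance),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(
            {"id": self.ids, "y_true": self.labels, "y_pred": self.predictions}
        ).to_csv(path, index=False)
        meta = {k: v for k, v in asdict(self).items() if k not in ("ids", "labels", "predictions")}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PredictionSet":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(ids=list(df["id"]), labels=df["y_true"].to_numpy(),
                   predictions=df["y_pred"].to_numpy(), **meta)


def _build_estimator(spec: ModelSpec):
    hyper = spec.hyper_dict()
    if spec.name == "RF":
        from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

        kw = {"n_estimators": 500, "max_features": "sqrt", "random_state": spec.seed, **hyper}
        return (RandomForestRegressor if spec.task == "regression" else RandomForestClassifier)(**kw)
    if spec.name == "SVM":
        from sklearn.svm import LinearSVC, LinearSVR

        if spec.task == "regression":
            return LinearSVR(random_state=spec.seed, dual="auto", max_iter=10000, **hyper)
        return LinearSVC(random_state=spec.seed, dual="auto", max_iter=10000, **hyper)
    if spec.name == "XGBoost":
        from xgboost import XGBClassifier, XGBRegressor

        kw = {"random_state": spec.seed, "n_jobs": 1, "verbosity": 0, **hyper}
        return (XGBRegressor if spec.task == "regression" else XGBClassifier)(**kw)
    raise ValueError(f"no estimator for model {spec.name!r}")


def _positive_scores(estimator, X: np.ndarray) -> np.ndarray:
    """Calibrated probabilities when available, else min-max-scaled decision values."""
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    raw = estimator.decision_function(X)
    lo, hi = raw.min(), raw.max()
    return (raw - lo) / (hi - lo) if hi > lo else np.full_like(raw, 0.5)


def train_and_predict(
    spec: ModelSpec,
    features: FeatureMatrix,
    dataset: CuratedDataset,
    manifest: SplitManifest,
    external_predictions: Optional[pd.DataFrame] = None,
) -> PredictionSet:
    """Fit on the train partition, predict the test partition.

    Deterministic given ``spec.seed``.  For ``spec.name == "external"``,
    ``external_predictions`` (columns id, y_pred) stands in for a fit, and
    must cover the manifest's test ids.
    """
    id_index = {mid: i for i, mid in enumerate(dataset.ids)}
    test_ids = manifest.test_ids
    y_test = np.array([dataset.labels[id_index[i]] for i in test_ids])

    if spec.name == "external":
        if external_predictions is None:
            raise ValueError("external model spec needs external_predictions")
        lookup = dict(zip(external_predictions["id"], external_predictions["y_pred"]))
        missing = [i for i in test_ids if i not in lookup]
        if missing:
            raise ValueError(f"external predictions missing test ids: {missing[:5]}")
        preds = np.array([lookup[i] for i in test_ids], dtype=float)
        score_kind = "external"
    else:
        train_ids = manifest.train_ids
        X_train = features.rows_for(train_ids)
        y_train = np.array([dataset.labels[id_index[i]] for i in train_ids])
        if spec.task == "classification" and np.unique(y_train).size < 2:
            raise ValueError("training partition is single-class; cannot fit a classifier")
        estimator = _build_estimator(spec)
        estimator.fit(X_train, y_train.astype(int) if spec.task == "classification" else y_train)
        X_test = features.rows_for(test_ids)
        if spec.task == "classification":
            preds = _positive_scores(estimator, X_test)
            score_kind = "probability" if hasattr(estimator, "predict_proba") else "scaled_decision"
        else:
            preds = estimator.predict(X_test)
            score_kind = "value"

    return PredictionSet(
        dataset=dataset.name,
        model=spec.name,
        representation=features.representation_name,
        method=manifest.method,
        seed=manifest.seed,
        task=spec.task,
        ids=list(test_ids),
        labels=y_test,
        predictions=preds,
        provenance={
            "model_seed": spec.seed,
            "hyperparameters": spec.hyper_dict(),
            "score_kind": score_kind,
            "feature_params": features.params,
        },
    )


def _metric_rows(
    pred: PredictionSet, results: Sequence[MetricResult]
) -> list[dict]:
    return [
        {
            "dataset": pred.dataset, "model": pred.model,
            "representation": pred.representation, "method": pred.method,
            "seed": pred.seed, "subset": r.subset, "metric": r.metric,
            "value": r.value, "n": r.n, "threshold": r.threshold,
        }
        for r in results
    ]


def evaluate_predictions(
    pred: PredictionSet,
    annotation: Optional[ACAnnotation] = None,
) -> pd.DataFrame:
    """Metric table for a prediction set, optionally AC/edge-stratified.

    With an annotation, metrics are recomputed on the AC, non-AC, and
    edge-removed views of the test set (views too small or single-class are
    skipped silently — they carry no information).
    """
    views = {"all": list(pred.ids)}
    if annotation is not None:
        views = stratify_ids(pred.ids, annotation)
    rows: list[dict] = []
    for tag, ids in views.items():
        if len(ids) < 2:
            continue
        sub = pred.subset(ids, tag) if tag != "all" else pred
        try:
            if pred.task == "classification":
                results, _ = classification_metrics(sub.predictions, sub.labels)
            else:
                results = regression_metrics(sub.predictions, sub.labels)
        except ValueError:
            continue  # single-class or degenerate view
        for r in results:
            r = MetricResult(r.metric, r.value, r.n, tag, r.threshold)
            rows.extend(_metric_rows(pred, [r]))
    return pd.DataFrame(rows)


def _cell_key(*parts) -> str:
    return hashlib.sha1("|".join(str(p) for p in parts).encode()).hexdigest()[:16]


def run_benchmark(
    dataset: CuratedDataset,
    representations: Sequence[str] = ("MorganBits",),
    models: Sequence[str] = ("RF",),
    methods: Sequence[str] = ("scaffold", "random"),
    n_seeds: int = 30,
    task: Literal["regression", "classification"] = "regression",
    cutoff: float = 6.0,
    out_dir: str | Path | None = None,
    annotate: bool = True,
) -> pd.DataFrame:
    """Full grid: split-protocol x representations x models -> metric table.

    Curate -> split (all seeds) -> featurize -> train/predict -> metrics
    (with AC-stratified views when ``annotate``).  With ``out_dir``, every
    prediction set persists as CSV+JSON keyed by a content hash of its cell
    coordinates, and completed cells are skipped on re-runs.  A failing cell
    is recorded (metric rows with value None) without aborting the grid.
    """
    work = binarize(dataset, cutoff) if task == "classification" else dataset
    annotation = annotate_cliffs(dataset) if (annotate and dataset.task == "regression") else None
    manifests = split_protocol(dataset, methods=methods, n_seeds=n_seeds)
    feature_cache = {
        rep: compute_representation(rep, dataset.molecules) for rep in representations
    }
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    tables: list[pd.DataFrame] = []
    for manifest in manifests:
        for rep in representations:
            for model in models:
                key = _cell_key(dataset.name, task, rep, model, manifest.method, manifest.seed)
                cell_path = out / f"pred_{key}.csv" if out is not None else None
                if cell_path is not None and cell_path.exists():
                    pred = PredictionSet.load(cell_path)
                else:
                    spec = ModelSpec.make(model, task, seed=manifest.seed)
                    try:
                        pred = train_and_predict(spec, feature_cache[rep], work, manifest)
                    except ValueError as exc:
                        tables.append(pd.DataFrame([{
                            "dataset": dataset.name, "model": model, "representation": rep,
                            "method": manifest.method, "seed": manifest.seed,
                            "subset": "all", "metric": "error", "value": None,
                            "n": 0, "threshold": None, "error": str(exc),
                        }]))
                        continue
                    if cell_path is not None:
                        pred.save(cell_path)
                tables.append(evaluate_predictions(pred, annotation))
    result = pd.concat(tables, ignore_index=True)
    if out is not None:
        result.to_csv(out / "metrics.csv", index=False)
    return result


def sweep_cutoffs(
    dataset: CuratedDataset,
    cutoffs: Sequence[float],
    representation: str = "MorganBits",
    model: str = "RF",
    methods: Sequence[str] = ("scaffold",),
    n_seeds: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classification performance as a function of the activity cutoff.

    For each cutoff the regression dataset is binarized, a classifier is
    trained per (method, seed), and metrics plus the dataset positive rate
    are recorded; predicted probabilities for edge-case molecules in each
    test set are collected separately so their drift across cutoffs can be
    inspected.  Cutoffs that produce a single-class training set are
    recorded as skipped cells rather than raised.

    Returns (metric table with a positive_rate column, edge-score table with
    columns cutoff/method/seed/id/score).
    """
    if dataset.task != "regression":
        raise ValueError("cutoff sweep needs regression labels")
    features = compute_representation(representation, dataset.molecules)
    manifests = split_protocol(dataset, methods=methods, n_seeds=n_seeds)
    annotation = annotate_cliffs(dataset)
    edge_ids = set(annotation.molecule_table.loc[annotation.molecule_table["is_edge"], "id"])

    metric_rows: list[pd.DataFrame] = []
    edge_rows: list[dict] = []
    for cutoff in cutoffs:
        clf_dataset = binarize(dataset, cutoff)
        positive_rate = float(clf_dataset.labels.mean())
        for manifest in manifests:
            spec = ModelSpec.make(model, "classification", seed=manifest.seed)
            try:
                pred = train_and_predict(spec, features, clf_dataset, manifest)
                table = evaluate_predictions(pred)
                fitted = True
            except ValueError as exc:
                fitted = False
                table = pd.DataFrame([{
                    "dataset": dataset.name, "model": model, "representation": representation,
                    "method": manifest.method, "seed": manifest.seed, "subset": "all",
                    "metric": "error", "value": None, "n": 0, "threshold": None,
                    "error": str(exc),
                }])
            table["cutoff"] = cutoff
            table["positive_rate"] = positive_rate
            metric_rows.append(table)
            if fitted:
                for mol_id, score in zip(pred.ids, pred.predictions):
                    if mol_id in edge_ids:
                        edge_rows.append({
                            "cutoff": cutoff, "method": manifest.method,
                            "seed": manifest.seed, "id": mol_id, "score": float(score),
                        })
    return pd.concat(metric_rows, ignore_index=True), pd.DataFrame(edge_rows)
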