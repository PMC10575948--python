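"""Classification and regression metric suite.

Classification: AUROC (rank-based, half-credit for ties), AUPRC (step-wise
average precision), and the threshold-dependent predictive values
PPV = TP/(TP+FP) and NPV = TN/(TN+FN).  Thresholds come from Youden's J
statistic (the maximal vertical distance between the ROC curve and the
chance line) when classes are imbalanced, else 0.5.

Regression: RMSE, MAE, the coefficient of determination R2 (baseline =
label mean; can be negative), and Pearson's correlation.  R2 and the square
of Pearson's R measure different things: R2 penalises any miscalibration
while Pearson_R only sees linear association, so R2 <= Pearson_R^2 always.

Metric values whose denominator vanishes (e.g. PPV with no predicted
positives) are reported as None — an explicit undefined marker — never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricResult",
    "youden_threshold",
    "confusion_counts",
    "classification_metrics",
    "regression_metrics",
    "auroc",
    "auprc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN at a fixed score threshold (positive iff score >= threshold)."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricResult:
    """One metric value with its context; value None marks 'undefined'."""

    metric: str
    value: Optional[float]
    n: int
    subset: str = "all"
    threshold: Optional[float] = None


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> None:
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    if scores.size == 0:
        raise ValueError("empty prediction set")
    classes = np.unique(labels)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError(f"labels must be binary 0/1, got {classes}")
    if classes.size < 2:
        raise ValueError("both classes must be present")


def youden_threshold(scores, labels) -> float:
    """Score threshold maximizing Youden's J = TPR - FPR.

    Candidate thresholds are the distinct observed scores (a molecule is
    called positive when its score >= threshold); ties in J break toward the
    higher threshold, the conservative operating point for screening.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_binary(scores, labels)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    # sweep distinct scores descending: cumulative TP/FP give TPR/FPR at each cut
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    cum_tp = np.cumsum(l_sorted)
    cum_fp = np.cumsum(1 - l_sorted)
    # J at threshold s_sorted[i]: counts include the whole tie block ending at i
    block_end = np.r_[np.nonzero(distinct)[0][1:] - 1, s_sorted.size - 1]
    thresholds = s_sorted[distinct]
    j = cum_tp[block_end] / n_pos - cum_fp[block_end] / n_neg
    best = np.flatnonzero(j == j.max())[0]  # thresholds sorted descending
    return float(thresholds[best])


def confusion_counts(scores, labels, threshold: float) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
        threshold=float(threshold),
    )


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Equals U/(n_pos * n_neg) with average ranks giving tied pairs half
    credit; 0.5 is chance level, below 0.5 is worse than random.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_binary(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve as step-wise average precision.

    AP = sum_k (R_k - R_{k-1}) * P_k over distinct-score cuts, descending.
    No trapezoidal interpolation (which is optimistic for PR curves).  The
    chance baseline is the positive fraction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_binary(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    block_end = np.r_[np.nonzero(distinct)[0][1:] - 1, s_sorted.size - 1]
    cum_tp = np.cumsum(l_sorted)[block_end]
    cum_pred = block_end + 1.0
    precision = cum_tp / cum_pred
    recall = cum_tp / l_sorted.sum()
    d_recall = np.diff(np.r_[0.0, recall])
    return float((d_recall * precision).sum())


def classification_metrics(
    scores,
    labels,
    threshold: Optional[float] = None,
    subset: str = "all",
    imbalance_trigger: float = 0.4,
) -> tuple[list[MetricResult], ConfusionCounts]:
    """AUROC, AUPRC, PPV, NPV plus the confusion counts behind PPV/NPV.

    Threshold policy: an explicit ``threshold`` wins; otherwise Youden's J
    is applied when the minority-class fraction is below
    ``imbalance_trigger`` (0.4), else 0.5.  PPV/NPV with an empty predicted
    class are reported as undefined (None).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_binary(scores, labels)
    n = scores.size
    if threshold is None:
        minority = min(labels.mean(), 1 - labels.mean())
        threshold = youden_threshold(scores, labels) if minority < imbalance_trigger else 0.5
    cm = confusion_counts(scores, labels, threshold)
    ppv = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else None
    npv = cm.tn / (cm.tn + cm.fn) if (cm.tn + cm.fn) else None
    results = [
        MetricResult("AUROC", auroc(scores, labels), n, subset),
        MetricResult("AUPRC", auprc(scores, labels), n, subset),
        MetricResult("PPV", ppv, n, subset, threshold),
        MetricResult("NPV", npv, n, subset, threshold),
    ]
    return results, cm


def regression_metrics(preds, labels, subset: str = "all") -> list[MetricResult]:
    """RMSE, MAE, R2 (mean-baseline), and Pearson_R.

    Pearson_R is undefined (None) when either vector is constant; R2 is
    undefined when the labels are constant.
    """
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if preds.shape != labels.shape:
        raise ValueError("predictions and labels length mismatch")
    n = preds.size
    if n < 2:
        raise ValueError("need at least 2 points for regression metrics")
    err = preds - labels
    rmse = math.sqrt(float(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((labels - labels.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else None
    sd_p = preds.std()
    sd_l = labels.std()
    if sd_p > 0 and sd_l > 0:
        pearson = float(
            np.sum((labels - labels.mean()) * (preds - preds.mean()))
            / math.sqrt(np.sum((labels - labels.mean()) ** 2) * np.sum((preds - preds.mean()) ** 2))
        )
    else:
        pearson = None
    return [
        MetricResult("RMSE", rmse, n, subset),
        MetricResult("MAE", mae, n, subset),
        MetricResult("R2", r2, n, subset),
        MetricResult("Pearson_R", pearson, n, subset),
    ]
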