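"""Metric suite versus independent brute-force oracles."""

import math

import numpy as np
import pytest

from molbench import (
    classification_metrics,
    regression_metrics,
    youden_threshold,
)
from molbench.metrics import auprc, auroc, confusion_counts


# --- independent oracles ---------------------------------------------------

def brute_auroc(scores, labels):
    """All positive-negative pairs, half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_average_precision(scores, labels):
    """Step-wise AP over distinct-score cuts, descending."""
    cuts = sorted(set(scores), reverse=True)
    n_pos = sum(labels)
    ap, prev_recall = 0.0, 0.0
    for t in cuts:
        tp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 0)
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def brute_youden(scores, labels):
    """Exhaustive J over distinct thresholds; ties -> higher threshold."""
    best_t, best_j = None, -2.0
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    for t in sorted(set(scores), reverse=True):
        tp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 0)
        j = tp / n_pos - fp / n_neg
        if j > best_j:  # strictly better only: keeps the highest threshold on ties
            best_t, best_j = t, j
    return best_t, best_j


def brute_regression(preds, labels):
    n = len(preds)
    rmse = math.sqrt(sum((p - y) ** 2 for p, y in zip(preds, labels)) / n)
    mae = sum(abs(p - y) for p, y in zip(preds, labels)) / n
    ybar = sum(labels) / n
    pbar = sum(preds) / n
    ss_res = sum((p - y) ** 2 for p, y in zip(preds, labels))
    ss_tot = sum((y - ybar) ** 2 for y in labels)
    r2 = 1 - ss_res / ss_tot
    cov = sum((y - ybar) * (p - pbar) for p, y in zip(preds, labels))
    pearson = cov / math.sqrt(
        sum((y - ybar) ** 2 for y in labels) * sum((p - pbar) ** 2 for p in preds)
    )
    return rmse, mae, r2, pearson


def _random_classification(rng, n=40):
    labels = np.zeros(n)
    labels[: rng.integers(1, n)] = 1
    rng.shuffle(labels)
    # quantized scores force plenty of ties
    scores = np.round(rng.random(n), 2)
    return scores, labels


# --- hand-checked examples -------------------------------------------------

def test_ppv_npv_hand_example():
    # TP=3 FP=1 TN=5 FN=1
    scores = np.r_[np.ones(4), np.zeros(6)]
    labels = np.r_[1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
    results, cm = classification_metrics(scores, labels, threshold=0.5)
    values = {r.metric: r.value for r in results}
    assert (cm.tp, cm.fp, cm.tn, cm.fn) == (3, 1, 5, 1)
    assert values["PPV"] == pytest.approx(0.75)
    assert values["NPV"] == pytest.approx(5 / 6)


def test_perfect_predictions():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array([1, 1, 0, 0])
    results, _ = classification_metrics(scores, labels, threshold=0.5)
    assert {r.metric: r.value for r in results} == {
        "AUROC": 1.0, "AUPRC": 1.0, "PPV": 1.0, "NPV": 1.0,
    }


def test_constant_scores_are_chance_level():
    scores = np.full(20, 0.3)
    labels = np.r_[np.ones(8), np.zeros(12)]
    assert auroc(scores, labels) == pytest.approx(0.5)


def test_undefined_ppv_is_none_not_zero():
    scores = np.array([0.1, 0.2, 0.3, 0.4])
    labels = np.array([0, 1, 0, 1])
    results, _ = classification_metrics(scores, labels, threshold=0.9)
    values = {r.metric: r.value for r in results}
    assert values["PPV"] is None


def test_regression_hand_examples():
    values = {r.metric: r.value for r in regression_metrics([3.0, 4.0], [0.0, 0.0])}
    assert values["RMSE"] == pytest.approx(math.sqrt(12.5))
    assert values["MAE"] == pytest.approx(3.5)

    y = np.array([1.0, 2.0, 3.0, 4.0])
    perfect = {r.metric: r.value for r in regression_metrics(y, y)}
    assert perfect == {"RMSE": 0.0, "MAE": 0.0, "R2": 1.0, "Pearson_R": 1.0}

    mean_model = {r.metric: r.value for r in regression_metrics(np.full(4, y.mean()), y)}
    assert mean_model["R2"] == pytest.approx(0.0)
    assert mean_model["Pearson_R"] is None  # constant predictions


def test_affine_rescaling_keeps_pearson_not_r2():
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    values = {r.metric: r.value for r in regression_metrics(2 * y + 5, y)}
    assert values["Pearson_R"] == pytest.approx(1.0)
    assert values["R2"] < 1.0


def test_youden_hand_example():
    labels = [1, 0, 1, 0]
    scores = [0.9, 0.8, 0.7, 0.2]
    t = youden_threshold(scores, labels)
    assert t == 0.9
    cm = confusion_counts(np.array(scores), np.array(labels), t)
    assert cm.tp / 2 - cm.fp / 2 == pytest.approx(0.5)


def test_youden_perfect_separation():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array([1, 1, 0, 0])
    t = youden_threshold(scores, labels)
    cm = confusion_counts(scores, labels, t)
    assert (cm.fp, cm.fn) == (0, 0)  # J = 1 at the returned threshold


def test_youden_null_scores_give_small_j():
    rng = np.random.default_rng(0)
    scores = rng.random(2000)
    labels = (rng.random(2000) < 0.5).astype(float)
    t = youden_threshold(scores, labels)
    cm = confusion_counts(scores, labels, t)
    j = cm.tp / (cm.tp + cm.fn) - cm.fp / (cm.fp + cm.tn)
    assert j < 0.1


def test_single_class_rejected():
    with pytest.raises(ValueError):
        youden_threshold([0.1, 0.2], [1, 1])
    with pytest.raises(ValueError):
        classification_metrics([0.1, 0.2], [0, 0])


# --- oracle equivalence & inequality properties ----------------------------

def test_classification_metrics_match_brute_force():
    rng = np.random.default_rng(42)
    for _ in range(300):
        scores, labels = _random_classification(rng)
        assert auroc(scores, labels) == pytest.approx(
            brute_auroc(scores, labels), abs=1e-10
        )
        assert auprc(scores, labels) == pytest.approx(
            brute_average_precision(scores, labels), abs=1e-10
        )


def test_auprc_matches_sklearn_average_precision():
    from sklearn.metrics import average_precision_score, roc_auc_score

    rng = np.random.default_rng(7)
    for _ in range(100):
        scores, labels = _random_classification(rng)
        assert auprc(scores, labels) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-10
        )
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-10
        )


def test_regression_metrics_match_brute_force():
    rng = np.random.default_rng(3)
    for _ in range(300):
        n = rng.integers(5, 60)
        y = rng.normal(size=n)
        p = y + rng.normal(scale=rng.uniform(0.01, 2.0), size=n)
        values = {r.metric: r.value for r in regression_metrics(p, y)}
        rmse, mae, r2, pearson = brute_regression(p, y)
        assert values["RMSE"] == pytest.approx(rmse, abs=1e-10)
        assert values["MAE"] == pytest.approx(mae, abs=1e-10)
        assert values["R2"] == pytest.approx(r2, abs=1e-10)
        assert values["Pearson_R"] == pytest.approx(pearson, abs=1e-10)
        # inequality properties
        assert mae <= rmse + 1e-12
        assert r2 <= pearson**2 + 1e-12


def test_auroc_equals_mann_whitney_u():
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(11)
    for _ in range(50):
        scores, labels = _random_classification(rng)
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        n1, n0 = int(labels.sum()), int((1 - labels).sum())
        assert auroc(scores, labels) == pytest.approx(u / (n1 * n0), abs=1e-12)


def test_youden_matches_exhaustive_enumeration():
    rng = np.random.default_rng(8)
    for _ in range(200):
        scores, labels = _random_classification(rng, n=25)
        t_ref, j_ref = brute_youden(list(scores), list(labels))
        t = youden_threshold(scores, labels)
        assert t == t_ref
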