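"""Statistical comparison of models over repeated splits.

Metric distributions over split seeds are typically skewed and
heteroscedastic, so pairwise comparisons use the non-parametric
Mann-Whitney U test (two-sided, alpha = 0.05 by default, no
multiple-testing correction unless requested).  Win counting emulates the
common informal practice of declaring whichever model tops a single fold
(or the mean of three folds) the "best" — counting how often each model
would win shows how easily a single-split comparison misleads.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonReport",
    "mann_whitney_u",
    "pairwise_compare",
    "count_wins",
    "impute_nonsignificant",
    "variability_analysis",
    "residual_analysis",
]

#: relative tolerance treating two metric values as tied in win counting
WIN_TIE_RTOL = 1e-12


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two samples -> (U of sample a, p).

    Uses the exact null distribution when the combined sample size is <= 16
    and there are no ties, otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 16 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonReport:
    """Pairwise significance, win counts, and variability for one metric."""

    metric: str
    better: Literal["higher", "lower"]
    models: list[str]
    means: dict[str, float]
    stds: dict[str, float]
    p_values: pd.DataFrame  # symmetric, unit diagonal
    significant: pd.DataFrame  # boolean, p < alpha
    alpha: float
    single_wins: dict[str, int] = field(default_factory=dict)
    single_ties: int = 0
    triple_wins: dict[str, int] = field(default_factory=dict)
    triple_ties: int = 0

    def save(self, path: str | Path) -> None:
        d = {
            "metric": self.metric,
            "better": self.better,
            "models": self.models,
            "means": self.means,
            "stds": self.stds,
            "alpha": self.alpha,
            "p_values": self.p_values.to_dict(),
            "significant": self.significant.astype(bool).to_dict(),
            "single_wins": self.single_wins,
            "single_ties": self.single_ties,
            "triple_wins": self.triple_wins,
            "triple_ties": self.triple_ties,
        }
        Path(path).write_text(json.dumps(d, indent=2))


def pairwise_compare(
    results: pd.DataFrame,
    metric: str = "metric",
    better: Literal["higher", "lower"] = "higher",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> ComparisonReport:
    """Full comparison over a seeds-by-models metric table.

    ``results``: DataFrame indexed by seed with one column per model; all
    models must be evaluated on the identical seed set (no missing cells).
    ``bonferroni`` divides alpha by the number of pairs (off by default —
    unadjusted pairwise p-values are the protocol's convention).
    """
    if results.isna().any().any():
        raise ValueError("metric table has missing cells")
    models = list(results.columns)
    k = len(models)
    p = pd.DataFrame(np.ones((k, k)), index=models, columns=models)
    for m1, m2 in itertools.combinations(models, 2):
        _, pv = mann_whitney_u(results[m1].to_numpy(), results[m2].to_numpy())
        p.loc[m1, m2] = p.loc[m2, m1] = pv
    thresh = alpha / max(1, k * (k - 1) // 2) if bonferroni else alpha
    significant = (p < thresh) & ~np.eye(k, dtype=bool)
    single_wins, single_ties = count_wins(results, mode="single", better=better)
    triple_wins, triple_ties = count_wins(results, mode="triple", better=better)
    return ComparisonReport(
        metric=metric,
        better=better,
        models=models,
        means={m: float(results[m].mean()) for m in models},
        stds={m: float(results[m].std(ddof=1)) for m in models},
        p_values=p,
        significant=pd.DataFrame(significant, index=models, columns=models),
        alpha=alpha,
        single_wins=single_wins,
        single_ties=single_ties,
        triple_wins=triple_wins,
        triple_ties=triple_ties,
    )


def _best_model(values: np.ndarray, models: list[str], better: str) -> Optional[str]:
    best = values.max() if better == "higher" else values.min()
    scale = max(abs(best), 1.0)
    winners = np.flatnonzero(np.abs(values - best) <= WIN_TIE_RTOL * scale)
    return models[winners[0]] if winners.size == 1 else None


def count_wins(
    metric_table: pd.DataFrame,
    mode: Literal["single", "triple"] = "single",
    better: Literal["higher", "lower"] = "higher",
) -> tuple[dict[str, int], int]:
    """Count per-model wins over folds -> (wins per model, tie count).

    single: per seed, the best model wins; exact ties (within floating-point
    tolerance) award nobody and are counted separately.  triple: over all
    C(n_seeds, 3) seed combinations, the best mean over the triple wins.
    Wins plus ties always total the number of folds (or triples).
    """
    if metric_table.isna().any().any():
        raise ValueError("metric table has missing cells")
    models = list(metric_table.columns)
    wins = {m: 0 for m in models}
    ties = 0
    values = metric_table.to_numpy(dtype=float)
    if mode == "single":
        rows: Sequence[np.ndarray] = values
    elif mode == "triple":
        rows = [
            values[list(combo)].mean(axis=0)
            for combo in itertools.combinations(range(values.shape[0]), 3)
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for row in rows:
        winner = _best_model(row, models, better)
        if winner is None:
            ties += 1
        else:
            wins[winner] += 1
    return wins, ties


def impute_nonsignificant(diffs, ps, alpha: float = 0.05) -> np.ndarray:
    """Zero out differences whose test p-value is not below alpha."""
    diffs = np.asarray(diffs, dtype=float)
    ps = np.asarray(ps, dtype=float)
    if diffs.shape != ps.shape:
        raise ValueError("diffs and ps length mismatch")
    return np.where(ps < alpha, diffs, 0.0)


def variability_analysis(
    results: pd.DataFrame,
) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-model mean/std over seeds plus corr(mean, std) across models.

    Returns (summary frame indexed by model with columns mean/std, Pearson
    correlation between the model means and stds — None when either vector
    is constant).  Needs >= 3 models and >= 2 seeds.
    """
    if results.shape[0] < 2:
        raise ValueError("need at least 2 seeds")
    if results.shape[1] < 3:
        raise ValueError("need at least 3 models")
    summary = pd.DataFrame(
        {"mean": results.mean(axis=0), "std": results.std(axis=0, ddof=1)}
    )
    if summary["mean"].std() == 0 or summary["std"].std() == 0:
        corr = None
    else:
        corr = float(sps.pearsonr(summary["mean"], summary["std"]).statistic)
    return summary, corr


def residual_analysis(
    preds,
    labels,
    subsets: Optional[dict[str, np.ndarray]] = None,
) -> dict:
    """Signed errors (prediction - label) with a trend summary.

    Returns the per-molecule errors, the least-squares slope of error on
    label (None for n < 3 or constant labels; a model that regresses to the
    mean shows slope -1: overestimation at low labels, underestimation at
    high), and mean error per optional boolean subset mask (e.g. edge
    cases).
    """
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if preds.shape != labels.shape:
        raise ValueError("predictions and labels length mismatch")
    errors = preds - labels
    if labels.size >= 3 and labels.std() > 0:
        slope = float(np.polyfit(labels, errors, 1)[0])
    else:
        slope = None
    subset_means = {}
    for name, mask in (subsets or {}).items():
        mask = np.asarray(mask, dtype=bool)
        subset_means[name] = float(errors[mask].mean()) if mask.any() else None
    return {"errors": errors, "slope": slope, "subset_mean_error": subset_means}
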