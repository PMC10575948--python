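"""Model-comparison statistics: Mann-Whitney, win counting, variability."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from molbench import (
    count_wins,
    impute_nonsignificant,
    mann_whitney_u,
    pairwise_compare,
    residual_analysis,
    variability_analysis,
)


def brute_exact_mwu_p(a, b):
    """Two-sided exact p by enumerating all rank assignments (no ties)."""
    pooled = sorted(a + b)
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    n = len(pooled)
    us = []
    for combo in itertools.combinations(range(n), n_a):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n) if i not in combo]
        us.append(sum(1 for x in xs for y in ys if x > y))
    mean_u = n_a * (n - n_a) / 2
    tail = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u))
    return tail / len(us)


def test_mwu_separated_samples_exact():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1, abs=1e-12)
    assert p == pytest.approx(brute_exact_mwu_p([1, 2, 3], [4, 5, 6]), abs=1e-12)


def test_mwu_identical_samples():
    a = [1.0, 2.0, 3.0, 4.0]
    u, p = mann_whitney_u(a, a)
    assert u == len(a) ** 2 / 2
    assert p > 0.9


def test_mwu_exact_matches_enumeration_on_random_inputs():
    rng = np.random.default_rng(0)
    for _ in range(10):
        a = list(np.round(rng.normal(size=4), 6))
        b = list(np.round(rng.normal(0.5, 1, size=5), 6))
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(brute_exact_mwu_p(a, b), abs=1e-9)


def test_mwu_exact_vs_asymptotic_boundary_consistency():
    # at n=15 per group the two paths should agree closely
    rng = np.random.default_rng(1)
    deltas = []
    for _ in range(40):
        a = rng.normal(size=8)          # 8 + 8 = 16 -> exact path
        b = rng.normal(0.4, 1, size=8)
        from scipy.stats import mannwhitneyu

        p_exact = mannwhitneyu(a, b, method="exact").pvalue
        p_asymp = mannwhitneyu(a, b, method="asymptotic").pvalue
        deltas.append(abs(p_exact - p_asymp))
    assert max(deltas) <= 0.02


def test_mwu_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


def test_count_wins_dominance_and_triple_identity():
    rng = np.random.default_rng(2)
    table = pd.DataFrame({"A": rng.random(30) + 10, "B": rng.random(30), "C": rng.random(30)})
    wins, ties = count_wins(table, mode="single", better="higher")
    assert wins == {"A": 30, "B": 0, "C": 0} and ties == 0
    wins3, ties3 = count_wins(table, mode="triple", better="higher")
    assert wins3["A"] == math.comb(30, 3) == 4060 and ties3 == 0


def test_count_wins_tie_convention():
    table = pd.DataFrame({"A": np.ones(30), "B": np.ones(30)})
    wins, ties = count_wins(table, mode="single")
    assert wins == {"A": 0, "B": 0} and ties == 30


def test_count_wins_matches_brute_force_triples():
    rng = np.random.default_rng(3)
    table = pd.DataFrame(rng.random((30, 3)), columns=["A", "B", "C"])
    wins, ties = count_wins(table, mode="triple", better="lower")
    brute = {"A": 0, "B": 0, "C": 0}
    for combo in itertools.combinations(range(30), 3):
        means = table.iloc[list(combo)].mean()
        brute[means.idxmin()] += 1
    assert wins == brute and ties == 0
    assert sum(wins.values()) + ties == math.comb(30, 3)


def test_count_wins_permutation_equivariant():
    rng = np.random.default_rng(4)
    table = pd.DataFrame(rng.random((12, 3)), columns=["A", "B", "C"])
    wins, _ = count_wins(table)
    renamed = table.rename(columns={"A": "C", "C": "A"})
    wins_renamed, _ = count_wins(renamed[["A", "B", "C"]])
    assert wins_renamed == {"A": wins["C"], "B": wins["B"], "C": wins["A"]}


def test_pairwise_compare_flags_shifted_model():
    rng = np.random.default_rng(5)
    table = pd.DataFrame(
        {
            "good": rng.normal(0.9, 0.02, size=30),
            "bad": rng.normal(0.7, 0.02, size=30),
            "same": rng.normal(0.9, 0.02, size=30),
        }
    )
    report = pairwise_compare(table, metric="AUROC", better="higher")
    assert report.significant.loc["good", "bad"]
    assert report.p_values.loc["good", "bad"] == report.p_values.loc["bad", "good"]
    assert (np.diag(report.p_values) == 1.0).all()
    assert sum(report.single_wins.values()) + report.single_ties == 30


def test_pairwise_compare_identical_models_not_significant():
    vec = np.linspace(0, 1, 30)
    table = pd.DataFrame({"A": vec, "B": vec})
    report = pairwise_compare(table)
    assert not report.significant.to_numpy().any()


def test_pairwise_compare_rejects_missing_cells():
    table = pd.DataFrame({"A": [1.0, np.nan], "B": [1.0, 2.0]})
    with pytest.raises(ValueError):
        pairwise_compare(table)


def test_impute_nonsignificant():
    out = impute_nonsignificant([0.5, 0.5], [0.01, 0.2], alpha=0.05)
    assert list(out) == [0.5, 0.0]
    assert list(impute_nonsignificant([1.0, -1.0], [0.5, 0.9])) == [0.0, 0.0]
    assert list(impute_nonsignificant([1.0, -1.0], [0.5, 0.9], alpha=1.0)) == [1.0, -1.0]


def test_variability_analysis_correlation_signs():
    rng = np.random.default_rng(6)
    # noisier models are also worse: higher RMSE mean <-> higher std
    means = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
    stds = np.array([0.05, 0.1, 0.2, 0.3, 0.4])
    table = pd.DataFrame(
        {f"m{i}": rng.normal(means[i], stds[i], size=30) for i in range(5)}
    )
    summary, corr = variability_analysis(table)
    assert corr > 0.8
    from scipy.stats import pearsonr

    assert corr == pytest.approx(
        pearsonr(summary["mean"], summary["std"]).statistic, abs=1e-10
    )


def test_variability_analysis_degenerate_cases():
    table = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0], "c": [3.0, 3.0]})
    summary, corr = variability_analysis(table)
    assert corr is None  # all stds zero
    with pytest.raises(ValueError):
        variability_analysis(table.iloc[:1])
    with pytest.raises(ValueError):
        variability_analysis(table[["a", "b"]])


def test_residual_analysis_slopes():
    y = np.linspace(4, 9, 50)
    perfect = residual_analysis(y, y)
    assert np.allclose(perfect["errors"], 0)
    assert perfect["slope"] == pytest.approx(0.0, abs=1e-12)
    mean_model = residual_analysis(np.full_like(y, y.mean()), y)
    assert mean_model["slope"] == pytest.approx(-1.0)


def test_residual_analysis_subset_means():
    y = np.array([5.0, 6.0, 7.0, 8.0])
    preds = y + np.array([0.5, 0.5, -0.2, -0.2])
    out = residual_analysis(preds, y, subsets={"low": y < 6.5, "high": y >= 6.5})
    assert out["subset_mean_error"]["low"] == pytest.approx(0.5)
    assert out["subset_mean_error"]["high"] == pytest.approx(-0.2)
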