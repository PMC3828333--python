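"""Logistic marker models: fits vs an independent Newton solver, AUC vs a
brute-force pairwise oracle, forward selection on planted-truth panels."""

import numpy as np
import pandas as pd
import pytest

from cytostrat.markers import (
    build_design,
    fit_logistic,
    forward_select,
    permutation_auc_test,
    roc_auc,
)
from cytostrat.panel_io import MolarMatrix
from cytostrat.subgrouping import SubgroupAssignment


def newton_logistic(X, y, tol=1e-12, max_iter=100):
    """Plain Newton-Raphson logistic MLE (independent of statsmodels)."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    cov = np.linalg.inv(hess)
    return beta, np.sqrt(np.diag(cov))


def pairwise_auc_oracle(scores, labels):
    """AUC by explicit comparison of every (positive, negative) pair."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_molar(cols, prefix="P"):
    df = pd.DataFrame(cols)
    df.index = [f"{prefix}{i}" for i in range(len(df))]
    return MolarMatrix(df, "baseline")


def assignment_from_bool(y, index):
    labels = pd.Series(np.where(y, "High", "Low"), index=index)
    return SubgroupAssignment.from_labels(labels, ["Low", "High"])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_half_wins(self):
        # positives {3, 2}, negatives {1, 4}: 2 wins of 4 pairs
        assert roc_auc([3, 2, 1, 4], [1, 1, 0, 0]) == 0.5

    def test_all_ties_give_half(self):
        assert roc_auc([1.0] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc_oracle(scores, labels), abs=1e-12
            )


class TestFitLogistic:
    def test_balanced_independent_predictor_has_zero_slope(self):
        # x and y perfectly balanced: empirical odds ratio is exactly 1
        x = np.array([0.0, 1.0] * 10)
        y = np.array([0, 1, 1, 0] * 5)
        model = fit_logistic(pd.DataFrame({"x": x}), y)
        assert model.terms[0].coefficient == pytest.approx(0.0, abs=1e-6)
        assert model.terms[0].wald_p == pytest.approx(1.0, abs=1e-4)

    def test_grouped_2x2_slope_is_log_odds_ratio(self):
        # exposure x=1: 8 events / 2 non-events; x=0: 2 events / 8 non-events
        x = np.repeat([1.0, 0.0], 10)
        y = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        model = fit_logistic(pd.DataFrame({"x": x}), y)
        assert model.terms[0].coefficient == pytest.approx(np.log(16.0), rel=1e-4)

    def test_perfect_separation_flagged_not_raised(self):
        x = np.arange(10, dtype=float)
        y = (x >= 5).astype(int)
        model = fit_logistic(pd.DataFrame({"x": x}), y)
        assert model.converged is False

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0]}), [1, 1])

    def test_matches_independent_newton_solver(self, rng):
        for _ in range(10):
            n = 200
            X = rng.normal(size=(n, 2))
            beta_true = np.array([0.3, -0.8, 0.5])
            p = 1 / (1 + np.exp(-(beta_true[0] + X @ beta_true[1:])))
            y = (rng.random(n) < p).astype(int)
            model = fit_logistic(pd.DataFrame(X, columns=["a", "b"]), y)
            beta, se = newton_logistic(X, y)
            assert model.intercept == pytest.approx(beta[0], abs=1e-5)
            assert model.terms[0].coefficient == pytest.approx(beta[1], abs=1e-5)
            assert model.terms[1].coefficient == pytest.approx(beta[2], abs=1e-5)
            assert model.terms[0].std_error == pytest.approx(se[1], rel=1e-3)

    def test_coefficients_reported_on_raw_scale(self, rng):
        # pM-scale columns of order 1e-2: slope must be of order 1e2
        n = 300
        x = rng.normal(0.0, 0.01, size=n) + 0.05
        y = (rng.random(n) < 1 / (1 + np.exp(-(100 * (x - 0.05))))).astype(int)
        model = fit_logistic(pd.DataFrame({"x": x}), y)
        beta, _ = newton_logistic(x[:, None], y)
        assert model.terms[0].coefficient == pytest.approx(beta[1], rel=1e-4)

    def test_one_term_auc_invariant_to_positive_rescaling(self, rng):
        n = 150
        x = 10 ** rng.normal(0.0, 0.5, size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-np.log10(x)))).astype(int)
        auc1 = fit_logistic(pd.DataFrame({"x": x}), y).auc
        auc2 = fit_logistic(pd.DataFrame({"x": 1e6 * x}), y).auc
        assert auc1 == pytest.approx(auc2, abs=1e-12)


def product_cohort(seed=0, n=200, n_noise=2):
    """Signal lives only in the product X1*X2; both marginals are weak.

    X1 = 10^(a-b), X2 = 10^(a+b) with sd(b) >> sd(a): the product 10^(2a)
    carries the outcome signal while each factor is dominated by b.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.15, n)
    b = rng.normal(0, 1.5, n)
    cols = {"X1": 10 ** (1.0 + a - b), "X2": 10 ** (0.5 + a + b)}
    for i in range(n_noise):
        cols[f"N{i}"] = 10 ** rng.normal(0.8, 0.5, n)
    y = rng.random(n) < 1 / (1 + np.exp(-3 * a / 0.15))
    matrix = make_molar(cols)
    return matrix, assignment_from_bool(y, matrix.values.index), y


class TestForwardSelect:
    def test_planted_single_marker_selected_first_with_high_auc(self, rng):
        n = 363
        y = rng.random(n) < 0.3
        cols = {f"N{i}": 10 ** rng.normal(0.5, 0.5, n) for i in range(10)}
        cols["MARK"] = 10 ** (rng.normal(0.5, 0.4, n) + 1.5 * y)
        matrix = make_molar(cols)
        model = forward_select(matrix, assignment_from_bool(y, matrix.values.index), "High")
        assert model.term_ids[0] == "MARK"
        assert model.auc > 0.95
        assert model.all_terms_significant()

    def test_pure_noise_panel_falls_back_to_intercept_only(self, rng):
        n = 80
        y = np.array([0, 1] * (n // 2), bool)
        cols = {f"N{i}": 10 ** rng.normal(0.0, 0.5, n) for i in range(3)}
        matrix = make_molar(cols)
        model = forward_select(
            matrix,
            assignment_from_bool(y, matrix.values.index),
            "High",
            allow_products=False,
        )
        if model.terms:  # a noise term may be spuriously significant
            assert model.all_terms_significant()
        else:
            assert model.converged is False

    def test_product_only_signal_recovered_as_product_term(self):
        matrix, assignment, _ = product_cohort(seed=0)
        model = forward_select(matrix, assignment, "High", allow_products=True)
        assert any("*" in t for t in model.term_ids)
        # the product model beats every single-term fit
        singles = [
            fit_logistic(build_design(matrix, [t]), assignment.labels == "High").auc
            for t in matrix.analyte_ids
        ]
        assert model.auc > max(singles)

    def test_unknown_target_rejected(self, rng):
        matrix = make_molar({"A": 10 ** rng.normal(size=10)})
        labels = pd.Series(["Low"] * 5 + ["High"] * 5, index=matrix.values.index)
        assignment = SubgroupAssignment.from_labels(labels, ["Low", "High"])
        with pytest.raises(ValueError):
            forward_select(matrix, assignment, "Medium")


class TestPermutationAUC:
    def test_same_seed_reproduces_null_distribution(self, rng):
        matrix, assignment, _ = product_cohort(seed=3, n=100)
        r1 = permutation_auc_test(matrix, assignment, "High", ["X1*X2"], 20, seed=9)
        r2 = permutation_auc_test(matrix, assignment, "High", ["X1*X2"], 20, seed=9)
        assert np.array_equal(r1.null_aucs, r2.null_aucs)

    def test_null_centred_near_half_and_strong_signal_significant(self):
        matrix, assignment, _ = product_cohort(seed=4, n=200)
        res = permutation_auc_test(
            matrix, assignment, "High", ["X1*X2"], n_perm=100, seed=11
        )
        # refit optimism keeps the null slightly above 1/2
        assert 0.47 <= res.null_mean <= 0.56
        assert res.observed_auc > res.null_max
        assert res.p_empirical < 0.01
        assert res.p_empirical == pytest.approx(1 / 101)
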