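"""Penalized logistic solvers: oracle equivalence, sparsity structure,
standardization hygiene and serialization."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from adtransfer import (
    FeatureTable,
    PenalizedLogisticModel,
    apply_standardization,
    fit_elastic_net_logistic,
    fit_group_lasso_logistic,
    fit_standardization,
    lambda_grid_group_lasso,
    predict_scores,
)
from adtransfer.classifiers import StandardizationParams


def _logit_oracle(X, y):
    """Unpenalized Newton-Raphson logistic fit on standardized features."""
    Xs = (X - X.mean(0)) / X.std(0)
    res = sm.Logit(y, sm.add_constant(Xs)).fit(disp=0)
    return res.params[1:], res.params[0]


@pytest.fixture()
def toy_problem(rng):
    n = 300
    X = rng.standard_normal((n, 4))
    eta = X @ np.array([1.2, -0.8, 0.0, 0.5]) - 0.3
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y


class TestStandardization:
    def test_fit_rows_become_standard(self, rng):
        X = rng.normal(3.0, 2.0, (50, 6))
        params = fit_standardization(X)
        Z = apply_standardization(X, params)
        assert np.allclose(Z.mean(0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(0), 1.0, atol=1e-12)

    def test_shifted_test_set_mean(self, rng):
        X = rng.standard_normal((200, 3))
        params = fit_standardization(X)
        Z = apply_standardization(X + 2.0, params)
        expected = (2.0 + X.mean(0) - params.means) / params.sds
        assert np.allclose(Z.mean(0), expected, atol=0.02)

    def test_constant_column_dropped(self, rng):
        X = np.column_stack([rng.standard_normal(30), np.full(30, 5.0)])
        params = fit_standardization(X, ["var", "const"])
        assert params.dropped == ["const"]
        model = fit_elastic_net_logistic(X, (rng.random(30) < 0.5).astype(int),
                                         alpha=0.5, lam=0.1,
                                         feature_names=["var", "const"])
        assert model.feature_names == ["var"]
        assert len(model.weights) == 1


class TestElasticNet:
    def test_unpenalized_matches_newton_oracle(self, toy_problem):
        X, y = toy_problem
        w_ref, b_ref = _logit_oracle(X, y)
        model = fit_elastic_net_logistic(X, y, alpha=0.5, lam=0.0)
        assert np.abs(model.weights - w_ref).max() < 1e-4
        assert abs(model.intercept - b_ref) < 1e-4

    def test_full_penalty_closed_form(self, toy_problem):
        X, y = toy_problem
        model = fit_elastic_net_logistic(X, y, alpha=0.7, lam=50.0)
        assert np.count_nonzero(model.weights) == 0
        p = y.mean()
        assert model.intercept == pytest.approx(np.log(p / (1 - p)), abs=1e-8)

    def test_ridge_limit_matches_sklearn(self, toy_problem):
        X, y = toy_problem
        lam = 0.05
        model = fit_elastic_net_logistic(X, y, alpha=0.0, lam=lam)
        Xs = (X - X.mean(0)) / X.std(0)
        ref = LogisticRegression(penalty="l2", C=1.0 / (len(y) * lam),
                                 solver="lbfgs", tol=1e-12, max_iter=5000)
        ref.fit(Xs, y)
        assert np.abs(model.weights - ref.coef_[0]).max() < 1e-4
        assert abs(model.intercept - ref.intercept_[0]) < 1e-4

    def test_lasso_support_recovery(self):
        hits, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p_inf, p_noise = 300, 5, 45
            X = rng.standard_normal((n, p_inf + p_noise))
            eta = X[:, :p_inf] @ np.full(p_inf, 1.0)
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            model = fit_elastic_net_logistic(X, y, alpha=1.0, lam=0.05)
            zero = np.flatnonzero(model.weights == 0)
            total += len(zero)
            hits += (zero >= p_inf).sum()
        assert total > 0 and hits / total >= 0.8

    def test_objective_monotone_and_deviance_path(self, toy_problem):
        X, y = toy_problem
        deviances = []
        for lam in [1.0, 0.3, 0.1, 0.03, 0.01, 0.0]:
            model = fit_elastic_net_logistic(X, y, alpha=0.5, lam=lam)
            hist = np.array(model.objective_history)
            assert (np.diff(hist) <= 1e-10).all()
            scores = predict_scores(model, X)
            eps = 1e-12
            deviances.append(-np.mean(y * np.log(scores + eps)
                                      + (1 - y) * np.log(1 - scores + eps)))
        assert all(a >= b - 1e-8 for a, b in zip(deviances, deviances[1:]))

    @pytest.mark.parametrize("bad", [dict(alpha=1.5, lam=0.1),
                                     dict(alpha=0.5, lam=-1.0)])
    def test_invalid_hyperparameters_rejected(self, toy_problem, bad):
        X, y = toy_problem
        with pytest.raises(ValueError):
            fit_elastic_net_logistic(X, y, **bad)

    def test_non_binary_outcome_rejected(self, toy_problem):
        X, _ = toy_problem
        with pytest.raises(ValueError, match="0/1"):
            fit_elastic_net_logistic(X, np.arange(len(X)), alpha=0.5, lam=0.1)


class TestGroupLasso:
    def test_unpenalized_matches_newton_oracle(self, toy_problem):
        X, y = toy_problem
        w_ref, b_ref = _logit_oracle(X, y)
        model = fit_group_lasso_logistic(X, y, groups=[0, 0, 1, 1], lam=0.0)
        assert np.abs(model.weights - w_ref).max() < 1e-4
        assert abs(model.intercept - b_ref) < 1e-4

    def test_full_penalty_intercept_only(self, toy_problem):
        X, y = toy_problem
        model = fit_group_lasso_logistic(X, y, groups=[0, 0, 1, 1], lam=50.0)
        assert np.count_nonzero(model.weights) == 0
        p = y.mean()
        assert model.intercept == pytest.approx(np.log(p / (1 - p)), abs=1e-6)

    def test_noise_group_block_zeroed(self):
        successes = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 400
            signal = rng.standard_normal((n, 5))
            noise = rng.standard_normal((n, 5))
            eta = signal @ np.full(5, 1.0 / np.sqrt(5))
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            X = np.hstack([signal, noise])
            groups = [0] * 5 + [1] * 5
            grid = lambda_grid_group_lasso(X, y, np.array(groups), n_lambdas=8,
                                           decades=2.0)
            for lam in grid:
                m = fit_group_lasso_logistic(X, y, groups=groups, lam=lam)
                w_signal, w_noise = m.weights[:5], m.weights[5:]
                if np.all(w_noise == 0.0) and np.any(w_signal != 0.0):
                    successes += 1
                    break
        assert successes >= 18

    def test_blocks_all_or_none(self, rng):
        X = rng.standard_normal((150, 9))
        y = (rng.random(150) < 0.5).astype(int)
        groups = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        for lam in [0.01, 0.05, 0.2]:
            m = fit_group_lasso_logistic(X, y, groups=groups, lam=lam)
            for g in range(3):
                block = m.weights[3 * g:3 * g + 3]
                assert np.all(block == 0.0) or np.all(block != 0.0)

    def test_empty_group_rejected(self, rng):
        X = rng.standard_normal((20, 2))
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError):
            fit_group_lasso_logistic(X, y, groups=None, lam=0.1)


class TestPredict:
    def test_intercept_only_gives_half(self):
        params = StandardizationParams(["a", "b"], np.zeros(2), np.ones(2),
                                       keep_indices=np.arange(2))
        model = PenalizedLogisticModel("elastic_net", np.zeros(2), 0.0,
                                       {}, params)
        scores = predict_scores(model, np.array([[3.0, -1.0], [0.5, 2.0]]))
        assert np.allclose(scores, 0.5)

    def test_hand_computed_example(self):
        # standardized input (1, 1), weights (2, -1), intercept -1 -> logistic(0)
        params = StandardizationParams(["a", "b"], np.zeros(2), np.ones(2),
                                       keep_indices=np.arange(2))
        model = PenalizedLogisticModel("elastic_net", np.array([2.0, -1.0]),
                                       -1.0, {}, params)
        assert predict_scores(model, np.array([[1.0, 1.0]]))[0] == pytest.approx(0.5)

    def test_duplicate_rows_score_identically(self, toy_problem):
        X, y = toy_problem
        model = fit_elastic_net_logistic(X, y, alpha=0.5, lam=0.05)
        s = predict_scores(model, np.vstack([X[:1], X[:1]]))
        assert s[0] == s[1]
        assert 0.0 < s[0] < 1.0

    def test_invariant_to_dropped_columns(self, rng):
        X = np.column_stack([rng.standard_normal(60), np.full(60, 2.0),
                             rng.standard_normal(60)])
        y = (rng.random(60) < 0.5).astype(int)
        names = ["a", "const", "b"]
        model = fit_elastic_net_logistic(X, y, alpha=0.5, lam=0.1,
                                         feature_names=names)
        tab = FeatureTable(pd.DataFrame(X, columns=names),
                           {n: "ALFF" for n in names})
        s_tab = predict_scores(model, tab)
        s_arr = predict_scores(model, X)
        assert np.allclose(s_tab, s_arr)

    def test_missing_model_feature_rejected(self, rng):
        X = rng.standard_normal((40, 2))
        y = (rng.random(40) < 0.5).astype(int)
        model = fit_elastic_net_logistic(X, y, alpha=0.5, lam=0.1,
                                         feature_names=["a", "b"])
        tab = FeatureTable(pd.DataFrame(X[:, :1], columns=["a"]), {"a": "ALFF"})
        with pytest.raises(KeyError, match="missing"):
            predict_scores(model, tab)


class TestSerialization:
    def test_json_round_trip(self, toy_problem, tmp_path):
        X, y = toy_problem
        model = fit_group_lasso_logistic(X, y, groups=[0, 0, 1, 1], lam=0.03)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = PenalizedLogisticModel.from_json(path)
        assert np.allclose(predict_scores(loaded, X), predict_scores(model, X))
        assert loaded.hyperparameters == model.hyperparameters
        assert loaded.group_of == model.group_of
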