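"""Baseline models: penalized logistic/Cox fits, mRMR, grid-search tuning."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.metrics import mutual_info_score, roc_auc_score

from hncprog.baselines import (cox_partial_loglik, fit_cox, fit_logistic,
                               logistic_objective, mrmr_select,
                               tune_by_grid_cv, volume_only_model)


class TestLogistic:
    def test_all_zero_features_predict_prevalence(self, rng):
        y = (rng.random(200) < 0.3).astype(int)
        lm = fit_logistic(np.zeros((200, 3)), y, l2_strength=1.0)
        assert np.allclose(lm.predict_prob(np.zeros((5, 3))), y.mean(),
                           atol=1e-6)
        assert np.allclose(lm.coefficients, 0.0, atol=1e-8)

    def test_separation_stays_finite_with_penalty(self):
        x = np.repeat([0.0, 1.0], 30)[:, None]
        y = np.repeat([0, 1], 30)
        lm = fit_logistic(x, y, l2_strength=0.5)
        assert np.isfinite(lm.coefficients).all()
        assert roc_auc_score(y, lm.predict_prob(x)) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((10, 1)), np.ones(10, int))

    def test_matches_independent_optimizer(self, rng):
        # oracle: direct scipy minimization of the same penalized loss
        for l2 in (0.5, 2.0):
            X = rng.normal(size=(80, 3))
            y = (rng.random(80) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
            lm = fit_logistic(X, y, l2_strength=l2)
            ours = logistic_objective(lm.coefficients, lm.intercept, X, y, l2)

            def loss(theta):
                return logistic_objective(theta[:-1], theta[-1], X, y, l2)

            oracle = minimize(loss, np.zeros(4), method="BFGS",
                              options={"gtol": 1e-10}).fun
            assert ours == pytest.approx(oracle, abs=1e-4)


class TestCox:
    def test_partial_loglik_hand_example(self):
        # 5 patients, distinct times, binary covariate; risk sets written
        # out explicitly.  Events at t=1 (x=1), t=2 (x=0), t=4 (x=1);
        # censored at t=3, t=5.
        X = np.array([[1.0], [0.0], [1.0], [0.0], [1.0]])
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 0, 1, 0])
        beta = 0.7
        r = np.exp(beta * X.ravel())
        expected = (np.log(r[0] / r.sum())
                    + np.log(r[1] / r[1:].sum())
                    + np.log(r[3] / r[3:].sum()))
        assert cox_partial_loglik(X, t, e, [beta]) == pytest.approx(expected)

    def test_fit_maximizes_penalized_partial_likelihood(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(120, 1))
        t = rng.exponential(10 * np.exp(-0.8 * X.ravel()))
        t = np.maximum(t, 1e-3)
        e = np.ones(120, int)
        l2 = 0.1
        lm = fit_cox(X, t, e, l2_strength=l2)
        beta_hat = lm.coefficients

        def penalized(b):
            return cox_partial_loglik(X, t, e, [b]) - 0.5 * l2 * 120 * b ** 2

        # lifelines scales its penalty by n; the optimum must dominate
        # nearby values of the same objective
        center = penalized(beta_hat[0])
        assert center >= penalized(beta_hat[0] + 0.05) - 1e-6
        assert center >= penalized(beta_hat[0] - 0.05) - 1e-6

    def test_null_effect_gives_near_zero_coefficient(self, rng):
        X = rng.normal(size=(500, 2))
        t = rng.exponential(10, 500)
        lm = fit_cox(X, t, np.ones(500, int), l2_strength=0.1)
        assert np.abs(lm.coefficients).max() < 0.15

    def test_protective_effect_recovered_negative(self, rng):
        X = rng.normal(size=(400, 1))
        t = rng.exponential(5 * np.exp(1.0 * X.ravel()))  # beta = -1
        lm = fit_cox(X, np.maximum(t, 1e-3), np.ones(400, int),
                     l2_strength=0.01)
        assert lm.coefficients[0] < -0.5

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox(np.zeros((5, 1)), np.ones(5), np.zeros(5, int))

    def test_constant_column_gets_zero_coefficient(self, rng):
        X = np.column_stack([rng.normal(size=100), np.zeros(100)])
        lm = fit_cox(X, rng.exponential(5, 100), np.ones(100, int))
        assert lm.coefficients[1] == 0.0


class TestMRMR:
    def test_single_pick_maximizes_relevance(self, rng):
        y = rng.integers(0, 2, 300)
        weak = rng.normal(size=300)
        strong = y + 0.3 * rng.normal(size=300)
        F = np.column_stack([weak, strong])
        sel = mrmr_select(F, y, m=1)
        assert sel.selected_indices == [1]

    def test_duplicate_feature_skipped_for_weaker_independent(self, rng):
        y = rng.integers(0, 2, 500)
        strong = y + 0.3 * rng.normal(size=500)
        duplicate = strong + 1e-9 * rng.normal(size=500)
        weaker = y + 1.5 * rng.normal(size=500)
        F = np.column_stack([strong, duplicate, weaker])
        sel = mrmr_select(F, y, m=2)
        assert sel.selected_indices[0] in (0, 1)
        assert sel.selected_indices[1] == 2  # redundancy kills the copy

    def test_selecting_all_features_exhausts(self, rng):
        F = rng.normal(size=(100, 6))
        y = rng.integers(0, 2, 100)
        sel = mrmr_select(F, y, m=6)
        assert sorted(sel.selected_indices) == list(range(6))

    def test_no_redundancy_reduces_to_relevance_ranking(self, rng):
        F = rng.normal(size=(200, 5))
        y = (rng.random(200) < 1 / (1 + np.exp(-F[:, 2]))).astype(int)
        sel = mrmr_select(F, y, m=5, redundancy_weight=0.0)
        # oracle: rank by marginal mutual information on the same bins
        from hncprog.baselines import _equal_frequency_bins
        mi = [mutual_info_score(_equal_frequency_bins(F[:, j], 8), y)
              for j in range(5)]
        assert sel.selected_indices == list(np.argsort(mi)[::-1])

    def test_invalid_m_rejected(self, rng):
        F = rng.normal(size=(50, 3))
        y = rng.integers(0, 2, 50)
        with pytest.raises(ValueError):
            mrmr_select(F, y, m=0)
        with pytest.raises(ValueError):
            mrmr_select(F, y, m=4)


class TestGridCV:
    @staticmethod
    def _fit_predict(X_train, y_train, X_val, l2_strength):
        lm = fit_logistic(X_train, y_train, l2_strength)
        return lm.predict_prob(X_val)

    def test_one_point_grid_returned(self, rng):
        X = rng.normal(size=(100, 2))
        y = (rng.random(100) < 0.5).astype(int)
        best, results = tune_by_grid_cv(self._fit_predict, X, y,
                                        {"l2_strength": [2.0]})
        assert best == {"l2_strength": 2.0}
        assert len(results) == 1

    def test_selected_config_attains_maximal_score(self, rng):
        X = rng.normal(size=(300, 4))
        y = (rng.random(300) < 1 / (1 + np.exp(-2 * X[:, 0]))).astype(int)
        best, results = tune_by_grid_cv(
            self._fit_predict, X, y,
            {"l2_strength": [0.01, 1.0, 1e4]}, seed=1)
        assert results["mean_val_auroc"].max() == pytest.approx(
            results.loc[results["l2_strength"] == best["l2_strength"],
                        "mean_val_auroc"].iloc[0])

    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.normal(size=(120, 3))
        y = (rng.random(120) < 0.4).astype(int)
        grid = {"l2_strength": [0.1, 1.0]}
        out1 = tune_by_grid_cv(self._fit_predict, X, y, grid, seed=7)
        out2 = tune_by_grid_cv(self._fit_predict, X, y, grid, seed=7)
        assert out1[0] == out2[0]
        assert out1[1].equals(out2[1])

    def test_ties_break_toward_stronger_regularization(self, rng):
        # stub fit ignores the configuration entirely -> exact ties
        def stub(X_train, y_train, X_val, l2_strength):
            return X_val[:, 0]

        X = rng.normal(size=(100, 2))
        y = (rng.random(100) < 0.5).astype(int)
        best, _ = tune_by_grid_cv(stub, X, y,
                                  {"l2_strength": [0.1, 1.0, 10.0]})
        assert best == {"l2_strength": 10.0}

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            tune_by_grid_cv(self._fit_predict, np.zeros((10, 1)),
                            np.zeros(10, int), {})


class TestVolumeOnly:
    def test_equivalent_to_logistic_on_standardized_column(self, rng):
        volume = np.exp(rng.normal(3, 1, 300))
        y = (rng.random(300) < 0.3).astype(int)
        lm = volume_only_model(volume, y=y, l2_strength=1.0)
        logv = np.log(volume)
        x = ((logv - logv.mean()) / logv.std())[:, None]
        ref = fit_logistic(x, y, l2_strength=1.0)
        assert lm.coefficients == pytest.approx(ref.coefficients, abs=1e-8)
        assert lm.intercept == pytest.approx(ref.intercept, abs=1e-8)

    def test_strong_volume_effect_detected(self, rng):
        volume = np.exp(rng.normal(3, 1, 1000))
        logit = 2.0 * (np.log(volume) - 3.0) - 1.0
        y = (rng.random(1000) < 1 / (1 + np.exp(-logit))).astype(int)
        lm = volume_only_model(volume, y=y)
        logv = np.log(volume)
        x = ((logv - logv.mean()) / logv.std())[:, None]
        assert roc_auc_score(y, lm.predict_prob(x)) > 0.7

    def test_null_volume_effect_near_chance(self, rng):
        volume = np.exp(rng.normal(3, 1, 2000))
        y = (rng.random(2000) < 0.3).astype(int)
        lm = volume_only_model(volume, y=y)
        logv = np.log(volume)
        x = ((logv - logv.mean()) / logv.std())[:, None]
        assert abs(roc_auc_score(y, lm.predict_prob(x)) - 0.5) < 0.05

    def test_cox_variant(self, rng):
        volume = np.exp(rng.normal(3, 1, 200))
        t = rng.exponential(10, 200)
        lm = volume_only_model(volume, time=t, event=np.ones(200, int))
        assert lm.model_kind == "cox_ph"


class TestRankInvariance:
    def test_logistic_ranking_invariant_to_feature_rescaling(self, rng):
        # near-unpenalized fits: affine rescaling of one column must not
        # change the predicted ranking
        X = rng.normal(size=(150, 3))
        y = (rng.random(150) < 1 / (1 + np.exp(-X[:, 0] + X[:, 1]))
             ).astype(int)
        lm1 = fit_logistic(X, y, l2_strength=1e-6)
        X2 = X.copy()
        X2[:, 1] = 10.0 * X2[:, 1] + 5.0
        lm2 = fit_logistic(X2, y, l2_strength=1e-6)
        assert np.array_equal(np.argsort(lm1.predict_prob(X)),
                              np.argsort(lm2.predict_prob(X2)))
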