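"""Metrics and inference: enumeration oracles, resampling, stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hncprog.evaluation import (MetricResult, auroc, average_precision,
                                c_index, cohort_shift_test, compare_models,
                                fdr_adjust, km_stratify, metric_agreement,
                                permutation_test, stratified_bootstrap_ci,
                                volume_dependence)


from oracles import ap_oracle, auroc_oracle, c_index_oracle


def random_binary_instance(rng, n=None):
    n = n or int(rng.integers(4, 21))
    labels = rng.integers(0, 2, n)
    labels[0], labels[-1] = 1, 0  # guarantee both classes
    scores = np.round(rng.random(n), 2)  # rounding forces some ties
    return scores, labels


class TestPointMetrics:
    def test_perfect_ranking(self):
        assert auroc(np.array([0.9, 0.8, 0.2, 0.1]),
                     np.array([1, 1, 0, 0])) == 1.0
        assert average_precision(np.array([0.9, 0.8, 0.2, 0.1]),
                                 np.array([1, 1, 0, 0])) == 1.0

    def test_constant_risk_cindex_half(self):
        assert c_index(np.ones(6), np.arange(1.0, 7.0),
                       np.ones(6, int)) == 0.5

    def test_risk_equal_minus_time_is_perfectly_concordant(self, rng):
        t = rng.uniform(1, 30, 15)
        assert c_index(-t, t, np.ones(15, int)) == 1.0

    def test_binary_metrics_match_sklearn(self, rng):
        # independent cross-check against the reference library routines
        from sklearn.metrics import average_precision_score, roc_auc_score
        for _ in range(100):
            s, y = random_binary_instance(rng, n=60)
            assert auroc(s, y) == pytest.approx(roc_auc_score(y, s),
                                                abs=1e-12)
            assert average_precision(s, y) == pytest.approx(
                average_precision_score(y, s), abs=1e-12)

    def test_auroc_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            s, y = random_binary_instance(rng)
            assert auroc(s, y) == pytest.approx(auroc_oracle(s, y))

    def test_ap_matches_threshold_oracle(self, rng):
        for _ in range(200):
            s, y = random_binary_instance(rng)
            assert average_precision(s, y) == pytest.approx(ap_oracle(s, y))

    def test_cindex_matches_pair_oracle(self, rng):
        # continuous times (no time ties, where conventions diverge);
        # rounded risks exercise the half-credit tie rule
        for _ in range(200):
            n = int(rng.integers(4, 16))
            t = rng.uniform(1, 30, n)
            e = rng.integers(0, 2, n)
            e[np.argmin(t)] = 1  # guarantees a comparable pair
            r = np.round(rng.random(n), 2)
            assert c_index(r, t, e) == pytest.approx(c_index_oracle(r, t, e))

    def test_metrics_invariant_under_monotone_transform(self, rng):
        s, y = random_binary_instance(rng, n=40)
        for f in (lambda x: 3 * x + 1, np.exp, lambda x: x ** 3):
            assert auroc(f(s), y) == pytest.approx(auroc(s, y))
            assert average_precision(f(s), y) == pytest.approx(
                average_precision(s, y))

    def test_auroc_flips_under_negation(self, rng):
        s = rng.random(50)  # continuous, no ties
        y = rng.integers(0, 2, 50)
        y[:5] = 1
        y[-5:] = 0
        assert auroc(-s, y) == pytest.approx(1.0 - auroc(s, y))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc(np.array([0.1, 0.2]), np.array([1, 1]))
        with pytest.raises(ValueError):
            average_precision(np.array([0.1, 0.2]), np.array([0, 0]))

    def test_mean_ap_of_random_scores_near_prevalence(self, rng):
        # AP of a random ranker converges to prevalence from above; the
        # small positive finite-sample bias shrinks with n
        prevalence, aps = 0.3, []
        for _ in range(300):
            y = (rng.random(1000) < prevalence).astype(int)
            if 0 < y.sum() < 1000:
                aps.append(average_precision(rng.random(1000), y))
        assert np.mean(aps) == pytest.approx(prevalence, abs=0.02)
        assert np.mean(aps) > prevalence  # bias direction


class TestBootstrap:
    def test_constant_metric_zero_width(self, rng):
        s, y = random_binary_instance(rng, n=30)
        res = stratified_bootstrap_ci(lambda s_, y_: 0.7, s, y, n_boot=50)
        assert res.ci_low == res.ci_high == res.estimate == 0.7

    def test_same_seed_identical_interval(self, rng):
        s, y = random_binary_instance(rng, n=60)
        a = stratified_bootstrap_ci(auroc, s, y, n_boot=200, seed=9)
        b = stratified_bootstrap_ci(auroc, s, y, n_boot=200, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_interval_contains_estimate(self, rng):
        s, y = random_binary_instance(rng, n=80)
        res = stratified_bootstrap_ci(auroc, s, y, n_boot=300, seed=1)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            stratified_bootstrap_ci(auroc, np.array([]), np.array([]),
                                    n_boot=10)


class TestPermutation:
    def test_anti_predictive_scores_large_p(self, rng):
        y = np.repeat([0, 1], 25)
        s = 1.0 - y + 0.01 * rng.random(50)  # perfectly wrong
        p = permutation_test(auroc, s, y, n_perm=99, seed=0)
        assert p > 0.9

    def test_add_one_smoothing_lower_bound(self, rng):
        y = np.repeat([0, 1], 25)
        s = y + 0.01 * rng.random(50)
        p = permutation_test(auroc, s, y, n_perm=99, seed=0)
        assert p >= 1.0 / 100.0

    def test_deterministic_under_seed(self, rng):
        s, y = random_binary_instance(rng, n=40)
        assert permutation_test(auroc, s, y, n_perm=99, seed=5) == \
            permutation_test(auroc, s, y, n_perm=99, seed=5)


class TestCompareModels:
    def test_identical_scores_give_p_one(self, rng):
        s, y = random_binary_instance(rng, n=60)
        assert compare_models(s, s, y, n_boot=100, seed=0) == 1.0

    def test_truth_vs_noise_strongly_significant(self, rng):
        n = 500
        y = (rng.random(n) < 0.3).astype(int)
        truth = y + 0.2 * rng.random(n)
        noise = rng.random(n)
        assert compare_models(truth, noise, y, n_boot=500, seed=0) < 0.01

    def test_deterministic_and_mismatch_rejected(self, rng):
        s, y = random_binary_instance(rng, n=40)
        s2 = rng.random(40)
        assert compare_models(s, s2, y, n_boot=100, seed=3) == \
            compare_models(s, s2, y, n_boot=100, seed=3)
        with pytest.raises(ValueError):
            compare_models(s, s2[:-1], y)


class TestFDR:
    def test_single_small_p_rejected(self):
        reject, p_adj = fdr_adjust([0.01], q=0.05)
        assert reject[0]
        assert p_adj[0] == pytest.approx(0.01)

    def test_all_ones_never_rejected(self):
        reject, _ = fdr_adjust(np.ones(10))
        assert not reject.any()

    def test_matches_step_up_definition(self, rng):
        # oracle: literal Benjamini-Hochberg step-up rule
        for _ in range(50):
            p = np.round(rng.random(int(rng.integers(2, 12))), 3)
            reject, _ = fdr_adjust(p, q=0.05)
            m = len(p)
            order = np.argsort(p)
            k_max = 0
            for rank, idx in enumerate(order, start=1):
                if p[idx] <= 0.05 * rank / m:
                    k_max = rank
            expected = np.zeros(m, bool)
            expected[order[:k_max]] = True
            assert np.array_equal(reject, expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestStratification:
    def test_km_without_censoring_is_empirical_survival(self, rng):
        t = np.concatenate([rng.uniform(1, 10, 40), rng.uniform(20, 40, 40)])
        e = np.ones(80, int)
        prob = np.concatenate([np.full(40, 0.9), np.full(40, 0.1)])
        res = km_stratify(prob, t, e, threshold=0.5)
        curve = res.km_curves["high_risk"]
        for _, row in curve.iloc[1:].iterrows():
            empirical = np.mean(t[prob >= 0.5] > row["time"])
            assert row["survival"] == pytest.approx(empirical, abs=1e-9)

    def test_hazard_ratio_three_recovered(self, rng):
        n = 1000
        t = np.concatenate([rng.exponential(10.0, n),
                            rng.exponential(30.0, n)])  # HR = 3
        e = np.ones(2 * n, int)
        prob = np.concatenate([np.full(n, 0.8), np.full(n, 0.2)])
        res = km_stratify(prob, t, e)
        assert 2.4 < res.hazard_ratio < 3.75
        assert res.logrank_p < 1e-10

    def test_identical_groups_hr_near_one(self, rng):
        t = rng.exponential(10.0, 1000)
        prob = rng.permutation(np.repeat([0.2, 0.8], 500))
        res = km_stratify(prob, t, np.ones(1000, int))
        assert 0.85 < res.hazard_ratio < 1.18
        assert res.logrank_p > 0.01

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            km_stratify(np.full(10, 0.9), rng.uniform(1, 5, 10),
                        np.ones(10, int))


class TestVolumeDependence:
    def test_monotone_prediction_has_rho_one(self, rng):
        v = np.exp(rng.normal(3, 1, 50))
        table = volume_dependence({"m": np.log(v) ** 3}, v)
        assert table["spearman_rho"].iloc[0] == pytest.approx(1.0)

    def test_independent_prediction_near_zero(self, rng):
        v = np.exp(rng.normal(3, 1, 2000))
        table = volume_dependence({"m": rng.random(2000)}, v)
        assert abs(table["spearman_rho"].iloc[0]) < 0.08

    def test_matches_rank_pearson_oracle(self, rng):
        v = rng.uniform(1, 100, 10)
        preds = rng.random(10)
        table = volume_dependence({"m": preds}, v)
        oracle = stats.pearsonr(stats.rankdata(preds),
                                stats.rankdata(v)).statistic
        assert table["spearman_rho"].iloc[0] == pytest.approx(oracle)

    def test_constant_predictions_rejected(self, rng):
        with pytest.raises(ValueError):
            volume_dependence({"m": np.ones(10)}, rng.uniform(1, 9, 10))


class TestCohortShift:
    def test_two_by_two_matches_hand_chi2(self):
        a = pd.DataFrame({"v": ["X"] * 10 + ["Y"] * 20})
        b = pd.DataFrame({"v": ["X"] * 20 + ["Y"] * 10})
        out = cohort_shift_test(a, b, ["v"])
        # chi2 = n (ad - bc)^2 / (row and column margins) = 20/3
        assert out["chi2"].iloc[0] == pytest.approx(20.0 / 3.0)

    def test_identical_cohorts_not_flagged(self, small_cohort):
        out = cohort_shift_test(small_cohort, small_cohort.copy(),
                                ["sex", "t_stage", "hpv_status"])
        assert not out["shifted"].any()
        assert (out["p_value"] > 0.99).all()

    def test_prevalence_shift_detected_others_spared(self, rng):
        n = 5000
        a = pd.DataFrame({
            "hpv": rng.choice(["pos", "neg"], n, p=[0.6, 0.4]),
            "sex": rng.choice(["M", "F"], n, p=[0.7, 0.3])})
        b = pd.DataFrame({
            "hpv": rng.choice(["pos", "neg"], n, p=[0.2, 0.8]),
            "sex": rng.choice(["M", "F"], n, p=[0.7, 0.3])})
        out = cohort_shift_test(a, b, ["hpv", "sex"]).set_index("variable")
        assert out.loc["hpv", "shifted"]
        assert not out.loc["sex", "shifted"]


class TestMetricAgreement:
    def test_identical_columns_perfectly_correlated(self):
        table = pd.DataFrame({"auroc": [0.7, 0.8, 0.9],
                              "ap": [0.7, 0.8, 0.9],
                              "c_index": [0.6, 0.7, 0.8]})
        out = metric_agreement(table)
        assert out[("auroc", "ap")] == pytest.approx(1.0)
        assert out[("auroc", "c_index")] == pytest.approx(1.0)

    def test_three_point_hand_example(self):
        table = pd.DataFrame({"auroc": [1.0, 2.0, 3.0],
                              "ap": [2.0, 4.0, 6.0],
                              "c_index": [3.0, 2.0, 1.0]})
        out = metric_agreement(table)
        assert out[("auroc", "ap")] == pytest.approx(1.0)
        assert out[("auroc", "c_index")] == pytest.approx(-1.0)

    def test_too_few_models_rejected(self):
        with pytest.raises(ValueError):
            metric_agreement(pd.DataFrame({"auroc": [0.7, 0.8],
                                           "ap": [0.4, 0.5],
                                           "c_index": [0.6, 0.7]}))


class TestMetricResult:
    def test_estimate_must_lie_in_interval(self):
        with pytest.raises(ValueError):
            MetricResult("auroc", estimate=0.9, ci_low=0.1, ci_high=0.5)

    def test_format(self):
        r = MetricResult("auroc", 0.823, 0.777, 0.866, n_boot=100)
        assert "0.823" in str(r)
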