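"""Propensity weighting and weighted survival contrasts."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.special import expit

import itesurv as its
from itesurv.iptw import PropensityFit, arr_at, drmst


class TestPropensity:
    def test_null_model_recovers_prevalence(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2000, 3))
        y = rng.integers(0, 2, 2000)
        fit = its.estimate_propensity(X, y)
        assert np.all(np.abs(fit.probabilities - 0.5) < 0.05)

    def test_single_binary_covariate_matches_2x2_log_odds_ratio(self):
        # counts: x=1 -> 40/60 in group 1; x=0 -> 20/80
        x = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(40), np.zeros(60), np.ones(20), np.zeros(80)]
        fit = its.estimate_propensity(x[:, None], y)
        lor = np.log((40 * 80) / (60 * 20))
        assert fit.coefficients.iloc[1] == pytest.approx(lor, abs=1e-6)

    def test_duplicated_rows_leave_fit_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 2))
        y = (rng.random(300) < expit(X[:, 0])).astype(int)
        f1 = its.estimate_propensity(X, y)
        f2 = its.estimate_propensity(np.vstack([X, X]), np.r_[y, y])
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-6)

    def test_perfect_separation_raises_with_advice(self):
        x = np.r_[np.zeros(50), np.ones(50)][:, None]
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        with pytest.raises(ValueError, match="separation"):
            its.estimate_propensity(x, y)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            its.estimate_propensity(np.zeros((10, 1)), np.ones(10, int))


class TestWeights:
    def test_probabilities_at_prevalence_give_unit_weights(self):
        y = np.r_[np.ones(30, int), np.zeros(70, int)]
        fit = PropensityFit(pd.Series(dtype=float), np.full(100, 0.3), (0.01, 0.99))
        wv = its.compute_iptw_weights(fit, y)
        np.testing.assert_allclose(wv.weights, 1.0)

    def test_weight_arithmetic(self):
        # group-1 member with P=0.25, prevalence 0.5 -> stabilized weight 2
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        probs = np.full(100, 0.5)
        probs[0] = 0.25
        fit = PropensityFit(pd.Series(dtype=float), probs, (0.01, 0.99))
        wv = its.compute_iptw_weights(fit, y, truncate_percentiles=(0.0, 100.0))
        assert wv.weights[0] == pytest.approx(2.0)

    def test_truncation_bounds_contract(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 500)
        probs = np.clip(rng.beta(2, 2, 500), 0.01, 0.99)
        fit = PropensityFit(pd.Series(dtype=float), probs, (0.01, 0.99))
        wv = its.compute_iptw_weights(fit, y)
        lo, hi = wv.truncation_bounds
        assert np.all(wv.weights >= lo - 1e-12) and np.all(wv.weights <= hi + 1e-12)
        assert np.all(np.isfinite(wv.weights)) and np.all(wv.weights > 0)

    def test_stabilized_weights_average_near_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(3000, 2))
        y = (rng.random(3000) < expit(0.8 * X[:, 0])).astype(int)
        fit = its.estimate_propensity(X, y)
        wv = its.compute_iptw_weights(fit, y, truncate_percentiles=(0.0, 100.0))
        for g in (0, 1):
            assert np.mean(wv.weights[y == g]) == pytest.approx(1.0, abs=0.1)


def _two_group_data(seed=0, n=400, hr=1.0):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (0.02 * hr**g))
    c = rng.exponential(80.0, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return time, event, g


class TestWeightedCox:
    def test_unit_weights_reproduce_classical_fit(self):
        time, event, g = _two_group_data(seed=4)
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(len(g), 2))
        mine = its.weighted_cox_hr(time, event, g, weights=np.ones(len(g)),
                                   adjustment_covariates=Z)
        df = pd.DataFrame({"time": time, "event": event, "group": g, "z0": Z[:, 0], "z1": Z[:, 1]})
        ref = CoxPHFitter().fit(df, "time", "event")
        assert mine.log_hr == pytest.approx(ref.params_["group"], abs=1e-9)

    def test_identical_duplicated_groups_give_unit_hr(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(50, 100)
        e = (rng.random(100) < 0.8).astype(int)
        time = np.r_[t, t]
        event = np.r_[e, e]
        g = np.r_[np.zeros(100, int), np.ones(100, int)]
        res = its.weighted_cox_hr(time, event, g)
        assert res.hr == pytest.approx(1.0, abs=1e-6)

    def test_recovers_true_hazard_ratio(self):
        time, event, g = _two_group_data(seed=7, n=5000, hr=0.5)
        res = its.weighted_cox_hr(time, event, g, weights=np.ones(len(g)))
        assert res.ci[0] < 0.5 < res.ci[1]
        assert np.log(res.ci[1]) - np.log(res.ci[0]) < 0.2

    def test_weight_scale_invariance(self):
        time, event, g = _two_group_data(seed=8)
        w = np.random.default_rng(9).uniform(0.5, 2.0, len(g))
        a = its.weighted_cox_hr(time, event, g, weights=w)
        b = its.weighted_cox_hr(time, event, g, weights=7.0 * w)
        assert a.hr == pytest.approx(b.hr, rel=1e-9)

    def test_group_without_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            its.weighted_cox_hr([1, 2, 3, 4], [1, 1, 0, 0], [0, 0, 1, 1])


class TestWeightedKM:
    def test_equal_weights_match_lifelines(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(10, 80)
        e = (rng.random(80) < 0.7).astype(int)
        mine = its.weighted_km(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            assert mine.at(q)[0] == pytest.approx(kmf.predict(q), abs=1e-12)

    def test_single_subject_step(self):
        c = its.weighted_km([5.0], [1])
        assert c.at(4.99)[0] == 1.0
        assert c.at(5.0)[0] == 0.0

    def test_weighted_four_subject_case_matches_hand_product(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        w = np.array([2.0, 1.0, 1.0, 3.0])
        c = its.weighted_km(t, e, w)
        s1 = 1 - 2 / 7
        s2 = s1 * (1 - 1 / 5)
        s4 = s2 * (1 - 3 / 3)
        np.testing.assert_allclose(c.values[0], [1.0, s1, s2, s4], atol=1e-12)


class TestArrDrmst:
    def _km_pair(self):
        rng = np.random.default_rng(11)
        t1 = rng.exponential(100, 300)
        t0 = rng.exponential(50, 300)
        k1 = its.weighted_km(np.minimum(t1, 120), (t1 <= 120).astype(int))
        k0 = its.weighted_km(np.minimum(t0, 120), (t0 <= 120).astype(int))
        return k1, k0

    def test_identical_curves_zero(self):
        k1, _ = self._km_pair()
        assert arr_at(k1, k1, 60.0) == 0.0
        assert drmst(k1, k1, 60.0) == 0.0

    def test_arr_arithmetic(self):
        t = np.array([0.0, 60.0])
        k1 = its.curves.SurvivalCurves(t, [[1.0, 0.60]], step=True)
        k0 = its.curves.SurvivalCurves(t, [[1.0, 0.45]], step=True)
        # S(60) uses the value attained at 60
        assert arr_at(k1, k0, 60.0) == pytest.approx(15.0)

    def test_antisymmetry(self):
        k1, k0 = self._km_pair()
        assert arr_at(k1, k0) == pytest.approx(-arr_at(k0, k1))
        assert drmst(k1, k0) == pytest.approx(-drmst(k0, k1))

    def test_drmst_converges_to_exponential_closed_form(self):
        rng = np.random.default_rng(12)
        n = 30000
        t1 = rng.exponential(1 / 0.01, n)
        t0 = rng.exponential(1 / 0.02, n)
        k1 = its.weighted_km(t1, np.ones(n, int))
        k0 = its.weighted_km(t0, np.ones(n, int))
        assert drmst(k1, k0, 60.0) == pytest.approx(10.18, abs=0.5)
        assert abs(drmst(k1, k0, 60.0)) <= 60.0


class TestWeightedLogrank:
    def test_identical_duplicated_groups_null(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(10, 50)
        e = (rng.random(50) < 0.8).astype(int)
        stat, p = its.weighted_logrank(np.r_[t, t], np.r_[e, e],
                                       np.r_[np.zeros(50, int), np.ones(50, int)])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_small_unweighted_case_matches_lifelines(self):
        t = np.array([3.0, 5.0, 7.0, 9.0, 18.0, 12.0, 19.0, 20.0, 20.0, 33.0])
        e = np.array([1, 1, 1, 1, 0, 1, 1, 0, 1, 1])
        g = np.r_[np.zeros(5, int), np.ones(5, int)]
        stat, p = its.weighted_logrank(t, e, g)
        ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert stat == pytest.approx(ref.test_statistic, abs=1e-10)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_weight_rescaling_leaves_p_unchanged(self):
        time, event, g = _two_group_data(seed=14)
        w = np.random.default_rng(15).uniform(0.5, 2.0, len(g))
        _, p1 = its.weighted_logrank(time, event, g, weights=w)
        _, p2 = its.weighted_logrank(time, event, g, weights=2.0 * w)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestCauseSpecific:
    def _competing(self, seed=16, n=5000, affects_a=True):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 2, n)
        hr_a = 0.5 if affects_a else 1.0
        ta = rng.exponential(1 / (0.02 * hr_a**g))
        tb = rng.exponential(1 / 0.01, n)
        time = np.minimum(ta, tb)
        cause = np.where(ta <= tb, "A", "B")
        return time, cause, g

    def test_single_cause_reduces_to_all_cause(self):
        time, cause, g = self._competing()
        cause = np.full_like(cause, "A")
        res = its.cause_specific_hr(time, cause, "A", g)
        ref = its.weighted_cox_hr(time, np.ones(len(g), int), g)
        assert res.hr == pytest.approx(ref.hr, rel=1e-9)

    def test_group_affects_only_cause_a(self):
        time, cause, g = self._competing()
        res_a = its.cause_specific_hr(time, cause, "A", g)
        res_b = its.cause_specific_hr(time, cause, "B", g)
        assert res_a.ci[1] < 1.0  # protective, clearly
        assert res_b.ci[0] < 1.0 < res_b.ci[1]  # null

    def test_inputs_not_mutated(self):
        time, cause, g = self._competing(n=500)
        cause_copy = cause.copy()
        its.cause_specific_hr(time, cause, "A", g)
        np.testing.assert_array_equal(cause, cause_copy)


class TestSplit:
    def test_thirty_percent_of_7376_is_2213(self):
        df = pd.DataFrame({"x": np.arange(7376)})
        train, test = its.train_test_split(df, 0.3, seed=0)
        assert len(test) == 2213
        assert len(train) == 7376 - 2213

    def test_small_n(self):
        df = pd.DataFrame({"x": np.arange(10)})
        _, test = its.train_test_split(df, 0.3, seed=1)
        assert len(test) == 3

    def test_same_seed_same_membership(self):
        df = pd.DataFrame({"x": np.arange(100)})
        _, t1 = its.train_test_split(df, 0.3, seed=5)
        _, t2 = its.train_test_split(df, 0.3, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_degenerate_fraction_rejected(self):
        df = pd.DataFrame({"x": np.arange(5)})
        with pytest.raises(ValueError):
            its.train_test_split(df, 0.0)
        with pytest.raises(ValueError):
            its.train_test_split(df, 0.05, seed=0)  # empty test side


def test_weighting_restores_covariate_balance():
    """Injected confounding between group and covariates disappears after IPTW."""
    rng = np.random.default_rng(17)
    n = 5000
    X = rng.normal(size=(n, 3))
    y = (rng.random(n) < expit(0.9 * X[:, 0] - 0.6 * X[:, 1])).astype(int)
    smd_before = its.standardized_mean_differences(X, y)
    assert smd_before.max() > 0.3
    fit = its.estimate_propensity(X, y)
    w = its.compute_iptw_weights(fit, y).weights
    smd_after = its.standardized_mean_differences(X, y, weights=w)
    assert smd_after.max() < 0.1
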