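"""Balanced T-learner training, benchmarks, tuning, and the Brier score."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import itesurv as its
from itesurv.curves import SurvivalCurves
from itesurv.ipm import ipm_penalty
from itesurv.metrics import integrated_brier_score
from itesurv.tlearner import BalancedTLearner, BalancedTLearnerSpec, tune_hyperparameters


def _per_arm_lifelines_coefs(cohort, X, names, arm):
    mask = (cohort["arm"] == arm).to_numpy()
    df = pd.DataFrame(X[mask], columns=names)
    df["time"] = cohort["time"].to_numpy()[mask]
    df["event"] = cohort["event"].to_numpy()[mask]
    return CoxPHFitter().fit(df, "time", "event").params_


def test_alpha0_linear_matches_partial_likelihood_fit(cohort5k, encoded5k, linear_fit5k):
    """With no balancing penalty and a linear model, joint gradient training
    recovers the per-arm Cox MLE."""
    cfg, cohort, _ = cohort5k
    enc, X = encoded5k
    for arm in (0, 1):
        ref = _per_arm_lifelines_coefs(cohort, X, enc.feature_names_, arm)
        mine = linear_fit5k.coefficients(arm)
        np.testing.assert_allclose(mine.to_numpy(), ref.to_numpy(), atol=0.15)


def test_same_spec_same_seed_identical_fit(cohort5k, encoded5k):
    cfg, cohort, _ = cohort5k
    enc, X = encoded5k
    sub = slice(0, 800)
    spec = BalancedTLearnerSpec(seed=4, max_steps=150, patience_steps=50)
    args = (X[sub], cohort["arm"][sub], cohort["time"][sub], cohort["event"][sub])
    r1 = its.fit_balanced_tlearner(*args, spec)
    r2 = its.fit_balanced_tlearner(*args, spec)
    assert r1.best_val_loss == r2.best_val_loss
    np.testing.assert_array_equal(r1.heads[0].weights[0], r2.heads[0].weights[0])


def test_identical_arm_representations_make_penalty_vacuous():
    # duplicated rows across arms: IPM term is 0, so alpha does not change the loss
    rng = np.random.default_rng(0)
    Xh = rng.normal(size=(40, 3))
    X = np.vstack([Xh, Xh])
    arm = np.r_[np.zeros(40, int), np.ones(40, int)]
    t = np.tile(rng.exponential(10, 40), 2)
    e = np.tile((rng.random(40) < 0.8).astype(int), 2)
    model = BalancedTLearner(X, arm, t, e)
    rng_a = np.random.default_rng(1)
    enc, heads = model._build(BalancedTLearnerSpec(seed=1), rng_a)
    idx = np.arange(80)
    loss0, _, _ = model._loss_and_grads(enc, heads, idx, BalancedTLearnerSpec(balance_weight=0.0), rng_a, train=False)
    loss5, _, _ = model._loss_and_grads(enc, heads, idx, BalancedTLearnerSpec(balance_weight=5.0), rng_a, train=False)
    assert loss0 == pytest.approx(loss5, abs=1e-9)


def test_divergent_training_aborts_with_diagnostics():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(60, 2)) * 1e4
    arm = rng.integers(0, 2, 60)
    t = rng.exponential(10, 60)
    e = np.ones(60, int)
    spec = BalancedTLearnerSpec(seed=0, learning_rate=1e6, max_steps=50, patience_steps=50,
                                shared_layers=(8,), head_layers=(8,))
    with pytest.raises((RuntimeError, FloatingPointError)):
        with np.errstate(over="raise", invalid="raise"):
            its.fit_balanced_tlearner(X, arm, t, e, spec)


def test_too_few_events_rejected():
    X = np.zeros((10, 2))
    arm = np.r_[np.zeros(5, int), np.ones(5, int)]
    t = np.arange(1.0, 11.0)
    e = np.r_[np.ones(5, int), np.zeros(5, int)]  # arm 1 has no events
    with pytest.raises(ValueError, match="events in arm 1"):
        BalancedTLearner(X, arm, t, e)


def test_balancing_penalty_shrinks_with_alpha(cohort5k, encoded5k):
    """Holding the data fixed, converged representations are more balanced
    for larger balance weights."""
    cfg, cohort, _ = cohort5k
    enc, X = encoded5k
    sub = slice(0, 600)
    penalties = {}
    for alpha in (0.0, 10.0):
        spec = BalancedTLearnerSpec(seed=3, shared_layers=(8,), head_layers=(),
                                    balance_weight=alpha, max_steps=250,
                                    patience_steps=250, learning_rate=0.02)
        res = its.fit_balanced_tlearner(X[sub], cohort["arm"][sub], cohort["time"][sub],
                                        cohort["event"][sub], spec)
        z, _ = res.encoder.forward(X[sub])
        a = cohort["arm"].to_numpy()[sub]
        penalties[alpha] = ipm_penalty(z[a == 0], z[a == 1])
    assert penalties[10.0] < penalties[0.0]


def test_predicted_curves_satisfy_invariants(linear_fit5k, encoded5k):
    enc, X = encoded5k
    grid = np.arange(0.0, 61.0, 1.0)
    rng = np.random.default_rng(0)
    idx = rng.choice(len(X), 100, replace=False)
    for arm in (0, 1):
        curves = linear_fit5k.predict_survival(X[idx], arm, grid)
        curves.validate()  # S(0)=1, non-increasing, within [0,1]


def test_higher_risk_lowers_curve(linear_fit5k, encoded5k):
    enc, X = encoded5k
    grid = np.arange(0.0, 61.0, 1.0)
    eta = linear_fit5k.predict_log_risk(X[:500], 0)
    hi, lo = np.argmax(eta), np.argmin(eta)
    curves = linear_fit5k.predict_survival(X[[hi, lo]], 0, grid)
    assert np.all(curves.values[0, 1:] <= curves.values[1, 1:])


def test_rank_agreement_with_benchmark_cox(cohort5k, encoded5k, linear_fit5k):
    from scipy.stats import spearmanr

    cfg, cohort, _ = cohort5k
    enc, X = encoded5k
    bench = its.fit_benchmark_tlearner("proportional-hazards", X, cohort["arm"],
                                       cohort["time"], cohort["event"],
                                       feature_names=enc.feature_names_)
    grid = np.arange(0.0, 61.0, 1.0)
    for arm in (0, 1):
        eta = linear_fit5k.predict_log_risk(X[:1000], arm)
        ref = -bench.predict_survival(X[:1000], arm, grid).values[:, 30]
        rho = spearmanr(eta, ref).statistic
        assert rho >= 0.98


def test_forest_single_stump_predicts_leafwise_constants(cohort5k, encoded5k):
    cfg, cohort, _ = cohort5k
    enc, X = encoded5k
    sub = slice(0, 500)
    res = its.fit_benchmark_tlearner("survival-forest", X[sub], cohort["arm"][sub],
                                     cohort["time"][sub], cohort["event"][sub],
                                     n_estimators=1, max_depth=1)
    grid = np.arange(0.0, 61.0, 1.0)
    curves = res.predict_survival(X[sub][:100], 0, grid)
    assert len(np.unique(curves.values.round(12), axis=0)) <= 2


def test_benchmark_curves_satisfy_invariants(cohort5k, encoded5k):
    cfg, cohort, _ = cohort5k
    enc, X = encoded5k
    sub = slice(0, 400)
    grid = np.arange(0.0, 61.0, 1.0)
    for method, kw in (("proportional-hazards", {}), ("survival-forest", {"n_estimators": 10})):
        res = its.fit_benchmark_tlearner(method, X[sub], cohort["arm"][sub],
                                         cohort["time"][sub], cohort["event"][sub], **kw)
        for arm in (0, 1):
            res.predict_survival(X[sub][:100], arm, grid).validate()


class TestTuning:
    def _data(self, cohort5k, encoded5k):
        cfg, cohort, _ = cohort5k
        enc, X = encoded5k
        sub = slice(0, 600)
        return (X[sub], cohort["arm"][sub].to_numpy(), cohort["time"][sub].to_numpy(),
                cohort["event"][sub].to_numpy())

    def test_single_point_grid_returned(self, cohort5k, encoded5k):
        X, arm, t, e = self._data(cohort5k, encoded5k)
        spec = BalancedTLearnerSpec(seed=0, max_steps=60, patience_steps=60)
        best, report = tune_hyperparameters(X, arm, t, e, [spec], n_folds=3)
        assert best is spec
        assert len(report) == 3

    def test_pathological_point_scores_infinite(self, cohort5k, encoded5k):
        X, arm, t, e = self._data(cohort5k, encoded5k)
        good = BalancedTLearnerSpec(seed=0, max_steps=60, patience_steps=60)
        bad = BalancedTLearnerSpec(seed=0, max_steps=60, patience_steps=60,
                                   learning_rate=1e8, shared_layers=(8,))
        with pytest.warns(UserWarning, match="failed"):
            best, report = tune_hyperparameters(X, arm, t, e, [bad, good], n_folds=2)
        assert best is good
        assert np.isinf(report.loc[report.grid_index == 0, "val_loss"]).any()

    def test_fold_assignment_deterministic(self, cohort5k, encoded5k):
        X, arm, t, e = self._data(cohort5k, encoded5k)
        spec = BalancedTLearnerSpec(seed=0, max_steps=30, patience_steps=30)
        _, r1 = tune_hyperparameters(X, arm, t, e, [spec], n_folds=4, seed=9)
        _, r2 = tune_hyperparameters(X, arm, t, e, [spec], n_folds=4, seed=9)
        pd.testing.assert_frame_equal(r1, r2)


class TestIntegratedBrierScore:
    def test_perfect_step_predictions_score_zero(self):
        t = np.array([3.0, 6.0, 9.0, 12.0])
        e = np.ones(4, int)
        grid = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
        vals = np.array([[1.0 if g < ti else 0.0 for g in grid] for ti in t])
        vals[:, 0] = 1.0
        curves = SurvivalCurves(grid, vals, step=True)
        assert integrated_brier_score(curves, t, e, 12.0) == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_predictor_scores_quarter(self):
        t = np.array([5.0, 10.0, 15.0, 20.0, 25.0])
        e = np.ones(5, int)
        grid = np.linspace(0.0, 25.0, 26)
        vals = np.full((5, 26), 0.5)
        vals[:, 0] = 1.0
        # S(0)=1 is required; excluding t=0 from the average via [1, horizon]
        curves = SurvivalCurves(grid, vals, step=True)
        ibs = integrated_brier_score(curves, t, e, 25.0)
        # the first 1-month sliver where S=1 contributes ~0: IBS slightly below 0.25
        assert ibs == pytest.approx(0.25, abs=0.01)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(4)
        t = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        e = np.array([1, 0, 1, 1, 0])
        grid = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        vals = np.minimum.accumulate(
            np.column_stack([np.ones(5), rng.uniform(0.2, 1.0, size=(5, 8))]), axis=1)
        curves = SurvivalCurves(grid, vals, step=True)
        horizon = 8.0

        # independent brute force: KM of censoring by explicit product,
        # Brier at each grid time by explicit patient loop, trapezoid by hand
        def km_censor(at, left=False):
            s = 1.0
            for ti in sorted(t[e == 0]):
                if (ti < at) if left else (ti <= at):
                    n_risk = sum(1 for tj in t if tj >= ti)
                    s *= 1 - 1 / n_risk
            return s

        bs = []
        for j, g in enumerate(grid):
            total = 0.0
            for i in range(5):
                s = vals[i, j]
                if t[i] <= g and e[i] == 1:
                    total += s**2 / km_censor(t[i], left=True)
                elif t[i] > g:
                    total += (1 - s) ** 2 / km_censor(g)
            bs.append(total / 5)
        expected = np.trapezoid(bs, grid) / horizon
        assert integrated_brier_score(curves, t, e, horizon) == pytest.approx(expected, abs=1e-10)

    def test_horizon_beyond_followup_rejected(self):
        curves = SurvivalCurves(np.array([0.0, 5.0]), np.array([[1.0, 0.5]]), step=True)
        with pytest.raises(ValueError):
            integrated_brier_score(curves, np.array([3.0]), np.array([1]), 10.0)
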