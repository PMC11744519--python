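"""Propensity weighting and weighted survival contrasts.

The paper-style evaluation of a treatment recommender on observational data:
patients whose actual treatment agrees with the recommendation ("Consis")
are compared with those whose treatment disagrees ("Inconsis") on overall
survival.  Because the two groups are not randomized, group membership is
modelled with a logistic propensity on the covariates and contrasts are
reweighted by stabilized inverse-probability-of-treatment weights (IPTW):
hazard ratios from a weighted Cox model with robust (sandwich) errors,
5-year absolute risk reduction and difference in restricted mean survival
time from weighted Kaplan-Meier curves, and a weighted log-rank test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import SurvivalCurves
from .ite import rst

__all__ = [
    "PropensityFit",
    "WeightVector",
    "estimate_propensity",
    "compute_iptw_weights",
    "weighted_cox_hr",
    "weighted_km",
    "arr_at",
    "drmst",
    "weighted_logrank",
    "cause_specific_hr",
    "train_test_split",
    "standardized_mean_differences",
    "EvalReport",
    "evaluate_recommendations",
    "HRResult",
]


# ---------------------------------------------------------------------------
# propensity and weights

@dataclass
class PropensityFit:
    coefficients: pd.Series  # includes "intercept"
    probabilities: np.ndarray  # P(group = 1 | x), clipped into (0, 1)
    clip: tuple[float, float]


@dataclass
class WeightVector:
    weights: np.ndarray  # stabilized, truncated; all finite and positive
    truncation_bounds: tuple[float, float]


def estimate_propensity(features, group_labels, feature_names=None,
                        clip: tuple[float, float] = (0.01, 0.99),
                        l2: float = 0.0) -> PropensityFit:
    """Logistic regression of group membership on covariates.

    Unpenalized maximum likelihood by default; ``l2 > 0`` adds a ridge
    penalty (useful for sparse strata that quasi-separate).  Fitted
    probabilities are clipped into ``clip`` so no weight explodes.  Perfect
    separation under the unpenalized fit raises with advice rather than
    returning a divergent fit.
    """
    import statsmodels.api as sm

    X = np.asarray(features, dtype=float)
    y = np.asarray(group_labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("both groups must be non-empty")
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(X.shape[1])]
    design = sm.add_constant(X, has_constant="add")
    # drop linearly dependent columns (constant-within-stratum indicators,
    # complementary one-hot sets) so the information matrix stays invertible
    from scipy.linalg import qr as _qr

    _, r, piv = _qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag[0] * 1e-9).sum()) if diag.size else 0
    keep = np.sort(piv[:rank])
    if 0 not in keep:  # always keep the intercept
        keep = np.unique(np.r_[0, keep[:-1]])
    design = design[:, keep]
    kept_names = [(["intercept"] + names)[j] for j in keep]
    import warnings as _warnings

    if l2 > 0:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(penalty="l2", C=1.0 / l2, solver="lbfgs", max_iter=500,
                                fit_intercept=False)
        lr.fit(design, y)
        params = lr.coef_.ravel()
        probs = np.clip(lr.predict_proba(design)[:, 1], clip[0], clip[1])
        return PropensityFit(coefficients=pd.Series(params, index=kept_names),
                             probabilities=probs, clip=clip)

    try:
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
    except Exception as exc:  # PerfectSeparationError and friends
        raise ValueError(
            "propensity model failed (likely perfect separation); "
            "consider clipping covariates or adding regularization"
        ) from exc
    if not np.all(np.isfinite(params)) or np.max(np.abs(params[1:]), initial=0.0) > 30:
        raise ValueError(
            "propensity model shows (quasi-)perfect separation; "
            "consider clipping covariates or adding regularization"
        )
    probs = np.clip(res.predict(design), clip[0], clip[1])
    coefs = pd.Series(params, index=kept_names)
    return PropensityFit(coefficients=coefs, probabilities=probs, clip=clip)


def compute_iptw_weights(fit: PropensityFit, group_labels,
                         truncate_percentiles: tuple[float, float] = (1.0, 99.0)) -> WeightVector:
    """Stabilized weights P(G=g) / P(G=g|x), truncated at percentiles."""
    y = np.asarray(group_labels, dtype=int)
    p1 = fit.probabilities
    prev = y.mean()
    w = np.where(y == 1, prev / p1, (1 - prev) / (1 - p1))
    lo, hi = np.percentile(w, truncate_percentiles)
    w = np.clip(w, lo, hi)
    return WeightVector(weights=w, truncation_bounds=(float(lo), float(hi)))


# ---------------------------------------------------------------------------
# weighted survival contrasts

@dataclass
class HRResult:
    hr: float
    ci: tuple[float, float]
    p: float
    log_hr: float
    se: float

    def __str__(self):
        return f"HR {self.hr:.2f} (95% CI {self.ci[0]:.2f}-{self.ci[1]:.2f}), p={self.p:.3g}"


def weighted_cox_hr(times, events, group_labels, weights=None,
                    adjustment_covariates=None, covariate_names=None) -> HRResult:
    """Hazard ratio of group 1 vs 0 from a weighted Cox partial likelihood.

    Confidence intervals use the robust sandwich variance whenever weights
    are supplied; with unit weights the fit is the ordinary (multivariate)
    Cox model.  The HR is invariant to rescaling all weights by a constant.
    """
    from lifelines import CoxPHFitter

    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    g = np.asarray(group_labels, dtype=int)
    for grp in (0, 1):
        if d[g == grp].sum() == 0:
            raise ValueError(f"no events in group {grp}")
    df = pd.DataFrame({"time": t, "event": d, "group": g})
    cols = ["group"]
    if adjustment_covariates is not None:
        Z = np.atleast_2d(np.asarray(adjustment_covariates, dtype=float))
        if Z.shape[0] != len(t):
            Z = Z.T
        names = (list(covariate_names) if covariate_names is not None
                 else [f"z{i}" for i in range(Z.shape[1])])
        for j, name in enumerate(names):
            df[name] = Z[:, j]
        cols += names
    robust = weights is not None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        df["w"] = w / w.mean()  # scale invariance
    cph = CoxPHFitter()
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        cph.fit(df[["time", "event", "w"] + cols] if weights is not None else df[["time", "event"] + cols],
                duration_col="time", event_col="event",
                weights_col="w" if weights is not None else None, robust=robust)
    row = cph.summary.loc["group"]
    return HRResult(
        hr=float(row["exp(coef)"]),
        ci=(float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
        p=float(row["p"]),
        log_hr=float(row["coef"]),
        se=float(row["se(coef)"]),
    )


def weighted_km(times, events, weights=None) -> SurvivalCurves:
    """Product-limit estimator with weighted event and at-risk counts."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty sample")
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(t, kind="stable")
    t_s, d_s, w_s = t[order], d[order], w[order]
    uniq = np.unique(t_s[d_s == 1])
    total = w_s.sum()
    # weighted at-risk count just before each event time
    cum_before = np.concatenate([[0.0], np.cumsum(w_s)])
    surv = []
    s = 1.0
    for ti in uniq:
        at_risk = total - cum_before[np.searchsorted(t_s, ti, side="left")]
        dw = w_s[(t_s == ti) & (d_s == 1)].sum()
        s *= max(1.0 - dw / at_risk, 0.0)
        surv.append(s)
    grid = np.concatenate([[0.0], uniq])
    values = np.concatenate([[1.0], surv])[None, :]
    return SurvivalCurves(grid, values, step=True)


def _km_value_at(curve: SurvivalCurves, t: float) -> float:
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return float(curve.values[0, idx])


def arr_at(km_group1: SurvivalCurves, km_group0: SurvivalCurves, horizon: float = 60.0) -> float:
    """Absolute risk reduction at the horizon, percentage points:
    100 * (S_1(h) - S_0(h))."""
    return 100.0 * (_km_value_at(km_group1, horizon) - _km_value_at(km_group0, horizon))


def _km_rst(curve: SurvivalCurves, horizon: float) -> float:
    # KM curves may end before the horizon; extend flat (last value carried forward)
    if curve.times[-1] < horizon:
        t = np.append(curve.times, horizon)
        v = np.column_stack([curve.values, curve.values[:, -1:]])
        curve = SurvivalCurves(t, v, step=True)
    return float(rst(curve, horizon)[0])


def drmst(km_group1: SurvivalCurves, km_group0: SurvivalCurves, horizon: float = 60.0) -> float:
    """Difference in restricted mean survival time (months) over the horizon,
    exact step-function integration."""
    return _km_rst(km_group1, horizon) - _km_rst(km_group0, horizon)


def weighted_logrank(times, events, group_labels, weights=None) -> tuple[float, float]:
    """Weighted log-rank test (1 df).  Weights are normalized to mean 1
    first, so rescaling all weights leaves the statistic unchanged; unit
    weights give the classical test.  Returns (chi-square, p)."""
    from scipy.stats import chi2

    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    g = np.asarray(group_labels, dtype=int)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.mean()
    event_times = np.unique(t[d == 1])
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        at_risk = t >= ti
        n = w[at_risk].sum()
        n1 = w[at_risk & (g == 1)].sum()
        dead = (t == ti) & (d == 1)
        dtot = w[dead].sum()
        d1 = w[dead & (g == 1)].sum()
        if n <= 1 or dtot == 0:
            continue
        e1 = dtot * n1 / n
        o_minus_e += d1 - e1
        var += dtot * (n1 / n) * (1 - n1 / n) * (n - dtot) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(chi2.sf(stat, df=1))


def cause_specific_hr(times, causes, cause_of_interest, group_labels, weights=None,
                      adjustment_covariates=None, covariate_names=None) -> HRResult:
    """Cause-specific hazard ratio under competing risks.

    Deaths from other causes are re-coded as censoring at their own time
    (the input arrays are not modified), then the weighted Cox contrast is
    applied — a marginal-structural cause-specific model when IPTW weights
    are supplied.
    """
    causes = np.asarray(causes, dtype=object)
    events = (causes == cause_of_interest).astype(int)
    g = np.asarray(group_labels, dtype=int)
    for grp in (0, 1):
        if events[g == grp].sum() == 0:
            raise ValueError(f"no events of cause {cause_of_interest!r} in group {grp}")
    return weighted_cox_hr(times, events, g, weights=weights,
                           adjustment_covariates=adjustment_covariates,
                           covariate_names=covariate_names)


def train_test_split(df: pd.DataFrame, test_fraction: float = 0.3, seed: int = 0):
    """Simple random split; test size is round(fraction * n)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(df)
    n_test = int(round(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise ValueError("split leaves one side empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return df.iloc[train_idx].reset_index(drop=True), df.iloc[test_idx].reset_index(drop=True)


def standardized_mean_differences(features, group_labels, weights=None,
                                  feature_names=None) -> pd.Series:
    """Absolute standardized mean differences between groups (balance check)."""
    X = np.asarray(features, dtype=float)
    g = np.asarray(group_labels, dtype=int)
    w = np.ones(len(g)) if weights is None else np.asarray(weights, dtype=float)
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(X.shape[1])]
    out = {}
    for j, name in enumerate(names):
        x = X[:, j]
        m1 = np.average(x[g == 1], weights=w[g == 1])
        m0 = np.average(x[g == 0], weights=w[g == 0])
        v1 = np.average((x[g == 1] - m1) ** 2, weights=w[g == 1])
        v0 = np.average((x[g == 0] - m0) ** 2, weights=w[g == 0])
        pooled = np.sqrt((v1 + v0) / 2)
        out[name] = abs(m1 - m0) / pooled if pooled > 0 else 0.0
    return pd.Series(out)


# ---------------------------------------------------------------------------
# the assembled evaluation report

@dataclass
class EvalReport:
    """Consis-vs-Inconsis survival contrast, unweighted and IPTW-weighted."""

    n_consis: int
    n_inconsis: int
    hr: HRResult
    iptw_hr: HRResult
    arr: float
    arr_ci: tuple[float, float]
    iptw_arr: float
    iptw_arr_ci: tuple[float, float]
    drmst: float
    drmst_ci: tuple[float, float]
    iptw_drmst: float
    iptw_drmst_ci: tuple[float, float]
    logrank_p: float
    iptw_logrank_p: float
    horizon: float
    ibs: dict = field(default_factory=dict)  # per-arm integrated Brier scores

    def to_dict(self) -> dict:
        def _hr(h: HRResult):
            return {"hr": h.hr, "ci": list(h.ci), "p": h.p}

        return {
            "n_consis": self.n_consis,
            "n_inconsis": self.n_inconsis,
            "hr": _hr(self.hr),
            "iptw_hr": _hr(self.iptw_hr),
            "arr_pct": self.arr,
            "arr_ci": list(self.arr_ci),
            "iptw_arr_pct": self.iptw_arr,
            "iptw_arr_ci": list(self.iptw_arr_ci),
            "drmst_months": self.drmst,
            "drmst_ci": list(self.drmst_ci),
            "iptw_drmst_months": self.iptw_drmst,
            "iptw_drmst_ci": list(self.iptw_drmst_ci),
            "logrank_p": self.logrank_p,
            "iptw_logrank_p": self.iptw_logrank_p,
            "horizon_months": self.horizon,
            "ibs": self.ibs,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_table(self) -> pd.DataFrame:
        """One-row table mirroring the usual performance-table layout."""
        row = {
            "HR": f"{self.hr.hr:.2f} ({self.hr.ci[0]:.2f}-{self.hr.ci[1]:.2f})",
            "IPTW-HR": f"{self.iptw_hr.hr:.2f} ({self.iptw_hr.ci[0]:.2f}-{self.iptw_hr.ci[1]:.2f})",
            "DRMST": f"{self.drmst:.2f} ({self.drmst_ci[0]:.2f}-{self.drmst_ci[1]:.2f})",
            "IPTW-DRMST": f"{self.iptw_drmst:.2f} ({self.iptw_drmst_ci[0]:.2f}-{self.iptw_drmst_ci[1]:.2f})",
            "ARR": f"{self.arr:.1f} ({self.arr_ci[0]:.1f}-{self.arr_ci[1]:.1f})",
            "IPTW-ARR": f"{self.iptw_arr:.1f} ({self.iptw_arr_ci[0]:.1f}-{self.iptw_arr_ci[1]:.1f})",
        }
        for key, val in self.ibs.items():
            row[f"IBS[{key}]"] = f"{val:.2f}"
        return pd.DataFrame([row])

    def summary(self) -> str:
        lines = [
            f"Consis vs Inconsis survival contrast (horizon {self.horizon:.0f} months)",
            "=" * 64,
            f"n: Consis {self.n_consis}, Inconsis {self.n_inconsis}",
            f"HR        : {self.hr}",
            f"IPTW HR   : {self.iptw_hr}",
            f"ARR       : {self.arr:.1f}% ({self.arr_ci[0]:.1f}-{self.arr_ci[1]:.1f})",
            f"IPTW ARR  : {self.iptw_arr:.1f}% ({self.iptw_arr_ci[0]:.1f}-{self.iptw_arr_ci[1]:.1f})",
            f"DRMST     : {self.drmst:.2f} mo ({self.drmst_ci[0]:.2f}-{self.drmst_ci[1]:.2f})",
            f"IPTW DRMST: {self.iptw_drmst:.2f} mo ({self.iptw_drmst_ci[0]:.2f}-{self.iptw_drmst_ci[1]:.2f})",
            f"log-rank p: {self.logrank_p:.3g} (IPTW: {self.iptw_logrank_p:.3g})",
        ]
        for key, val in self.ibs.items():
            lines.append(f"IBS [{key}]: {val:.3f}")
        return "\n".join(lines)


def evaluate_recommendations(times, events, consis_labels, features, feature_names=None,
                             horizon: float = 60.0, n_bootstrap: int = 200, seed: int = 0,
                             ibs: dict | None = None) -> EvalReport:
    """Full Consis-vs-Inconsis evaluation.

    ``consis_labels`` is 1 for patients whose actual treatment matched the
    recommendation.  ``features`` are the adjustment covariates: they feed
    both the propensity model for IPTW and the multivariate Cox adjustment.
    ARR/DRMST confidence intervals are percentile bootstrap over patients
    (propensity refitted in each resample).
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    g = np.asarray(consis_labels, dtype=int)
    X = np.asarray(features, dtype=float)

    fit = estimate_propensity(X, g, feature_names=feature_names)
    wv = compute_iptw_weights(fit, g)
    w = wv.weights

    hr = weighted_cox_hr(t, d, g, adjustment_covariates=X, covariate_names=feature_names)
    iptw_hr = weighted_cox_hr(t, d, g, weights=w, adjustment_covariates=X,
                              covariate_names=feature_names)

    def _contrasts(tt, dd, gg, ww):
        km1 = weighted_km(tt[gg == 1], dd[gg == 1], None if ww is None else ww[gg == 1])
        km0 = weighted_km(tt[gg == 0], dd[gg == 0], None if ww is None else ww[gg == 0])
        return arr_at(km1, km0, horizon), drmst(km1, km0, horizon)

    arr, dr = _contrasts(t, d, g, None)
    iptw_arr, iptw_dr = _contrasts(t, d, g, w)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, 4))
    n = len(t)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(g[idx])) < 2 or d[idx].sum() == 0:
            boots[b] = np.nan
            continue
        try:
            bfit = estimate_propensity(X[idx], g[idx], feature_names=feature_names)
            bw = compute_iptw_weights(bfit, g[idx]).weights
        except ValueError:
            boots[b] = np.nan
            continue
        a_u, d_u = _contrasts(t[idx], d[idx], g[idx], None)
        a_w, d_w = _contrasts(t[idx], d[idx], g[idx], bw)
        boots[b] = (a_u, d_u, a_w, d_w)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)

    lr_stat, lr_p = weighted_logrank(t, d, g)
    wlr_stat, wlr_p = weighted_logrank(t, d, g, weights=w)

    return EvalReport(
        n_consis=int(g.sum()), n_inconsis=int((1 - g).sum()),
        hr=hr, iptw_hr=iptw_hr,
        arr=arr, arr_ci=(float(lo[0]), float(hi[0])),
        iptw_arr=iptw_arr, iptw_arr_ci=(float(lo[2]), float(hi[2])),
        drmst=dr, drmst_ci=(float(lo[1]), float(hi[1])),
        iptw_drmst=iptw_dr, iptw_drmst_ci=(float(lo[3]), float(hi[3])),
        logrank_p=lr_p, iptw_logrank_p=wlr_p,
        horizon=horizon, ibs=ibs or {},
    )
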