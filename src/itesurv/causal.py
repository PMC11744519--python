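"""Interpretation of treatment recommendations by causal contrasts.

Three layers: (1) probability differences (PD) — how much more often a
characteristic leads to an arm-1 recommendation, optionally IPTW-adjusted
for the remaining covariates; (2) a linear-regression mediation
decomposition of the consistency effect on mortality into a natural direct
effect (NDE) and a natural indirect effect (NIE) through the actual
treatment received; (3) subgroup average treatment effects (hazard ratios
of the actual treatment within recommendation-defined subgroups), which
expose qualitative treatment heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iptw import HRResult, compute_iptw_weights, estimate_propensity, weighted_cox_hr

__all__ = [
    "PDResult",
    "MediationResult",
    "probability_difference",
    "mediation_nde_nie",
    "subgroup_ate",
]


# ---------------------------------------------------------------------------
# probability difference

@dataclass
class PDResult:
    characteristic: str
    pd: float  # percentage points
    pd_ci: tuple[float, float]
    iptw_pd: float | None
    iptw_pd_ci: tuple[float, float] | None

    def __str__(self):
        s = f"PD[{self.characteristic}] = {self.pd:.2f} pts ({self.pd_ci[0]:.2f}-{self.pd_ci[1]:.2f})"
        if self.iptw_pd is not None:
            s += f"; IPTW-adjusted {self.iptw_pd:.2f} pts ({self.iptw_pd_ci[0]:.2f}-{self.iptw_pd_ci[1]:.2f})"
        return s


def _weighted_pd(rec, ind, w):
    p1 = np.average(rec[ind == 1], weights=w[ind == 1])
    p0 = np.average(rec[ind == 0], weights=w[ind == 0])
    return 100.0 * (p1 - p0)


def probability_difference(recommendations, characteristic_indicator, other_features=None,
                           feature_names=None, name: str = "characteristic",
                           n_bootstrap: int = 500, seed: int = 0) -> PDResult:
    """P(recommended | characteristic) - P(recommended | no characteristic), x100.

    When ``other_features`` is given, the IPTW-adjusted PD reweights each
    stratum by stabilized inverse-probability weights from a logistic
    propensity of the characteristic on those covariates, isolating the
    characteristic's own contribution.  CIs are percentile bootstrap over
    patients.
    """
    rec = np.asarray(recommendations, dtype=float)
    ind = np.asarray(characteristic_indicator, dtype=int)
    if set(np.unique(ind)) - {0, 1}:
        raise ValueError("characteristic indicator must be binary")
    for s in (0, 1):
        if not np.any(ind == s):
            raise ValueError(f"stratum indicator={s} is empty")

    unit = np.ones_like(rec)
    point = _weighted_pd(rec, ind, unit)

    adjusted = None
    if other_features is not None:
        Z = np.asarray(other_features, dtype=float)
        fit = estimate_propensity(Z, ind, feature_names=feature_names)
        w = compute_iptw_weights(fit, ind).weights
        adjusted = _weighted_pd(rec, ind, w)

    rng = np.random.default_rng(seed)
    n = len(rec)
    boot_u = np.full(n_bootstrap, np.nan)
    boot_a = np.full(n_bootstrap, np.nan)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(ind[idx])) < 2:
            continue
        boot_u[b] = _weighted_pd(rec[idx], ind[idx], unit[idx])
        if other_features is not None:
            try:
                bfit = estimate_propensity(Z[idx], ind[idx], feature_names=feature_names)
                bw = compute_iptw_weights(bfit, ind[idx]).weights
                boot_a[b] = _weighted_pd(rec[idx], ind[idx], bw)
            except ValueError:
                continue
    ci_u = tuple(np.nanpercentile(boot_u, [2.5, 97.5]))
    ci_a = tuple(np.nanpercentile(boot_a, [2.5, 97.5])) if other_features is not None else None
    return PDResult(
        characteristic=name,
        pd=float(point), pd_ci=(float(ci_u[0]), float(ci_u[1])),
        iptw_pd=None if adjusted is None else float(adjusted),
        iptw_pd_ci=None if ci_a is None else (float(ci_a[0]), float(ci_a[1])),
    )


# ---------------------------------------------------------------------------
# mediation (linear probability models)

@dataclass
class MediationResult:
    nde: float  # exposure slope with mediator held in the model
    nie: float  # product of paths a (exposure->mediator) and b (mediator->outcome)
    total: float  # exposure slope of the reduced model; equals nde + nie exactly
    nde_ci: tuple[float, float]
    nie_ci: tuple[float, float]
    total_ci: tuple[float, float]

    def summary(self) -> str:
        return (
            "Mediation decomposition (linear probability models)\n"
            f"  NDE  : {self.nde:+.4f} ({self.nde_ci[0]:+.4f}, {self.nde_ci[1]:+.4f})\n"
            f"  NIE  : {self.nie:+.4f} ({self.nie_ci[0]:+.4f}, {self.nie_ci[1]:+.4f})\n"
            f"  Total: {self.total:+.4f} ({self.total_ci[0]:+.4f}, {self.total_ci[1]:+.4f})"
        )


def _ols_slope(y, cols):
    X = np.column_stack([np.ones(len(y))] + cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _mediation_point(e, m, y, Z):
    covs = [Z[:, j] for j in range(Z.shape[1])] if Z is not None and Z.size else []
    if np.all(m == m[0]):
        warnings.warn("mediator is constant; NIE = 0")
        a, b = 0.0, 0.0
        beta_out = _ols_slope(y, [e] + covs)
        nde = beta_out[1]
    else:
        beta_out = _ols_slope(y, [e, m] + covs)
        nde, b = beta_out[1], beta_out[2]
        beta_med = _ols_slope(m, [e] + covs)
        a = beta_med[1]
    nie = a * b
    return float(nde), float(nie), float(nde + nie)


def mediation_nde_nie(exposure, mediator, outcome, covariates=None,
                      n_bootstrap: int = 200, seed: int = 0) -> MediationResult:
    """Product-of-coefficients mediation with linear probability models.

    outcome ~ exposure + mediator + covariates gives the NDE (exposure
    slope) and the mediator slope b; mediator ~ exposure + covariates gives
    path a; NIE = a*b.  For ordinary least squares this decomposition is
    exactly additive: NDE + NIE equals the exposure slope of the reduced
    model outcome ~ exposure + covariates.  CIs are percentile bootstrap.
    """
    e = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    Z = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z is not None and Z.shape[0] != len(e):
        Z = Z.T
    nde, nie, total = _mediation_point(e, m, y, Z if Z is not None else np.empty((len(e), 0)))

    rng = np.random.default_rng(seed)
    n = len(e)
    boots = np.full((n_bootstrap, 3), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            Zb = Z[idx] if Z is not None else np.empty((n, 0))
            boots[b] = _mediation_point(e[idx], m[idx], y[idx], Zb)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return MediationResult(
        nde=nde, nie=nie, total=total,
        nde_ci=(float(lo[0]), float(hi[0])),
        nie_ci=(float(lo[1]), float(hi[1])),
        total_ci=(float(lo[2]), float(hi[2])),
    )


# ---------------------------------------------------------------------------
# subgroup average treatment effects

def subgroup_ate(times, events, actual_treatment, subgroup_labels, features,
                 feature_names=None) -> pd.DataFrame:
    """Hazard ratio of treatment 1 vs 0 within each subgroup and overall.

    The IPTW column reweights by a propensity for the actual treatment given
    the covariates, fitted within the subgroup.  Subgroups where one arm has
    no events are flagged non-estimable rather than raising.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    trt = np.asarray(actual_treatment, dtype=int)
    sub = np.asarray(subgroup_labels)
    X = np.asarray(features, dtype=float)

    rows = []
    groups = [("overall", np.ones(len(t), dtype=bool))]
    groups += [(str(lv), sub == lv) for lv in pd.unique(sub)]
    for label, mask in groups:
        row = {"subgroup": label, "n": int(mask.sum()), "estimable": True}
        try:
            hr = weighted_cox_hr(t[mask], d[mask], trt[mask])
            # drop columns constant within the subgroup (e.g. the covariate
            # that defines it) so the logistic design stays full rank
            Xm = X[mask]
            keep = Xm.std(axis=0) > 0
            names_m = None if feature_names is None else [n for n, k in zip(feature_names, keep) if k]
            try:
                fit = estimate_propensity(Xm[:, keep], trt[mask], feature_names=names_m)
            except ValueError:
                # sparse cells can quasi-separate within a subgroup; a light
                # ridge keeps the weights finite
                fit = estimate_propensity(Xm[:, keep], trt[mask], feature_names=names_m, l2=1.0)
            w = compute_iptw_weights(fit, trt[mask]).weights
            whr = weighted_cox_hr(t[mask], d[mask], trt[mask], weights=w)
            row.update(
                hr=hr.hr, hr_lo=hr.ci[0], hr_hi=hr.ci[1],
                iptw_hr=whr.hr, iptw_hr_lo=whr.ci[0], iptw_hr_hi=whr.ci[1],
            )
        except ValueError:
            row.update(hr=np.nan, hr_lo=np.nan, hr_hi=np.nan,
                       iptw_hr=np.nan, iptw_hr_lo=np.nan, iptw_hr_hi=np.nan,
                       estimable=False)
        rows.append(row)
    return pd.DataFrame(rows)
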