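"""Prediction accuracy metrics for survival curves."""

from __future__ import annotations

import warnings

import numpy as np

from .curves import SurvivalCurves

__all__ = ["integrated_brier_score"]


def _censoring_km(times, events):
    """Kaplan-Meier estimate of the censoring distribution G(t)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=1 - np.asarray(events))
    t = kmf.survival_function_.index.to_numpy(dtype=float)
    s = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    return t, s

def _eval_step(t_grid, s_vals, t, left=False):
    """Right-continuous (or left-limit) evaluation of a step function."""
    side = "left" if left else "right"
    idx = np.searchsorted(t_grid, np.asarray(t, dtype=float), side=side)
    padded = np.concatenate([[1.0], s_vals])
    return padded[idx]


def integrated_brier_score(curves: SurvivalCurves, times, events, horizon: float) -> float:
    """Time-averaged Brier score over [0, horizon] with IPCW weighting.

    BS(t) = mean_i [ S_hat(t|x_i)^2 1{T_i <= t, event} / G(T_i-)
                     + (1 - S_hat(t|x_i))^2 1{T_i > t} / G(t) ]

    where G is the Kaplan-Meier estimator of the censoring survival
    function.  The time average is a trapezoidal integral over the curve
    grid restricted to [0, horizon], divided by the horizon.  If G reaches 0
    before the horizon the integration is truncated there with a warning.
    """
    t_obs = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if horizon > t_obs.max():
        raise ValueError("horizon exceeds the maximum observed time")
    curves = curves.truncated(min(horizon, curves.times[-1]))
    grid = curves.times

    gt, gs = _censoring_km(t_obs, d)
    g_at_grid = _eval_step(gt, gs, grid)
    g_at_obs_left = _eval_step(gt, gs, t_obs, left=True)

    upper = horizon
    if np.any(g_at_grid <= 0):
        upper = grid[g_at_grid <= 0].min()
        warnings.warn(
            f"censoring survival reaches 0 at t={upper:.3f} < horizon; truncating IBS there"
        )
    keep = grid <= upper
    grid = grid[keep]
    vals = curves.values[:, keep]
    g_at_grid = g_at_grid[keep]

    bs = np.empty(grid.size)
    for j, t in enumerate(grid):
        s = vals[:, j]
        died = (t_obs <= t) & (d == 1)
        alive = t_obs > t
        contrib = np.zeros_like(s)
        contrib[died] = s[died] ** 2 / g_at_obs_left[died]
        contrib[alive] = (1.0 - s[alive]) ** 2 / g_at_grid[j]
        bs[j] = contrib.mean()
    return float(np.trapezoid(bs, grid) / upper)
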