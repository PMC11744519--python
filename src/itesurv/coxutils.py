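"""Cox partial likelihood (Breslow ties) and the Breslow baseline hazard.

These are the primitives behind both risk heads of the balanced T-learner:
the negative log partial likelihood is the per-head training objective, and
the Breslow estimator converts fitted log risks into per-arm baseline
cumulative hazards, hence into absolute survival curves.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cox_partial_likelihood_loss", "cox_loss_grad", "BreslowBaseline", "breslow_baseline"]


def _risk_sums(times: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Sum of scores over each subject's risk set {j : t_j >= t_i}, tie-aware."""
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    rev_csum = np.cumsum(scores[order][::-1])[::-1]
    # risk sum at t_i = rev_csum at the first sorted index with time == t_i
    first = np.searchsorted(t_sorted, times, side="left")
    return rev_csum[first]


def cox_partial_likelihood_loss(log_risks, times, events) -> float:
    """Negative log Cox partial likelihood, Breslow tie handling, per event.

    loss = -(1/D) * sum_{i: event} [ eta_i - log sum_{j: t_j >= t_i} e^{eta_j} ]

    Raises if the batch contains no events (the objective is undefined).
    """
    eta = np.asarray(log_risks, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    n_events = d.sum()
    if n_events == 0:
        raise ValueError("Cox partial likelihood undefined: no events in batch")
    # subtract max for numerical stability; cancels in eta_i - log(risk sum)
    shift = eta.max()
    risk = _risk_sums(t, np.exp(eta - shift))
    ll = np.sum(d * ((eta - shift) - np.log(risk)))
    return float(-ll / n_events)


def cox_loss_grad(log_risks, times, events) -> np.ndarray:
    """d loss / d eta_j = -(1/D) * (delta_j - e^{eta_j} * A(t_j)),

    where A(t) = sum over event times t_i <= t of d_i / riskset_sum(t_i) —
    i.e. the Breslow cumulative hazard evaluated at the subject's own time.
    """
    eta = np.asarray(log_risks, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    n_events = d.sum()
    if n_events == 0:
        raise ValueError("Cox partial likelihood undefined: no events in batch")
    shift = eta.max()
    scores = np.exp(eta - shift)
    base = breslow_baseline(eta - shift, t, d)
    cumhaz_at_own = base(t)
    return -(d - scores * cumhaz_at_own) / n_events


class BreslowBaseline:
    """Right-continuous non-decreasing step function H0(t), H0(0) = 0."""

    def __init__(self, event_times: np.ndarray, cumhaz: np.ndarray):
        self.event_times = np.asarray(event_times, dtype=float)
        self.cumhaz = np.asarray(cumhaz, dtype=float)

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cumhaz])
        return padded[idx]


def breslow_baseline(log_risks, times, events) -> BreslowBaseline:
    """Breslow estimator: H0(t) = sum_{event times t_i <= t} d_i / sum_{j in R(t_i)} e^{eta_j}."""
    eta = np.asarray(log_risks, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    if not np.any(d > 0):
        return BreslowBaseline(np.empty(0), np.empty(0))
    scores = np.exp(eta)
    risk = _risk_sums(t, scores)
    ev_mask = d > 0
    ev_times = t[ev_mask]
    uniq, inv = np.unique(ev_times, return_inverse=True)
    d_per_time = np.bincount(inv, weights=d[ev_mask])
    # risk-set sum at each unique event time (same for all tied subjects)
    risk_per_time = np.zeros(uniq.size)
    risk_per_time[inv] = risk[ev_mask]
    increments = d_per_time / risk_per_time
    return BreslowBaseline(uniq, np.cumsum(increments))
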