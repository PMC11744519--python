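"""Integral probability metrics between treatment-arm representations.

Two estimators of distributional imbalance between the encoded covariates of
the two arms are provided: an entropy-regularized 2-Wasserstein distance
(debiased Sinkhorn divergence) and the RBF-kernel maximum mean discrepancy.
Both are non-negative, symmetric, vanish on identical point sets, and expose
gradients with respect to the representations so they can serve as an
additive balancing penalty during training.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["ipm_penalty", "ipm_penalty_with_grad"]

_KINDS = ("wasserstein-sinkhorn", "mmd-rbf")


def _pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def _sinkhorn_plan(cost: np.ndarray, reg: float, n_iter: int = 1000, tol: float = 1e-12):
    """Entropic OT plan between uniform marginals (log-domain iterations)."""
    n0, n1 = cost.shape
    log_a = -np.log(n0) * np.ones(n0)
    log_b = -np.log(n1) * np.ones(n1)
    f = np.zeros(n0)
    g = np.zeros(n1)
    for _ in range(n_iter):
        m = (-cost + f[:, None] + g[None, :]) / reg
        f_new = f + reg * (log_a - _logsumexp_rows(m))
        m = (-cost + f_new[:, None] + g[None, :]) / reg
        g_new = g + reg * (log_b - _logsumexp_rows(m.T))
        if np.max(np.abs(f_new - f)) < tol and np.max(np.abs(g_new - g)) < tol:
            f, g = f_new, g_new
            break
        f, g = f_new, g_new
    log_p = (-cost + f[:, None] + g[None, :]) / reg
    return np.exp(log_p)


def _logsumexp_rows(m: np.ndarray) -> np.ndarray:
    mx = m.max(axis=1, keepdims=True)
    return (mx + np.log(np.exp(m - mx).sum(axis=1, keepdims=True))).ravel()


def _sinkhorn_cost(z0, z1, reg):
    cost = _pairwise_sq_dists(z0, z1)
    plan = _sinkhorn_plan(cost, reg)
    return float(np.sum(plan * cost)), plan


def _mmd_sq_terms(z0, z1):
    pooled = np.vstack([z0, z1])
    sq = _pairwise_sq_dists(pooled, pooled)
    off = sq[np.triu_indices_from(sq, k=1)]
    med = np.median(off[off > 0]) if np.any(off > 0) else 1.0
    sigma_sq = max(med, 1e-12)  # median heuristic on squared distances
    kxx = np.exp(-_pairwise_sq_dists(z0, z0) / sigma_sq)
    kyy = np.exp(-_pairwise_sq_dists(z1, z1) / sigma_sq)
    kxy = np.exp(-_pairwise_sq_dists(z0, z1) / sigma_sq)
    return kxx, kyy, kxy, sigma_sq


def ipm_penalty(z0, z1, kind: str = "wasserstein-sinkhorn", reg: float = 0.1) -> float:
    """Non-negative divergence between the two arms' representation samples.

    ``wasserstein-sinkhorn`` returns the square root of the debiased Sinkhorn
    divergence with squared-Euclidean ground cost (an entropy-regularized
    2-Wasserstein distance); ``mmd-rbf`` returns the biased-estimator MMD
    with a median-heuristic RBF bandwidth.  An empty arm yields 0 with a
    warning (a mini-batch can miss one arm; the penalty is then vacuous).
    """
    value, _, _ = ipm_penalty_with_grad(z0, z1, kind=kind, reg=reg)
    return value


def ipm_penalty_with_grad(z0, z1, kind: str = "wasserstein-sinkhorn", reg: float = 0.1):
    """Penalty plus its gradients with respect to each arm's representations.

    The Sinkhorn gradient uses the envelope theorem (transport plan held
    fixed); the MMD bandwidth is likewise treated as a constant.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown IPM kind {kind!r}; expected one of {_KINDS}")
    z0 = np.atleast_2d(np.asarray(z0, dtype=float))
    z1 = np.atleast_2d(np.asarray(z1, dtype=float))
    if z0.shape[0] == 0 or z1.shape[0] == 0:
        warnings.warn("one treatment arm empty in batch; IPM penalty set to 0")
        return 0.0, np.zeros_like(z0), np.zeros_like(z1)

    if kind == "wasserstein-sinkhorn":
        s01, p01 = _sinkhorn_cost(z0, z1, reg)
        s00, p00 = _sinkhorn_cost(z0, z0, reg)
        s11, p11 = _sinkhorn_cost(z1, z1, reg)
        div = max(s01 - 0.5 * (s00 + s11), 0.0)
        value = float(np.sqrt(div))
        # envelope gradients: transport plans held fixed
        g0 = 2.0 * (p01.sum(axis=1)[:, None] * z0 - p01 @ z1)
        g1 = 2.0 * (p01.sum(axis=0)[:, None] * z1 - p01.T @ z0)
        # debiasing self-terms (symmetric plans): d s00 / d z0 = 4 (r z0 - P00 z0)
        g0 -= 2.0 * (p00.sum(axis=1)[:, None] * z0 - p00 @ z0)
        g1 -= 2.0 * (p11.sum(axis=1)[:, None] * z1 - p11 @ z1)
        if value > 1e-12:
            g0 /= 2.0 * value
            g1 /= 2.0 * value
        else:
            g0 = np.zeros_like(z0)
            g1 = np.zeros_like(z1)
        return value, g0, g1

    kxx, kyy, kxy, sigma_sq = _mmd_sq_terms(z0, z1)
    n0, n1 = z0.shape[0], z1.shape[0]
    mmd_sq = kxx.mean() + kyy.mean() - 2.0 * kxy.mean()
    mmd_sq = max(mmd_sq, 0.0)
    value = float(np.sqrt(mmd_sq))
    # d k(a,b)/d a = -(2/sigma_sq) * k(a,b) * (a - b)
    c = 2.0 / sigma_sq
    g0 = (
        -c / (n0 * n0) * (kxx.sum(axis=1)[:, None] * z0 - kxx @ z0)
        + c / (n0 * n1) * (kxy.sum(axis=1)[:, None] * z0 - kxy @ z1)
    ) * 2.0
    g1 = (
        -c / (n1 * n1) * (kyy.sum(axis=1)[:, None] * z1 - kyy @ z1)
        + c / (n0 * n1) * (kxy.sum(axis=0)[:, None] * z1 - kxy.T @ z0)
    ) * 2.0
    if value > 1e-12:
        g0 /= 2.0 * value
        g1 /= 2.0 * value
    else:
        g0 = np.zeros_like(z0)
        g1 = np.zeros_like(z1)
    return value, g0, g1
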