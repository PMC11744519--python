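"""Counterfactual survival models organised as model / results pairs.

The core estimator is a balanced T-learner: a shared representation network
feeds two Cox risk heads, one per treatment arm, trained jointly on

    loss = CoxLoss(head 0) + CoxLoss(head 1) + alpha * IPM(repr arm 0, repr arm 1)

where the integral-probability-metric term penalises distributional
imbalance between the two arms' learned representations (entropic
2-Wasserstein or RBF MMD).  With ``alpha = 0`` the loss is exactly the sum
of the two heads' negative log partial likelihoods, i.e. an unbalanced
neural T-learner; with no hidden layers it degenerates to two linear Cox
models sharing nothing but the optimiser.

Breslow baselines are estimated per arm on that arm's own training data, so
each predicted curve is S_a(t|x) = exp(-H0_a(t) * exp(eta_a(x))).

Classical T-learner benchmarks (Cox proportional hazards via lifelines,
random survival forests via scikit-survival) expose the same prediction
contract so the downstream treatment-effect engine is estimator-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mlp import MLP, Adam
from .coxutils import breslow_baseline, cox_loss_grad, cox_partial_likelihood_loss
from .curves import SurvivalCurves
from .ipm import ipm_penalty_with_grad

__all__ = [
    "BalancedTLearnerSpec",
    "BalancedTLearner",
    "BalancedTLearnerResults",
    "fit_balanced_tlearner",
    "fit_benchmark_tlearner",
    "BenchmarkTLearnerResults",
    "tune_hyperparameters",
]


@dataclass(frozen=True)
class BalancedTLearnerSpec:
    """Hyperparameters of the balanced T-learner.

    ``shared_layers == ()`` makes the encoder the identity, and
    ``head_layers == ()`` makes each head a single linear map — together the
    correctly-specified linear configuration for proportional-hazards data.
    ``patience_steps`` counts gradient steps since the last improvement of
    the validation loss (Cox terms only) before training stops.
    """

    shared_layers: tuple[int, ...] = ()
    head_layers: tuple[int, ...] = ()
    dropout: float = 0.0
    balance_weight: float = 0.0  # alpha
    ipm_kind: str = "wasserstein-sinkhorn"
    learning_rate: float = 0.05
    batch_size: int | None = None  # None = full batch
    max_steps: int = 1500
    patience_steps: int = 300
    l2_weight: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.balance_weight < 0:
            raise ValueError("balance_weight must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size is not None and self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.l2_weight < 0:
            raise ValueError("l2_weight must be >= 0")


class BalancedTLearner:
    """Model object: encoded features, treatment arm, follow-up, event flag.

    ``fit`` returns a :class:`BalancedTLearnerResults`.
    """

    def __init__(self, features, arms, times, events, feature_names=None):
        self.X = np.asarray(features, dtype=float)
        self.arm = np.asarray(arms, dtype=int)
        self.time = np.asarray(times, dtype=float)
        self.event = np.asarray(events, dtype=int)
        if not set(np.unique(self.arm)) <= {0, 1}:
            raise ValueError("arms must be binary 0/1")
        for a in (0, 1):
            if self.event[self.arm == a].sum() < 2:
                raise ValueError(f"need at least 2 events in arm {a}")
        self.feature_names = list(feature_names) if feature_names is not None else [
            f"x{i}" for i in range(self.X.shape[1])
        ]

    # -- internal ------------------------------------------------------
    def _build(self, spec: BalancedTLearnerSpec, rng: np.random.Generator):
        d = self.X.shape[1]
        encoder = MLP(d, list(spec.shared_layers), d if not spec.shared_layers else spec.shared_layers[-1],
                      rng, identity=not spec.shared_layers)
        rep_dim = d if not spec.shared_layers else spec.shared_layers[-1]
        heads = [MLP(rep_dim, list(spec.head_layers), 1, rng) for _ in range(2)]
        return encoder, heads

    def _loss_and_grads(self, encoder, heads, idx, spec, rng, train=True):
        X, arm, time, event = self.X[idx], self.arm[idx], self.time[idx], self.event[idx]
        drop = spec.dropout if train else 0.0
        drop_rng = rng if train else None
        z, enc_cache = encoder.forward(X, dropout=drop, rng=drop_rng)
        grad_z = np.zeros_like(z)
        loss = 0.0
        head_grads = [None, None]
        for a in (0, 1):
            mask = arm == a
            if event[mask].sum() == 0:
                head_grads[a] = ([np.zeros_like(p) for p in heads[a].params()]
                                 if not heads[a].identity else [])
                continue
            eta, cache = heads[a].forward(z[mask], dropout=drop, rng=drop_rng)
            eta = eta.ravel()
            loss += cox_partial_likelihood_loss(eta, time[mask], event[mask])
            g_eta = cox_loss_grad(eta, time[mask], event[mask])[:, None]
            g_in, gw, gb = heads[a].backward(cache, g_eta)
            head_grads[a] = gw + gb
            grad_z[mask] += g_in
        if spec.balance_weight > 0:
            pen, g0, g1 = ipm_penalty_with_grad(z[arm == 0], z[arm == 1], kind=spec.ipm_kind)
            loss += spec.balance_weight * pen
            grad_z[arm == 0] += spec.balance_weight * g0
            grad_z[arm == 1] += spec.balance_weight * g1
        _, egw, egb = encoder.backward(enc_cache, grad_z) if enc_cache is not None else (None, [], [])
        enc_grads = egw + egb
        # L2 on weights only
        if spec.l2_weight > 0:
            for net, grads in ((encoder, enc_grads), (heads[0], head_grads[0]), (heads[1], head_grads[1])):
                nw = len(net.weights)
                for i in range(nw):
                    loss += spec.l2_weight * float(np.sum(net.weights[i] ** 2))
                    grads[i] = grads[i] + 2.0 * spec.l2_weight * net.weights[i]
        return loss, enc_grads, head_grads

    def _validation_loss(self, encoder, heads, idx) -> float:
        z, _ = encoder.forward(self.X[idx])
        total = 0.0
        for a in (0, 1):
            mask = self.arm[idx] == a
            if self.event[idx][mask].sum() == 0:
                continue
            eta, _ = heads[a].forward(z[mask])
            total += cox_partial_likelihood_loss(eta.ravel(), self.time[idx][mask], self.event[idx][mask])
        return total

    # -- public --------------------------------------------------------
    def fit(self, spec: BalancedTLearnerSpec, validation_idx=None) -> "BalancedTLearnerResults":
        """Mini-batch Adam on the joint loss with early stopping.

        ``validation_idx`` (row indices into this model's data) overrides the
        default internal 80/20 split; the validation loss is the sum of the
        two heads' Cox losses (no balance penalty), so it is comparable
        across balance weights.
        """
        spec.validate()
        rng = np.random.default_rng(spec.seed)
        n = self.X.shape[0]
        if validation_idx is None:
            perm = rng.permutation(n)
            n_val = max(int(round(0.2 * n)), 2)
            val_idx, train_idx = perm[:n_val], perm[n_val:]
        else:
            val_idx = np.asarray(validation_idx, dtype=int)
            train_idx = np.setdiff1d(np.arange(n), val_idx)

        encoder, heads = self._build(spec, rng)
        params = encoder.params() + heads[0].params() + heads[1].params()
        opt = Adam(params, lr=spec.learning_rate)

        best_val = np.inf
        best_step = 0
        best_params = [p.copy() for p in params]
        history = []
        batch = spec.batch_size
        for step in range(1, spec.max_steps + 1):
            if batch is None or batch >= train_idx.size:
                idx = train_idx
            else:
                idx = rng.choice(train_idx, size=batch, replace=False)
            loss, enc_g, head_g = self._loss_and_grads(encoder, heads, idx, spec, rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at step {step}: loss={loss!r} "
                    f"(lr={spec.learning_rate}, alpha={spec.balance_weight})"
                )
            opt.step(enc_g + head_g[0] + head_g[1])
            val = self._validation_loss(encoder, heads, val_idx)
            history.append((step, loss, val))
            if val < best_val - 1e-9:
                best_val, best_step = val, step
                best_params = [p.copy() for p in params]
            if step - best_step >= spec.patience_steps:
                break
        for p, bp in zip(params, best_params):
            p[...] = bp

        # Breslow baselines per arm on that arm's own data, final parameters
        z_all, _ = encoder.forward(self.X)
        baselines = []
        etas = []
        for a in (0, 1):
            mask = self.arm == a
            eta, _ = heads[a].forward(z_all[mask])
            eta = eta.ravel()
            etas.append(eta)
            baselines.append(breslow_baseline(eta, self.time[mask], self.event[mask]))
        report = pd.DataFrame(history, columns=["step", "train_loss", "val_loss"])
        return BalancedTLearnerResults(
            model=self, spec=spec, encoder=encoder, heads=heads,
            baselines=baselines, history=report,
            best_val_loss=float(best_val), best_step=int(best_step),
        )


@dataclass
class BalancedTLearnerResults:
    """Fitted balanced T-learner: parameters, per-arm Breslow baselines,
    and the training trajectory."""

    model: BalancedTLearner
    spec: BalancedTLearnerSpec
    encoder: MLP
    heads: list
    baselines: list
    history: pd.DataFrame
    best_val_loss: float
    best_step: int
    encoding: object = None  # CovariateEncoder when fitted through the pipeline

    def predict_log_risk(self, features, arm: int) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        z, _ = self.encoder.forward(X)
        eta, _ = self.heads[arm].forward(z)
        return eta.ravel()

    def predict_survival(self, features, arm: int, grid) -> SurvivalCurves:
        """S_a(t|x) = exp(-H0_a(t) exp(eta_a(x))) on the given grid."""
        grid = np.asarray(grid, dtype=float)
        eta = self.predict_log_risk(features, arm)
        h0 = self.baselines[arm](grid)
        values = np.exp(-np.outer(np.exp(eta), h0))
        return SurvivalCurves(grid, values, step=True)

    def coefficients(self, arm: int) -> pd.Series:
        """Linear log-hazard coefficients (identity encoder + linear head only)."""
        if not self.encoder.identity or len(self.heads[arm].weights) != 1:
            raise ValueError("coefficients are defined only for the linear configuration")
        return pd.Series(self.heads[arm].weights[0].ravel(), index=self.model.feature_names)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Balanced T-learner (Cox heads, shared representation)",
            "=" * 56,
            f"n_obs: {m.X.shape[0]}   features: {m.X.shape[1]}",
            f"arm 0: n={int((m.arm == 0).sum())}, events={int(m.event[m.arm == 0].sum())}",
            f"arm 1: n={int((m.arm == 1).sum())}, events={int(m.event[m.arm == 1].sum())}",
            f"shared_layers: {self.spec.shared_layers}  head_layers: {self.spec.head_layers}",
            f"balance_weight: {self.spec.balance_weight} ({self.spec.ipm_kind})",
            f"best validation loss: {self.best_val_loss:.4f} at step {self.best_step}",
        ]
        if self.encoder.identity and len(self.heads[0].weights) == 1:
            lines.append("-" * 56)
            lines.append(f"{'feature':<20}{'coef arm0':>12}{'coef arm1':>12}")
            c0, c1 = self.coefficients(0), self.coefficients(1)
            for name in m.feature_names:
                lines.append(f"{name:<20}{c0[name]:>12.4f}{c1[name]:>12.4f}")
        return "\n".join(lines)


def fit_balanced_tlearner(features, arms, times, events, spec: BalancedTLearnerSpec,
                          feature_names=None) -> BalancedTLearnerResults:
    """Functional wrapper around :class:`BalancedTLearner`."""
    return BalancedTLearner(features, arms, times, events, feature_names).fit(spec)


# ---------------------------------------------------------------------------
# classical benchmarks

@dataclass
class BenchmarkTLearnerResults:
    """Per-arm classical survival models with the shared prediction contract."""

    method: str
    models: dict
    feature_names: list[str]
    encoding: object = None

    def predict_survival(self, features, arm: int, grid) -> SurvivalCurves:
        grid = np.asarray(grid, dtype=float)
        X = np.asarray(features, dtype=float)
        if self.method == "proportional-hazards":
            cph = self.models[arm]
            df = pd.DataFrame(X, columns=self.feature_names)
            sf = cph.predict_survival_function(df, times=grid[grid > 0])
            values = sf.to_numpy().T
            values = np.column_stack([np.ones(len(X)), values]) if grid[0] == 0 else values
            values = np.minimum.accumulate(np.clip(values, 0.0, 1.0), axis=1)
            return SurvivalCurves(grid, values, step=True)
        # survival forest: evaluate scikit-survival step functions manually
        rsf = self.models[arm]
        fns = rsf.predict_survival_function(X)
        values = np.empty((len(X), grid.size))
        for i, fn in enumerate(fns):
            idx = np.searchsorted(fn.x, grid, side="right")  # 0 => before first jump
            padded = np.concatenate([[1.0], fn.y])
            values[i] = padded[idx]
        values = np.minimum.accumulate(np.clip(values, 0.0, 1.0), axis=1)
        values[:, grid == 0.0] = 1.0
        return SurvivalCurves(grid, values, step=True)


def fit_benchmark_tlearner(method: str, features, arms, times, events,
                           feature_names=None, seed: int = 0,
                           **params) -> BenchmarkTLearnerResults:
    """T-learner with a classical per-arm fitter.

    method: "proportional-hazards" (lifelines CoxPHFitter) or
    "survival-forest" (scikit-survival RandomSurvivalForest).  Extra keyword
    arguments are forwarded to the underlying fitter.
    """
    X = np.asarray(features, dtype=float)
    arm = np.asarray(arms, dtype=int)
    time = np.asarray(times, dtype=float)
    event = np.asarray(events, dtype=int)
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(X.shape[1])]
    for a in (0, 1):
        if event[arm == a].sum() < 2:
            raise ValueError(f"need at least 2 events in arm {a}")
    models = {}
    if method == "proportional-hazards":
        from lifelines import CoxPHFitter

        for a in (0, 1):
            mask = arm == a
            df = pd.DataFrame(X[mask], columns=names)
            df["time"] = time[mask]
            df["event"] = event[mask]
            cph = CoxPHFitter(penalizer=params.get("penalizer", 0.0))
            cph.fit(df, duration_col="time", event_col="event")
            models[a] = cph
    elif method == "survival-forest":
        from sksurv.ensemble import RandomSurvivalForest

        for a in (0, 1):
            mask = arm == a
            y = np.empty(mask.sum(), dtype=[("event", bool), ("time", float)])
            y["event"] = event[mask].astype(bool)
            y["time"] = time[mask]
            rsf = RandomSurvivalForest(
                n_estimators=params.get("n_estimators", 100),
                max_depth=params.get("max_depth", None),
                min_samples_leaf=params.get("min_samples_leaf", 15),
                random_state=seed,
                n_jobs=1,
            )
            rsf.fit(X[mask], y)
            models[a] = rsf
    else:
        raise ValueError(f"unknown benchmark method {method!r}")
    return BenchmarkTLearnerResults(method=method, models=models, feature_names=names)


# ---------------------------------------------------------------------------
# hyperparameter tuning

def tune_hyperparameters(features, arms, times, events, grid, n_folds: int = 5,
                         seed: int = 0, feature_names=None):
    """Exhaustive grid search with k-fold cross-validation.

    Each grid point is trained on k-1 folds with the held-out fold as the
    validation set (which also drives early stopping); its score is the mean
    held-out Cox loss over folds.  A grid point whose training fails scores
    infinity instead of aborting the search.  Fold assignment is a
    deterministic function of ``seed``.

    Returns (best_spec, report) where report has one row per (spec, fold).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    rows = []
    mean_losses = []
    for gi, spec in enumerate(grid):
        fold_losses = []
        for fi, val_idx in enumerate(folds):
            try:
                model = BalancedTLearner(X, arms, times, events, feature_names)
                res = model.fit(spec, validation_idx=val_idx)
                loss = res.best_val_loss
            except Exception as exc:  # noqa: BLE001 — failed points score inf
                warnings.warn(f"grid point {gi} failed on fold {fi}: {exc}")
                loss = np.inf
            fold_losses.append(loss)
            rows.append({"grid_index": gi, "fold": fi, "val_loss": loss})
        mean_losses.append(float(np.mean(fold_losses)))
    best = int(np.argmin(mean_losses))
    report = pd.DataFrame(rows)
    report["mean_val_loss"] = report["grid_index"].map(dict(enumerate(mean_losses)))
    return grid[best], report
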