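"""End-to-end orchestration: split, tune, fit, recommend, evaluate, report.

A phase is one binary treatment comparison (e.g. organ preservation vs
surgery-based therapy; or, within surgical patients, one adjuvant regimen
vs the other).  ``run_phase`` executes the whole analysis on either a
generated synthetic cohort or a cohort loaded from CSV and writes all
artifacts (evaluation report, per-patient treatment effects, subgroup and
probability-difference tables, machine-readable run log) to an output
directory.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .causal import mediation_nde_nie, probability_difference, subgroup_ate
from .curves import default_grid
from .datagen import GeneratorConfig, default_config, generate_cohort
from .encoding import CovariateEncoder
from .ite import compute_ite, concordance_grouping
from .iptw import EvalReport, evaluate_recommendations, train_test_split
from .metrics import integrated_brier_score
from .tlearner import BalancedTLearnerSpec, fit_balanced_tlearner, fit_benchmark_tlearner, tune_hyperparameters

__all__ = ["RunConfig", "StageError", "run_phase", "load_cohort", "write_report"]

AGE_BANDS = ((0.0, 30.0), (30.0, 60.0), (60.0, np.inf))  # [0,30), [30,60], (60,inf)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one recommendation phase."""

    phase: int = 1
    generator: GeneratorConfig | None = None  # synthetic source ...
    cohort_path: str | None = None  # ... or a CSV cohort
    estimator: str = "balanced"  # balanced | proportional-hazards | survival-forest | oracle
    spec: BalancedTLearnerSpec = field(default_factory=BalancedTLearnerSpec)
    tuning_grid: list | None = None  # list of BalancedTLearnerSpec; enables CV tuning
    n_folds: int = 5
    horizon: float = 60.0
    test_fraction: float = 0.3
    seed: int = 0
    eval_covariates: list[str] | None = None  # None = all schema covariates
    include_treatment_in_adjustment: bool = True
    n_bootstrap: int = 200
    output_dir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_cohort(path, schema) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    ``schema`` is a list of (name, kind) pairs or Covariate objects.  Rows
    violating basic constraints (non-positive follow-up, non-binary arm or
    event) are reported with their line numbers; unknown columns beyond the
    expected set produce a warning and are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    names = [getattr(c, "name", None) or c[0] for c in schema]
    expected = {"patient_id", "arm", "time", "event", "cause", *names}
    unknown = set(df.columns) - expected
    if unknown:
        warnings.warn(f"ignoring unknown columns {sorted(unknown)}")
        df = df.drop(columns=sorted(unknown))
    missing = {"arm", "time", "event", *names} - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing required columns {sorted(missing)}")
    bad = []
    bad += [(i, "non-positive time") for i in df.index[df["time"] <= 0]]
    bad += [(i, "arm not in {0,1}") for i in df.index[~df["arm"].isin([0, 1])]]
    bad += [(i, "event not in {0,1}") for i in df.index[~df["event"].isin([0, 1])]]
    if df[names + ["arm", "time", "event"]].isna().any().any():
        bad += [(i, "missing value") for i in df.index[df[names + ["arm", "time", "event"]].isna().any(axis=1)]]
    if bad:
        listing = "; ".join(f"row {i + 2}: {msg}" for i, msg in bad[:20])  # +2: header + 0-base
        raise ValueError(f"malformed cohort rows: {listing}")
    if "patient_id" not in df.columns:
        df.insert(0, "patient_id", np.arange(len(df)))
    return df


def run_phase(config: RunConfig) -> tuple[EvalReport, dict]:
    """Execute one full recommendation phase.

    Returns (EvalReport, artifacts) where artifacts holds the fitted
    results object, the per-patient treatment-effect table, subgroup and
    PD tables, the mediation decomposition and the run log.  When
    ``config.output_dir`` is set everything is also written to disk.
    """
    log = {"package_version": __version__, "seed": config.seed,
           "config_hash": config.config_hash(), "stages": {}}
    artifacts: dict = {"log": log}

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = _time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                log["stages"][name] = round(_time.perf_counter() - self.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc

        return _Ctx()

    # ---- load / generate -------------------------------------------------
    with _stage("load"):
        truth = None
        if config.generator is not None:
            gen = config.generator
            cohort, truth = generate_cohort(gen)
            schema = gen.covariates
        elif config.cohort_path is not None:
            schema_cfg = default_config().covariates
            cohort = load_cohort(config.cohort_path, schema_cfg)
            schema = schema_cfg
        else:
            raise ValueError("RunConfig needs a generator or a cohort_path")
        cov_names = [c.name for c in schema]
        eval_covs = config.eval_covariates or cov_names
        missing = set(eval_covs) - set(cov_names)
        if missing:
            raise ValueError(f"eval covariates not in cohort schema: {sorted(missing)}")

    # ---- split -----------------------------------------------------------
    with _stage("split"):
        train, test = train_test_split(cohort, config.test_fraction, seed=config.seed)

    # ---- encode ----------------------------------------------------------
    with _stage("encode"):
        encoder = CovariateEncoder(schema).fit(train)
        X_train = encoder.transform(train)
        X_test = encoder.transform(test)

    # ---- tune + fit ------------------------------------------------------
    with _stage("fit"):
        results = None
        if config.estimator == "balanced":
            spec = config.spec
            if config.tuning_grid:
                spec, tune_report = tune_hyperparameters(
                    X_train, train["arm"], train["time"], train["event"],
                    config.tuning_grid, n_folds=config.n_folds, seed=config.seed,
                    feature_names=encoder.feature_names_,
                )
                artifacts["tuning_report"] = tune_report
            results = fit_balanced_tlearner(
                X_train, train["arm"], train["time"], train["event"], spec,
                feature_names=encoder.feature_names_,
            )
            results.encoding = encoder
        elif config.estimator in ("proportional-hazards", "survival-forest"):
            results = fit_benchmark_tlearner(
                config.estimator, X_train, train["arm"], train["time"], train["event"],
                feature_names=encoder.feature_names_, seed=config.seed,
            )
            results.encoding = encoder
        elif config.estimator == "oracle":
            if truth is None:
                raise ValueError("oracle estimator requires a generated cohort")
        else:
            raise ValueError(f"unknown estimator {config.estimator!r}")
        artifacts["results"] = results

    # ---- recommend -------------------------------------------------------
    with _stage("recommend"):
        if config.estimator == "oracle":
            ite_vals = truth.ite_rst[test["patient_id"].to_numpy()]
            ite_table = pd.DataFrame({
                "patient_id": test["patient_id"].to_numpy(),
                "rst_arm1": np.nan, "rst_arm0": np.nan,
                "ite": ite_vals,
                "recommended_arm": (ite_vals > 0).astype(int),
            })
        else:
            ite_table = compute_ite(results, X_test, horizon=config.horizon,
                                    patient_ids=test["patient_id"].to_numpy())
        consistency = concordance_grouping(test["arm"].to_numpy(),
                                           ite_table["recommended_arm"].to_numpy())
        ite_table["consistency"] = consistency
        artifacts["ite_table"] = ite_table

    # ---- evaluate --------------------------------------------------------
    with _stage("evaluate"):
        eval_enc = CovariateEncoder([(n, k) for n, k in
                                     [(c.name, c.kind) for c in schema if c.name in eval_covs]]).fit(train)
        Z_test = eval_enc.transform(test)
        z_names = list(eval_enc.feature_names_)
        if config.include_treatment_in_adjustment:
            Z_test = np.column_stack([Z_test, test["arm"].to_numpy(dtype=float)])
            z_names.append("actual_arm")
        consis = (consistency == "Consis").astype(int)
        ibs = {}
        if results is not None:
            for a in (0, 1):
                mask = (test["arm"] == a).to_numpy()
                tmax = test.loc[mask, "time"].max()
                h = min(config.horizon, float(tmax))
                grid = default_grid(test.loc[mask, "time"][test.loc[mask, "event"] == 1], h)
                curves = results.predict_survival(X_test[mask], a, grid)
                ibs[f"arm{a}"] = integrated_brier_score(
                    curves, test.loc[mask, "time"], test.loc[mask, "event"], h)
        report = evaluate_recommendations(
            test["time"], test["event"], consis, Z_test, feature_names=z_names,
            horizon=config.horizon, n_bootstrap=config.n_bootstrap, seed=config.seed,
            ibs=ibs,
        )
        artifacts["report"] = report

    # ---- interpret -------------------------------------------------------
    with _stage("interpret"):
        rec = ite_table["recommended_arm"].to_numpy()
        outcome = ((test["event"] == 1) & (test["time"] <= config.horizon)).astype(int).to_numpy()
        mediation = mediation_nde_nie(consis, test["arm"].to_numpy(), outcome,
                                      covariates=eval_enc.transform(test),
                                      n_bootstrap=config.n_bootstrap, seed=config.seed)
        artifacts["mediation"] = mediation

        sub_labels = np.where(rec == 1, "arm1-recommended", "arm0-recommended")
        artifacts["subgroup_ate"] = subgroup_ate(
            test["time"], test["event"], test["arm"], sub_labels,
            eval_enc.transform(test), feature_names=eval_enc.feature_names_)

        artifacts["pd_table"] = _pd_table(test, rec, schema, eval_covs,
                                          n_bootstrap=min(config.n_bootstrap, 200),
                                          seed=config.seed)

    if config.output_dir is not None:
        with _stage("write"):
            write_report(report, artifacts, config, Path(config.output_dir))
    return report, artifacts


def _pd_table(test: pd.DataFrame, rec: np.ndarray, schema, eval_covs,
              n_bootstrap: int = 200, seed: int = 0) -> pd.DataFrame:
    """One-vs-rest probability differences per categorical level and age band."""
    rows = []
    full_enc = CovariateEncoder(schema).fit(test)

    def _one(name, indicator):
        keep_cols = [c for c in full_enc.feature_names_ if not c.startswith(f"{name}=") and c != name]
        Z = full_enc.transform(test)
        idx = [full_enc.feature_names_.index(c) for c in keep_cols]
        try:
            res = probability_difference(rec, indicator, other_features=Z[:, idx],
                                         feature_names=keep_cols, name=name,
                                         n_bootstrap=n_bootstrap, seed=seed)
        except ValueError:
            return
        rows.append({
            "characteristic": res.characteristic, "pd": res.pd,
            "pd_lo": res.pd_ci[0], "pd_hi": res.pd_ci[1],
            "iptw_pd": res.iptw_pd,
            "iptw_pd_lo": None if res.iptw_pd_ci is None else res.iptw_pd_ci[0],
            "iptw_pd_hi": None if res.iptw_pd_ci is None else res.iptw_pd_ci[1],
        })

    for cov in schema:
        if cov.name not in eval_covs:
            continue
        if cov.kind == "categorical":
            for lv in (cov.levels or sorted(test[cov.name].astype(str).unique())):
                ind = (test[cov.name].astype(str) == lv).astype(int).to_numpy()
                if 0 < ind.sum() < len(ind):
                    _one(f"{cov.name}={lv}", ind)
        elif cov.name == "age":
            for lo, hi in AGE_BANDS:
                if np.isinf(hi):
                    ind = (test[cov.name] > lo).astype(int).to_numpy()
                    label = f"age>{lo:.0f}"
                elif lo == 0:
                    ind = (test[cov.name] < hi).astype(int).to_numpy()
                    label = f"age<{hi:.0f}"
                else:
                    ind = ((test[cov.name] >= lo) & (test[cov.name] <= hi)).astype(int).to_numpy()
                    label = f"age{lo:.0f}-{hi:.0f}"
                if 0 < ind.sum() < len(ind):
                    _one(label, ind)
    return pd.DataFrame(rows)


def write_report(report: EvalReport, artifacts: dict, config: RunConfig, outdir: Path) -> list[Path]:
    """JSON report + delimited tables + a plain-text summary.

    Formatting follows the usual presentation: hazard ratios to 2 decimals,
    percentages to 1.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    p = outdir / "eval_report.json"
    report.to_json(p)
    written.append(p)

    p = outdir / "eval_table.csv"
    report.to_table().to_csv(p, index=False)
    written.append(p)

    for key in ("ite_table", "subgroup_ate", "pd_table", "tuning_report"):
        if key in artifacts and artifacts[key] is not None:
            p = outdir / f"{key}.csv"
            artifacts[key].to_csv(p, index=False)
            written.append(p)

    p = outdir / "summary.txt"
    parts = [report.summary()]
    if "mediation" in artifacts:
        parts.append(artifacts["mediation"].summary())
    p.write_text("\n\n".join(parts) + "\n")
    written.append(p)

    log = dict(artifacts.get("log", {}))
    log["config"] = _jsonable(config)
    p = outdir / "run_log.json"
    p.write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    written.append(p)
    return written


def run_config_from_yaml(path) -> RunConfig:
    """Load a RunConfig from a flat YAML file (generator inlined or by path)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    gen = raw.pop("generator", None)
    spec = raw.pop("spec", None)
    cfg = RunConfig(**raw)
    if gen is not None:
        if isinstance(gen, str):
            from .datagen import load_config

            cfg.generator = load_config(gen)
        else:
            cfg.generator = default_config(**gen)
    if spec is not None:
        cfg.spec = BalancedTLearnerSpec(**{k: tuple(v) if isinstance(v, list) else v
                                           for k, v in spec.items()})
    return cfg
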