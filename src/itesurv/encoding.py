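"""Covariate encoding: reference-coded indicators + standardized continuous columns.

The encoder is fitted on training data only and serialized alongside any
fitted model so that prediction-time feature construction is identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CovariateEncoder", "UnseenLevelError"]


class UnseenLevelError(ValueError):
    """A categorical level at transform time that was absent at fit time."""


class CovariateEncoder:
    """One-hot encode categoricals (first level = reference, dropped) and
    standardize continuous covariates with training mean/sd.

    Parameters
    ----------
    schema : list of (name, kind) or list of :class:`itesurv.datagen.Covariate`
        ``kind`` is "continuous" or "categorical".  Column order of the
        output follows the schema order.
    """

    def __init__(self, schema):
        self.schema = []
        for c in schema:
            if hasattr(c, "name") and hasattr(c, "kind"):
                self.schema.append((c.name, c.kind))
            else:
                self.schema.append((c[0], c[1]))
        self._fitted = False

    def fit(self, df: pd.DataFrame) -> "CovariateEncoder":
        self.levels_: dict[str, list[str]] = {}
        self.means_: dict[str, float] = {}
        self.sds_: dict[str, float] = {}
        for name, kind in self.schema:
            if name not in df.columns:
                raise KeyError(f"covariate {name!r} missing from data")
            if kind == "continuous":
                col = df[name].to_numpy(dtype=float)
                sd = float(np.std(col, ddof=0))
                if sd == 0.0:
                    raise ValueError(f"continuous covariate {name!r} has zero variance")
                self.means_[name] = float(np.mean(col))
                self.sds_[name] = sd
            else:
                self.levels_[name] = sorted(pd.unique(df[name].astype(str)))
        self.feature_names_ = []
        for name, kind in self.schema:
            if kind == "continuous":
                self.feature_names_.append(name)
            else:
                self.feature_names_.extend(f"{name}={lv}" for lv in self.levels_[name][1:])
        self._fitted = True
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("encoder not fitted")
        cols = []
        for name, kind in self.schema:
            if kind == "continuous":
                z = (df[name].to_numpy(dtype=float) - self.means_[name]) / self.sds_[name]
                cols.append(z)
            else:
                vals = df[name].astype(str).to_numpy()
                known = set(self.levels_[name])
                unseen = set(vals) - known
                if unseen:
                    raise UnseenLevelError(
                        f"covariate {name!r}: unseen level(s) {sorted(unseen)!r}"
                    )
                for lv in self.levels_[name][1:]:
                    cols.append((vals == lv).astype(float))
        return np.column_stack(cols) if cols else np.empty((len(df), 0))

    def fit_transform(self, df: pd.DataFrame) -> np.ndarray:
        return self.fit(df).transform(df)

    # serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": [list(s) for s in self.schema],
            "levels": self.levels_,
            "means": self.means_,
            "sds": self.sds_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateEncoder":
        enc = cls([tuple(s) for s in d["schema"]])
        enc.levels_ = {k: list(v) for k, v in d["levels"].items()}
        enc.means_ = {k: float(v) for k, v in d["means"].items()}
        enc.sds_ = {k: float(v) for k, v in d["sds"].items()}
        enc.feature_names_ = []
        for name, kind in enc.schema:
            if kind == "continuous":
                enc.feature_names_.append(name)
            else:
                enc.feature_names_.extend(f"{name}={lv}" for lv in enc.levels_[name][1:])
        enc._fitted = True
        return enc
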