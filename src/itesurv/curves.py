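"""Predicted / estimated survival curves on a common time grid."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SurvivalCurves", "default_grid"]


def default_grid(event_times, horizon: float) -> np.ndarray:
    """Monthly grid over [0, horizon] united with the observed event times.

    Step-function curves (Breslow/Kaplan-Meier based) then integrate exactly,
    because every jump location is a grid point.
    """
    et = np.asarray(event_times, dtype=float)
    et = et[(et > 0) & (et <= horizon)]
    grid = np.union1d(np.arange(0.0, horizon + 0.5, 1.0), et)
    if grid[-1] < horizon:
        grid = np.append(grid, horizon)
    return grid


@dataclass
class SurvivalCurves:
    """A bundle of per-patient survival functions S(t|x) on one grid.

    ``times`` is (T,), starting at 0 and strictly increasing; ``values`` is
    (n_patients, T) with S(0)=1 and each row non-increasing in [0, 1].
    ``step`` records whether the curves are right-continuous step functions
    (Kaplan-Meier / Breslow type), which selects exact rectangle integration
    in RST computations.
    """

    times: np.ndarray
    values: np.ndarray
    step: bool = True

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.validate()

    def validate(self) -> None:
        t, v = self.times, self.values
        if t.ndim != 1 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must start at 0 and be strictly increasing")
        if v.shape[1] != t.size:
            raise ValueError("values and grid sizes differ")
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if not np.allclose(v[:, 0], 1.0):
            raise ValueError("S(0) must equal 1")
        if np.any(np.diff(v, axis=1) > 1e-9):
            raise ValueError("survival curves must be non-increasing")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    def at(self, t: float) -> np.ndarray:
        """S(t) per patient; step curves evaluate right-continuously."""
        if t < 0 or t > self.times[-1]:
            raise ValueError(f"t={t} outside the curve grid")
        if self.step:
            idx = np.searchsorted(self.times, t, side="right") - 1
            return self.values[:, idx].copy()
        return np.array([np.interp(t, self.times, row) for row in self.values])

    def truncated(self, horizon: float) -> "SurvivalCurves":
        """Restrict to [0, horizon], inserting the horizon as a grid point."""
        if horizon > self.times[-1]:
            raise ValueError("horizon exceeds the curve grid")
        keep = self.times <= horizon
        t = self.times[keep]
        v = self.values[:, keep]
        if t[-1] < horizon:
            t = np.append(t, horizon)
            v = np.column_stack([v, self.at(horizon)])
        return SurvivalCurves(t, v, step=self.step)
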