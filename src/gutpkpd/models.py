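"""Structural models bound to a dataset's observation layout.

A *bound model* couples a forward evaluator with the flat observation
arrays of a :class:`~gutpkpd.data.Dataset`, so that the estimation engine
can map a parameter matrix straight to per-observation predictions:

    bound.predict(theta (n_subjects, p)) -> {response: flat predictions}

All subjects of a bound model share the dosing regimen (one trial arm).
"""

from __future__ import annotations

import numpy as np

from .data import Dataset
from .dosing import Regimen
from .pkmodels import (PlasmaClosedFormEvaluator, TransitPKEvaluator,
                       make_grid)
from .turnover import ShannonTurnoverEvaluator

__all__ = [
    "PlasmaBoundModel",
    "PKTransitBoundModel",
    "TurnoverBoundModel",
    "CurveBoundModel",
]


def _grid_indices(grid: np.ndarray, times: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(grid, times - 1e-9)
    if np.any(np.abs(grid[np.clip(idx, 0, len(grid) - 1)] - times) > 1e-6):
        raise ValueError("observation times missing from the grid")
    return idx


class PlasmaBoundModel:
    """Closed-form plasma concentrations (no integration grid)."""

    def __init__(self, dataset: Dataset, regimen: Regimen,
                 n_compartments: int = 2):
        self.ev = PlasmaClosedFormEvaluator(regimen, n_compartments)
        self.param_names = self.ev.param_names
        self.responses = ["plasma"]
        self.subj_idx, self.times, *_ = dataset.flat("plasma")

    def predict(self, theta: np.ndarray) -> dict:
        theta = np.atleast_2d(theta)
        flat_theta = theta[self.subj_idx]
        return {"plasma": self.ev.conc(flat_theta, self.times)}


class PKTransitBoundModel:
    """Plasma + fecal predictions from the full transit-chain system."""

    def __init__(self, dataset: Dataset, regimen: Regimen, *,
                 n_transit: int = 3, n_compartments: int = 2,
                 dt_dense: float = 0.25, dt_sparse: float = 12.0):
        self.regimen = regimen
        obs_times = []
        self._flat = {}
        responses = [r for r in ("plasma", "fecal") if r in dataset.responses]
        for r in responses:
            idx, t, *_ = dataset.flat(r)
            self._flat[r] = (idx, t)
            obs_times.append(t)
        all_t = np.concatenate(obs_times) if obs_times else np.array([1.0])
        t_end = max(float(all_t.max()), regimen.end_of_treatment_h) + 1e-9
        grid = make_grid(regimen, t_end, extra_times=np.unique(all_t),
                         dt_dense=dt_dense, dt_sparse=dt_sparse)
        self.grid = grid
        self.ev = TransitPKEvaluator(regimen, grid, n_transit=n_transit,
                                     n_compartments=n_compartments)
        self.param_names = self.ev.param_names
        self.responses = responses
        self._gidx = {r: _grid_indices(grid, t)
                      for r, (idx, t) in self._flat.items()}

    def predict(self, theta: np.ndarray) -> dict:
        theta = np.atleast_2d(theta)
        states = self.ev.states(theta)
        out = {}
        if "plasma" in self.responses:
            conc = self.ev.plasma_conc(states, theta)
            idx, _ = self._flat["plasma"]
            out["plasma"] = conc[idx, self._gidx["plasma"]]
        if "fecal" in self.responses:
            conc = self.ev.fecal_conc(states, theta)
            idx, _ = self._flat["fecal"]
            out["fecal"] = conc[idx, self._gidx["fecal"]]
        return out

    def fecal_conc_on(self, theta: np.ndarray, grid: np.ndarray) -> np.ndarray:
        """Free fecal concentration for each subject on an arbitrary grid (h)."""
        theta = np.atleast_2d(theta)
        ev = TransitPKEvaluator(self.regimen, grid,
                                n_transit=self.ev.n_transit,
                                n_compartments=self.ev.n_compartments)
        states = ev.states(theta)
        return ev.fecal_conc(states, theta)


class TurnoverBoundModel:
    """Shannon-index turnover model with per-subject concentration forcing."""

    def __init__(self, dataset: Dataset, grid_days: np.ndarray,
                 cf_grid: np.ndarray):
        self.ev = ShannonTurnoverEvaluator(grid_days, cf_grid)
        self.param_names = self.ev.param_names
        self.responses = ["shannon"]
        idx, t_h, *_ = dataset.flat("shannon")
        self.subj_idx = idx
        self._gidx = _grid_indices(np.round(grid_days, 9),
                                   np.round(t_h / 24.0, 9))

    def predict(self, theta: np.ndarray) -> dict:
        si = self.ev.trajectories(np.atleast_2d(theta))
        return {"shannon": si[self.subj_idx, self._gidx]}


class CurveBoundModel:
    """Arbitrary regression function f(theta_row, t) (test scaffolding)."""

    def __init__(self, dataset: Dataset, fn, param_names,
                 response: str = "plasma"):
        self.fn = fn
        self.param_names = tuple(param_names)
        self.responses = [response]
        self.response = response
        self.subj_idx, self.times, *_ = dataset.flat(response)

    def predict(self, theta: np.ndarray) -> dict:
        theta = np.atleast_2d(theta)
        flat = theta[self.subj_idx]
        return {self.response: self.fn(flat, self.times)}
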