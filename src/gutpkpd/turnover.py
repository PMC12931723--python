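"""Indirect-response (turnover) model for Shannon diversity under antibiotics.

Diversity follows dSI/dt = Rin - kout' * SI with Rin = SI0 * kout fixed by
the no-drug steady state, and the free fecal antibiotic concentration Cf
stimulating the loss rate:

    kout'(t) = kout * (1 + Emax * Cf(t) / (EC50 + Cf(t)))

SI is therefore confined to [SI0 / (1 + Emax), SI0].  The ODE is linear with
a time-varying coefficient; it is integrated exactly on a grid on which the
effect is held piecewise constant (interval-mean Cf), which is what the
batched evaluator below does for every subject at once.

Time unit: days.  kout in 1/day.  Cf in ug/g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = ["PDParameters", "shannon_trajectory", "ShannonTurnoverEvaluator"]


@dataclass(frozen=True)
class PDParameters:
    """Turnover-model parameters.

    SI0 : baseline Shannon index (log2 units); kout : loss rate (1/day);
    Emax : maximal fractional increase of kout (dimensionless, e.g. 0.78 for
    a 78% increase); EC50 : free fecal concentration (ug/g) at half-maximal
    stimulation.  Rin = SI0 * kout is derived, never stored.
    """

    SI0: float
    kout: float
    Emax: float
    EC50: float

    def __post_init__(self):
        if self.SI0 <= 0 or self.kout <= 0 or self.EC50 <= 0:
            raise ValueError("SI0, kout and EC50 must be positive")
        if self.Emax < 0:
            raise ValueError("Emax must be non-negative")

    @property
    def Rin(self) -> float:
        return self.SI0 * self.kout

    def as_array(self) -> np.ndarray:
        return np.array([self.SI0, self.kout, self.Emax, self.EC50])


PD_PARAM_NAMES = ("SI0", "kout", "Emax", "EC50")


class ShannonTurnoverEvaluator:
    """Batched exact piecewise integration of the turnover model.

    Parameters
    ----------
    grid_days : (g,) increasing times in days starting at the time at which
        SI(t0) = SI0 (treatment start; diversity is at steady state before).
    cf_grid : (n, g) free fecal concentration per subject on the grid.
    """

    param_names = PD_PARAM_NAMES

    def __init__(self, grid_days: np.ndarray, cf_grid: np.ndarray):
        self.grid = np.asarray(grid_days, dtype=float)
        cf = np.atleast_2d(np.asarray(cf_grid, dtype=float))
        if np.any(cf < 0):
            raise ValueError("free fecal concentrations must be non-negative")
        if cf.shape[1] != len(self.grid):
            raise ValueError("cf_grid does not match the time grid")
        self.cf_mid = 0.5 * (cf[:, :-1] + cf[:, 1:])
        self.cf = cf
        self.dt = np.diff(self.grid)

    def trajectories(self, theta: np.ndarray) -> np.ndarray:
        """SI (n, g) for parameter rows ordered as (SI0, kout, Emax, EC50)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        si0, kout, emax, ec50 = (theta[:, i][:, None] for i in range(4))
        # effect on each interval, from the interval-mean concentration
        eff = emax * self.cf_mid / (ec50 + self.cf_mid)
        k = kout * (1.0 + eff)                       # (n, g-1)
        decay = np.exp(-k * self.dt[None, :])
        target = si0 / (1.0 + eff)                   # Rin / kout'
        n = theta.shape[0]
        out = np.empty((n, len(self.grid)))
        si = np.broadcast_to(si0[:, 0], (n,)).copy()
        out[:, 0] = si
        for j in range(len(self.dt)):
            si = target[:, j] + (si - target[:, j]) * decay[:, j]
            out[:, j + 1] = si
        return out


def shannon_trajectory(pd: PDParameters, cf: Trajectory, times) -> Trajectory:
    """Integrate the turnover model against a free-fecal-concentration input.

    ``cf`` may be in hours or days; ``times`` are in days.  The
    concentration grid must cover the requested times (its last point may
    be extended by zero-order hold of the final value).
    """
    times = np.asarray(times, dtype=float)
    cfd = cf.to_days()
    if np.any(cfd.values < 0):
        raise ValueError("cf contains negative values")
    t0 = min(times.min(), cfd.times.min(), 0.0)
    grid = np.unique(np.concatenate([
        cfd.times, times, np.arange(t0, times.max() + 1e-9, 0.02)]))
    cf_on_grid = np.interp(grid, cfd.times, cfd.values,
                           left=0.0, right=cfd.values[-1])
    ev = ShannonTurnoverEvaluator(grid, cf_on_grid[None, :])
    si = ev.trajectories(pd.as_array()[None, :])[0]
    return Trajectory(times, np.interp(times, grid, si), "shannon", "day")
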