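"""Plasma and fecal antibiotic kinetics.

Structural model: one- or two-compartment disposition with first-order
elimination from the central compartment.  Central elimination is split into
an intestinal fraction ``f_gut`` feeding a chain of ``n_transit`` identical
transit compartments (rate ``k_t``) that empties into a fecal compartment
(elimination rate ``k_f``).  The observed fecal concentration is the
instantaneous excretion flux divided by the stool production rate:

    C_fecal(t) [ug/g] = k_f * A_fecal(t) / F_w

with amounts in mg, rates in 1/h and ``F_w`` the fecal weight, fixed at
200 g/day.  That mapping is the single place to change if an alternative
amount-to-concentration convention is required.

All systems are linear, so multiple doses are handled by superposition /
piecewise-constant-input propagation with matrix exponentials.  Plasma
concentrations also have closed forms used by the fast plasma-only models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .dosing import IV_INFUSION, ORAL, Regimen
from .trajectory import Trajectory

__all__ = [
    "PKParameters",
    "plasma_closed_form",
    "make_grid",
    "TransitPKEvaluator",
    "PlasmaClosedFormEvaluator",
    "plasma_concentration",
    "fecal_concentration",
]

FECAL_WEIGHT_G_PER_DAY = 200.0


@dataclass(frozen=True)
class PKParameters:
    """Structural PK parameters of one compound.

    Rates in 1/h, volumes in L, clearances in L/h.  ``f_gut`` is the
    fraction of central elimination routed to the gut (effective fraction
    recovered in feces, degradation folded in).  ``ka`` is the first-order
    absorption rate for oral dosing (0 for IV).
    """

    CL: float
    V1: float
    Q: float = 0.0
    V2: float = 1.0
    f_gut: float = 0.0
    k_t: float = 0.2
    k_f: float = 0.05
    n_transit: int = 3
    ka: float = 0.0
    n_compartments: int = 2
    F_w: float = FECAL_WEIGHT_G_PER_DAY

    def __post_init__(self):
        if min(self.CL, self.V1) <= 0:
            raise ValueError("CL and V1 must be positive")
        if self.n_compartments == 2 and (self.Q < 0 or self.V2 <= 0):
            raise ValueError("Q must be >= 0 and V2 > 0")
        if not 0.0 <= self.f_gut <= 1.0:
            raise ValueError("f_gut must lie in [0, 1]")
        if self.k_t <= 0 or self.k_f <= 0:
            raise ValueError("transit and fecal rates must be positive")
        if self.n_transit not in (3, 4):
            raise ValueError("n_transit must be 3 or 4")
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")

    def as_array(self) -> np.ndarray:
        return np.array([self.CL, self.V1, self.Q, self.V2,
                         self.f_gut, self.k_t, self.k_f], dtype=float)


PK_PARAM_NAMES = ("CL", "V1", "Q", "V2", "f_gut", "k_t", "k_f")


# ---------------------------------------------------------------------------
# closed-form plasma concentration (IV infusion 1/2-cpt, oral 1-cpt)
# ---------------------------------------------------------------------------

def _step_response(t, lam, coef, V1):
    """Central concentration under a unit-rate infusion switched on at 0.

    ``lam``/``coef`` are (..., k) exponential modes; zero for t < 0.
    sum_k coef_k (1 - exp(-lam_k t)) / lam_k / V1
    """
    t = np.maximum(t, 0.0)
    with np.errstate(over="ignore"):
        out = -np.expm1(-lam * t[..., None]) / lam * coef
    return out.sum(axis=-1) / V1


def _disposition_modes(CL, V1, Q, V2, n_compartments):
    """Exponential modes (lam, coef) of the central-amount impulse response."""
    CL, V1, Q, V2 = np.broadcast_arrays(
        np.atleast_1d(np.asarray(CL, float)), np.asarray(V1, float),
        np.asarray(Q, float), np.asarray(V2, float))
    k10 = CL / V1
    if n_compartments == 1:
        lam = k10[..., None]
        coef = np.ones_like(lam)
        return lam, coef
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    denom = np.where(lam1 - lam2 == 0.0, np.finfo(float).tiny, lam1 - lam2)
    a1 = (lam1 - k21) / denom
    a2 = (k21 - lam2) / denom
    return np.stack([lam1, lam2], axis=-1), np.stack([a1, a2], axis=-1)


def plasma_closed_form(CL, V1, Q, V2, regimen: Regimen, times,
                       n_compartments: int = 2, ka=None):
    """Plasma concentration (ug/mL) at ``times`` (h) by dose superposition.

    Parameters may be scalars or arrays of shape (n,); ``times`` may be
    (m,) (then output is (n, m) or (m,)) or, when parameters are (n,),
    an (n-aligned) flat array the same shape as each parameter.
    """
    times = np.asarray(times, dtype=float)
    scalar_params = np.isscalar(CL) or np.ndim(CL) == 0
    CLa = np.atleast_1d(np.asarray(CL, float))
    flat = CLa.shape == times.shape and not scalar_params
    if not flat and not scalar_params:
        times = times[None, :]  # (1, m) against (n, 1) params

    def _p(x):
        xa = np.atleast_1d(np.asarray(x, float))
        if flat or scalar_params:
            return xa
        return xa[:, None]

    if regimen.route == ORAL:
        if ka is None:
            raise ValueError("oral dosing requires ka")
        ke = _p(CL) / _p(V1)
        kaa = _p(ka)
        conc = np.zeros(np.broadcast_shapes(times.shape, ke.shape))
        for td in regimen.dose_times():
            dt = np.maximum(times - td, 0.0)
            on = times >= td
            term = (regimen.dose_mg * kaa / (_p(V1) * (kaa - ke))
                    * (np.exp(-ke * dt) - np.exp(-kaa * dt)))
            conc = conc + np.where(on, term, 0.0)
    else:
        lam, coef = _disposition_modes(_p(CL), _p(V1), _p(Q), _p(V2),
                                       n_compartments)
        rate = regimen.infusion_rate_mg_h
        tau = regimen.infusion_h
        conc = np.zeros(np.broadcast_shapes(times.shape, lam.shape[:-1]))
        for td in regimen.dose_times():
            conc = conc + rate * (_step_response(times - td, lam, coef, _p(V1))
                                  - _step_response(times - td - tau, lam, coef, _p(V1)))
    if scalar_params and conc.ndim > times.ndim:
        conc = conc[0]
    return conc


# ---------------------------------------------------------------------------
# time grids and batched propagation of the full linear system
# ---------------------------------------------------------------------------

def make_grid(regimen: Regimen, t_end: float, *, extra_times=(),
              dt_dense: float = 0.25, t_switch: float | None = None,
              dt_sparse: float = 12.0) -> np.ndarray:
    """Build an integration grid containing all dosing discontinuities.

    Dense spacing ``dt_dense`` up to ``t_switch`` (default: 24 h past the end
    of treatment), then ``dt_sparse`` until ``t_end``.  ``extra_times`` (e.g.
    observation times) are inserted exactly.
    """
    if t_switch is None:
        t_switch = min(regimen.end_of_treatment_h + 24.0, t_end)
    pts = {0.0, float(t_end), float(t_switch)}
    for td in regimen.dose_times():
        if td <= t_end:
            pts.add(float(td))
            if regimen.route == IV_INFUSION:
                pts.add(float(min(td + regimen.infusion_h, t_end)))
    for t in np.atleast_1d(np.asarray(extra_times, dtype=float)):
        if 0.0 <= t <= t_end:
            pts.add(float(t))
    # fill gaps
    anchors = np.array(sorted(pts))
    filled = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        dt = dt_dense if a < t_switch else dt_sparse
        n = max(1, int(np.ceil((b - a) / dt - 1e-9)))
        filled.append(a + (b - a) * np.arange(n) / n)
    filled.append(anchors[-1:])
    grid = np.concatenate(filled)
    # merge points closer than 1e-4 h so no spurious micro-segments remain
    grid = np.unique(np.round(grid, 4))
    return grid


class _SegmentPlan:
    """Per-interval dt index and constant infusion rate for a grid/regimen."""

    def __init__(self, grid: np.ndarray, regimen: Regimen):
        self.grid = grid
        dts = np.round(np.diff(grid), 9)
        self.unique_dts, self.dt_index = np.unique(dts, return_inverse=True)
        mid = 0.5 * (grid[:-1] + grid[1:])
        self.rates = np.zeros(len(mid))
        self.bolus = np.zeros(len(grid))  # amount entering depot AT grid point
        if regimen.route == IV_INFUSION:
            rate = regimen.infusion_rate_mg_h
            for td in regimen.dose_times():
                on = (mid > td) & (mid < td + regimen.infusion_h)
                self.rates[on] += rate
        else:
            for td in regimen.dose_times():
                i = np.searchsorted(grid, td - 1e-9)
                if i < len(grid) and abs(grid[i] - td) < 1e-6:
                    self.bolus[i] += regimen.dose_mg


class TransitPKEvaluator:
    """Batched forward evaluation of the plasma->transit->fecal system.

    Built once per (regimen, grid, structure); ``states(theta)`` then
    propagates a batch of subjects whose parameters are the rows of
    ``theta`` ordered as :data:`PK_PARAM_NAMES` (plus ``ka`` appended for
    oral dosing).

    With ``track_elimination=True`` two bookkeeping states accumulate
    extra-intestinal and fecal elimination so that mass balance can be
    checked exactly.
    """

    def __init__(self, regimen: Regimen, grid: np.ndarray, *,
                 n_transit: int = 3, n_compartments: int = 2,
                 track_elimination: bool = False,
                 F_w: float = FECAL_WEIGHT_G_PER_DAY):
        self.regimen = regimen
        self.grid = np.asarray(grid, dtype=float)
        self.n_transit = int(n_transit)
        self.n_compartments = int(n_compartments)
        self.track_elimination = bool(track_elimination)
        self.F_w = float(F_w)
        self.oral = regimen.route == ORAL
        self.plan = _SegmentPlan(self.grid, regimen)
        # state layout: [depot?] central [peripheral?] T1..Tn fecal [E_other E_fecal]?
        self.i_depot = 0 if self.oral else None
        self.i_central = (1 if self.oral else 0)
        self.i_periph = self.i_central + 1 if self.n_compartments == 2 else None
        first_transit = self.i_central + self.n_compartments
        self.i_transit = list(range(first_transit, first_transit + self.n_transit))
        self.i_fecal = first_transit + self.n_transit
        self.n_states = self.i_fecal + 1 + (2 if track_elimination else 0)
        self.param_names = PK_PARAM_NAMES + (("ka",) if self.oral else ())
        self._buf = None  # reusable output buffer (first-touch cost paid once)

    # -- system matrix -----------------------------------------------------
    def _matrices(self, theta: np.ndarray):
        n = theta.shape[0]
        CL, V1, Q, V2, f_gut, k_t, k_f = (theta[:, i] for i in range(7))
        ka = theta[:, 7] if self.oral else None
        A = np.zeros((n, self.n_states, self.n_states))
        ic, ip = self.i_central, self.i_periph
        k10 = CL / V1
        if self.oral:
            A[:, self.i_depot, self.i_depot] = -ka
            A[:, ic, self.i_depot] = ka
        A[:, ic, ic] = -k10
        if ip is not None:
            k12, k21 = Q / V1, Q / V2
            A[:, ic, ic] -= k12
            A[:, ic, ip] = k21
            A[:, ip, ic] = k12
            A[:, ip, ip] = -k21
        prev = ic
        for j, it in enumerate(self.i_transit):
            if j == 0:
                A[:, it, ic] = f_gut * k10
            else:
                A[:, it, prev] = k_t
            A[:, it, it] = -k_t
            prev = it
        A[:, self.i_fecal, prev] = k_t
        A[:, self.i_fecal, self.i_fecal] = -k_f
        if self.track_elimination:
            ie_other, ie_fec = self.n_states - 2, self.n_states - 1
            A[:, ie_other, ic] = (1.0 - f_gut) * k10
            A[:, ie_fec, self.i_fecal] = k_f
        b = np.zeros((n, self.n_states))
        b[:, self.i_depot if self.oral else ic] = 1.0
        return A, b

    def states(self, theta: np.ndarray) -> np.ndarray:
        """Propagate; returns amounts of shape (n, n_grid, n_states).

        The returned array is a buffer owned by the evaluator and is
        overwritten by the next call; copy it if it must persist.
        """
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        n = theta.shape[0]
        A, b = self._matrices(theta)
        s = self.n_states
        # augmented exponentials per unique step size
        P = np.empty((len(self.plan.unique_dts), n, s, s))
        M = np.empty((len(self.plan.unique_dts), n, s))
        aug = np.zeros((s + 1, s + 1))
        for k, dt in enumerate(self.plan.unique_dts):
            for i in range(n):
                aug[:s, :s] = A[i] * dt
                aug[:s, s] = b[i] * dt
                E = expm(aug)
                P[k, i] = E[:s, :s]
                M[k, i] = E[:s, s]
        if self._buf is None or self._buf.shape != (n, len(self.grid), s):
            self._buf = np.zeros((n, len(self.grid), s))
            self._buf.fill(0.0)  # touch pages up front
        out = self._buf
        x = np.zeros((n, s))
        bolus = self.plan.bolus
        depot = self.i_depot if self.oral else self.i_central
        if bolus[0]:
            x[:, depot] += bolus[0]
        out[:, 0] = x
        for j in range(len(self.grid) - 1):
            k = self.plan.dt_index[j]
            r = self.plan.rates[j]
            x = np.einsum("nij,nj->ni", P[k], x)
            if r != 0.0:
                x = x + r * M[k]
            if bolus[j + 1]:
                x = x.copy()
                x[:, depot] += bolus[j + 1]
            out[:, j + 1] = x
        return out

    # -- observables -------------------------------------------------------
    def plasma_conc(self, states: np.ndarray, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return states[:, :, self.i_central] / theta[:, 1][:, None]

    def fecal_conc(self, states: np.ndarray, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        k_f = theta[:, 6][:, None]
        # mg/h divided by g/h, times 1000 ug/mg
        return 24000.0 * k_f * states[:, :, self.i_fecal] / self.F_w


class PlasmaClosedFormEvaluator:
    """Closed-form plasma-only model (1- or 2-compartment IV, 1-cpt oral).

    Fast path for plasma-only fits: evaluates directly at flat observation
    times with per-observation subject parameters, no integration grid.
    """

    def __init__(self, regimen: Regimen, n_compartments: int = 2):
        self.regimen = regimen
        self.n_compartments = n_compartments
        self.oral = regimen.route == ORAL
        if self.oral:
            self.param_names = ("CL", "V1", "ka")
        elif n_compartments == 2:
            self.param_names = ("CL", "V1", "Q", "V2")
        else:
            self.param_names = ("CL", "V1")

    def conc(self, theta: np.ndarray, times: np.ndarray) -> np.ndarray:
        """theta (m, p) aligned with flat times (m,) -> concentrations (m,)."""
        theta = np.atleast_2d(theta)
        if self.oral:
            return plasma_closed_form(theta[:, 0], theta[:, 1], 0.0, 1.0,
                                      self.regimen, times, 1, ka=theta[:, 2])
        if self.n_compartments == 1:
            return plasma_closed_form(theta[:, 0], theta[:, 1], 0.0, 1.0,
                                      self.regimen, times, 1)
        return plasma_closed_form(theta[:, 0], theta[:, 1], theta[:, 2],
                                  theta[:, 3], self.regimen, times, 2)


# ---------------------------------------------------------------------------
# user-facing single-subject operations
# ---------------------------------------------------------------------------

def plasma_concentration(pk: PKParameters, regimen: Regimen, times) -> Trajectory:
    """Plasma concentration trajectory (ug/mL) at ``times`` in hours."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    conc = plasma_closed_form(pk.CL, pk.V1, pk.Q, pk.V2, regimen, times,
                              pk.n_compartments,
                              ka=pk.ka if regimen.route == ORAL else None)
    return Trajectory(times, np.asarray(conc, dtype=float), "plasma", "h")


def fecal_concentration(pk: PKParameters, regimen: Regimen, times,
                        charcoal=None) -> Trajectory | tuple:
    """Fecal concentration trajectory (ug/g) at ``times`` in hours.

    Without charcoal, returns the total (= free) fecal concentration.  With a
    :class:`~gutpkpd.charcoal.CharcoalParameters`, delegates to the
    adsorption-coupled system and returns ``(total, free)`` trajectories.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if charcoal is not None:
        from .charcoal import fecal_concentration_with_charcoal
        return fecal_concentration_with_charcoal(pk, regimen, charcoal, times)
    t_end = max(times.max(), regimen.end_of_treatment_h) + 1e-6
    grid = make_grid(regimen, t_end, extra_times=times)
    ev = TransitPKEvaluator(regimen, grid, n_transit=pk.n_transit,
                            n_compartments=pk.n_compartments, F_w=pk.F_w)
    theta = np.concatenate([pk.as_array(), [pk.ka]])[None, :] \
        if regimen.route == ORAL else pk.as_array()[None, :]
    st = ev.states(theta)
    conc = ev.fecal_conc(st, theta)[0]
    vals = np.interp(times, grid, conc)
    return Trajectory(times, vals, "fecal_total", "h")
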