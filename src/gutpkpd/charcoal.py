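"""DAV132 charcoal kinetics and antibiotic adsorption.

DAV132 delivers activated charcoal to the lower gastro-intestinal tract
through a chain of three transit compartments:

    dAa1/dt = -kt * Aa1          (doses enter Aa1)
    dAa2/dt =  kt * Aa1 - kt * Aa2
    dAa3/dt =  kt * Aa2 - kt * Aa3
    dAf/dt  =  kt * Aa3 - kf * Af

All stages are first order, so the response to a dosing schedule is the
superposition of single-dose Erlang(3)->elimination responses, for which the
closed form is implemented below.

Adsorption of antibiotic onto luminal charcoal is bilinear: the binding rate
is ``k_ads * Af_charc(t) * A_free`` applied in the last transit compartment
and the fecal compartment (where the released charcoal resides).  Bound drug
moves to a bound pool that is excreted with the same fecal rate but does not
contribute to the free fecal concentration driving the pharmacodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .dosing import Regimen, dav132_regimen
from .pkmodels import PKParameters, make_grid
from .trajectory import Trajectory

__all__ = [
    "CharcoalParameters",
    "charcoal_states",
    "charcoal_amount",
    "adsorption_rate",
    "fecal_concentration_with_charcoal",
]


@dataclass(frozen=True)
class CharcoalParameters:
    """DAV132 kinetic parameters and drug-specific adsorption constant.

    ``kt_DAV132``/``kf_Charc`` in 1/h, ``k_ads`` in 1/(mg.h) (zero for a
    compound the charcoal does not bind, e.g. avibactam), ``dose_mg`` per
    administration.
    """

    kt_DAV132: float
    kf_Charc: float
    k_ads: float = 0.0
    dose_mg: float = 7500.0
    n_days: int = 7
    start_h: float = 0.0

    def __post_init__(self):
        if self.kt_DAV132 <= 0 or self.kf_Charc <= 0:
            raise ValueError("charcoal rate constants must be positive")
        if self.k_ads < 0:
            raise ValueError("k_ads must be non-negative")
        if self.dose_mg <= 0:
            raise ValueError("dose must be positive")

    def regimen(self) -> Regimen:
        return dav132_regimen(self.dose_mg / 1000.0, self.n_days, self.start_h)

    def dose_times(self) -> np.ndarray:
        return self.regimen().dose_times()


def _erlang_chain_states(t, kt, kf, dose):
    """Single-dose closed form for (Aa1, Aa2, Aa3, Af) at times t >= 0.

    Aa_j are Erlang stages of rate kt; Af integrates the chain output
    against first-order loss kf.  Uses the a = kt - kf partial-fraction
    form, with a series fallback near kt == kf.
    """
    t = np.asarray(t, dtype=float)
    tp = np.maximum(t, 0.0)
    on = t >= 0
    e_kt = np.exp(-kt * tp)
    aa1 = dose * e_kt
    aa2 = dose * kt * tp * e_kt
    aa3 = dose * 0.5 * (kt * tp) ** 2 * e_kt
    a = kt - kf
    if abs(a) * tp.max(initial=0.0) > 1e-6:
        poly = 1.0 + a * tp + 0.5 * (a * tp) ** 2
        af = dose * (kt / a) ** 3 * np.exp(-kf * tp) * (1.0 - np.exp(-a * tp) * poly)
    else:  # kt ~ kf: Af = dose * kt^3 t^3 e^{-kt t} / 6 at leading order
        af = dose * (kt * tp) ** 3 * e_kt / 6.0
    zero = np.zeros_like(tp)
    return tuple(np.where(on, x, zero) for x in (aa1, aa2, aa3, af))


def charcoal_states(cp: CharcoalParameters, times) -> np.ndarray:
    """Amounts (n_times, 4) in the three transit stages and the gut pool."""
    times = np.asarray(times, dtype=float)
    out = np.zeros((len(times), 4))
    for td in cp.dose_times():
        st = _erlang_chain_states(times - td, cp.kt_DAV132, cp.kf_Charc, cp.dose_mg)
        for j in range(4):
            out[:, j] += st[j]
    return out


def charcoal_amount(cp: CharcoalParameters, times) -> Trajectory:
    """Activated charcoal amount in the lower GI tract (mg) over time (h)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    af = charcoal_states(cp, times)[:, 3]
    return Trajectory(times, af, "charcoal", "h")


def charcoal_amount_at(cp: CharcoalParameters, t) -> np.ndarray:
    """Vectorized Af_charc(t); helper for ODE right-hand sides."""
    t = np.asarray(t, dtype=float)
    af = np.zeros_like(t)
    for td in cp.dose_times():
        af = af + _erlang_chain_states(t - td, cp.kt_DAV132, cp.kf_Charc,
                                       cp.dose_mg)[3]
    return af


def adsorption_rate(fecal_free_amount, af_charc, k_ads) -> np.ndarray:
    """Binding rate (mg/h) of free drug onto luminal charcoal."""
    free = np.asarray(fecal_free_amount, dtype=float)
    charc = np.asarray(af_charc, dtype=float)
    if np.any(free < 0) or np.any(charc < 0) or k_ads < 0:
        raise ValueError("adsorption inputs must be non-negative")
    return k_ads * charc * free


def fecal_concentration_with_charcoal(pk: PKParameters, regimen: Regimen,
                                      cp: CharcoalParameters, times,
                                      rtol: float = 1e-8,
                                      atol: float = 1e-10):
    """Total and free fecal concentration (ug/g) under DAV132 co-dosing.

    Integrates the drug system with the time-varying bilinear binding term
    (charcoal trajectory entered in closed form), restarting the integrator
    at every dosing discontinuity.  Returns ``(total, free)`` trajectories.
    """
    times = np.asarray(times, dtype=float)
    t_end = max(times.max(), regimen.end_of_treatment_h,
                cp.regimen().end_of_treatment_h) + 1e-6
    nt = pk.n_transit
    oral = regimen.route == "oral"
    n_disp = pk.n_compartments
    # states: [depot?] central [periph?] T1..Tnt Af_free Af_bound
    n_states = (1 if oral else 0) + n_disp + nt + 2
    ic = 1 if oral else 0
    i_t0 = ic + n_disp
    i_free = i_t0 + nt
    i_bound = i_free + 1
    k10 = pk.CL / pk.V1

    def rhs(t, x):
        dx = np.zeros_like(x)
        afc = charcoal_amount_at(cp, np.array([t]))[0]
        inp = 0.0
        for td in regimen.dose_times():
            if regimen.route == "iv_infusion" and td <= t < td + regimen.infusion_h:
                inp += regimen.infusion_rate_mg_h
        if oral:
            dx[0] = -pk.ka * x[0]
            dx[ic] += pk.ka * x[0]
        else:
            dx[ic] += inp
        dx[ic] += -k10 * x[ic]
        if n_disp == 2:
            k12, k21 = pk.Q / pk.V1, pk.Q / pk.V2
            dx[ic] += -k12 * x[ic] + k21 * x[ic + 1]
            dx[ic + 1] = k12 * x[ic] - k21 * x[ic + 1]
        prev = ic
        for j in range(nt):
            i = i_t0 + j
            inflow = pk.f_gut * k10 * x[ic] if j == 0 else pk.k_t * x[prev]
            dx[i] = inflow - pk.k_t * x[i]
            prev = i
        # binding in the last transit and fecal compartments
        bind_last = cp.k_ads * afc * x[prev]
        bind_fec = cp.k_ads * afc * x[i_free]
        dx[prev] -= bind_last
        dx[i_free] = pk.k_t * x[prev] - pk.k_f * x[i_free] - bind_fec
        dx[i_bound] = bind_last + bind_fec - pk.k_f * x[i_bound]
        return dx

    # event-restart integration between dosing discontinuities
    breaks = {0.0, t_end}
    for td in regimen.dose_times():
        breaks.add(float(td))
        if regimen.route == "iv_infusion":
            breaks.add(float(td + regimen.infusion_h))
    for td in cp.dose_times():
        breaks.add(float(td))
    breaks = np.array(sorted(b for b in breaks if b <= t_end))
    grid = np.unique(np.concatenate([make_grid(regimen, t_end, extra_times=times,
                                               dt_dense=0.5), breaks]))
    x = np.zeros(n_states)
    sols = [x.copy()[None, :]]
    sol_t = [np.array([grid[0]])]
    for a, b in zip(breaks[:-1], breaks[1:]):
        seg = grid[(grid > a + 1e-12) & (grid <= b + 1e-12)]
        if oral:
            for td in regimen.dose_times():
                if abs(td - a) < 1e-9:
                    x[0] += regimen.dose_mg
        res = solve_ivp(rhs, (a, b), x, t_eval=seg, method="LSODA",
                        rtol=rtol, atol=atol)
        if not res.success:
            raise RuntimeError(f"adsorption ODE failed on [{a}, {b}]: {res.message}")
        x = res.y[:, -1].copy()
        if len(seg):
            sols.append(res.y.T)
            sol_t.append(res.t)
    full_t = np.concatenate(sol_t)
    full_x = np.vstack(sols)
    keep = np.unique(np.round(full_t, 9), return_index=True)[1]
    full_t, full_x = full_t[keep], full_x[keep]
    scale = 24000.0 * pk.k_f / pk.F_w
    free = np.interp(times, full_t, scale * full_x[:, i_free])
    total = np.interp(times, full_t,
                      scale * (full_x[:, i_free] + full_x[:, i_bound]))
    return (Trajectory(times, np.maximum(total, 0.0), "fecal_total", "h"),
            Trajectory(times, np.maximum(free, 0.0), "fecal_free", "h"))
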