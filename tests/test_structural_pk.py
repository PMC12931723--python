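"""Plasma/fecal kinetics: closed forms, ODE agreement, mass balance."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gutpkpd.dosing import Regimen
from gutpkpd.pkmodels import (PKParameters, TransitPKEvaluator, make_grid,
                              plasma_closed_form, plasma_concentration,
                              fecal_concentration)

PK = dict(CL=7.0, V1=11.0, Q=4.0, V2=7.0, f_gut=5e-4, k_t=0.2, k_f=0.045)


def two_cpt_infusion_ode(CL, V1, Q, V2, rate, tau, times):
    """Independent oracle: direct stiff integration of the 2-cpt system."""
    k10, k12, k21 = CL / V1, Q / V1, Q / V2

    def rhs(t, x):
        inp = rate if t < tau else 0.0
        return [inp - (k10 + k12) * x[0] + k21 * x[1],
                k12 * x[0] - k21 * x[1]]

    sol = solve_ivp(rhs, (0.0, float(np.max(times))), [0.0, 0.0],
                    t_eval=np.sort(times), method="LSODA",
                    rtol=1e-10, atol=1e-12, max_step=tau / 4)
    return sol.y[0] / V1


class TestPlasmaClosedForm:
    def test_zero_before_first_dose(self):
        reg = Regimen("X", 500.0, interval_h=24.0, n_days=2, infusion_h=1.0,
                      start_h=5.0)
        c = plasma_closed_form(5.0, 10.0, 2.0, 8.0, reg, np.array([0.0, 4.9]))
        assert np.all(c == 0.0)

    def test_matches_ode_single_infusion(self, single_infusion):
        t = np.linspace(0.05, 20.0, 20)
        cf = plasma_closed_form(PK["CL"], PK["V1"], PK["Q"], PK["V2"],
                                single_infusion, t)
        oracle = two_cpt_infusion_ode(PK["CL"], PK["V1"], PK["Q"], PK["V2"],
                                      single_infusion.infusion_rate_mg_h,
                                      single_infusion.infusion_h, t)
        assert np.allclose(cf, oracle, rtol=1e-8)

    def test_q_to_zero_limit_is_one_compartment(self, single_infusion):
        t = np.linspace(0.1, 30.0, 25)
        c2 = plasma_closed_form(PK["CL"], PK["V1"], 1e-10, 5.0,
                                single_infusion, t, 2)
        c1 = plasma_closed_form(PK["CL"], PK["V1"], 0.0, 1.0,
                                single_infusion, t, 1)
        assert np.allclose(c2, c1, rtol=1e-6)

    def test_multidose_is_superposition_of_shifts(self):
        reg3 = Regimen("X", 800.0, interval_h=12.0, n_days=1, infusion_h=0.5)
        reg1 = Regimen("X", 800.0, interval_h=24.0, n_days=1, infusion_h=0.5)
        t = np.linspace(0.0, 40.0, 60)
        multi = plasma_closed_form(**{k: PK[k] for k in ("CL", "V1", "Q", "V2")},
                                   regimen=reg3, times=t)
        single = sum(
            plasma_closed_form(PK["CL"], PK["V1"], PK["Q"], PK["V2"], reg1,
                               np.maximum(t - off, -1.0))
            * (t >= off)
            for off in (0.0, 12.0))
        assert np.allclose(multi, single, rtol=1e-9, atol=1e-12)

    def test_trajectory_wrapper_validates(self, single_infusion):
        pk = PKParameters(**PK)
        with pytest.raises(ValueError):
            plasma_concentration(pk, single_infusion, [-1.0, 2.0])


class TestTransitSystem:
    def make_eval(self, reg, t_end, **kw):
        grid = make_grid(reg, t_end, dt_dense=0.25)
        return TransitPKEvaluator(reg, grid, **kw), grid

    def test_numeric_matches_plasma_closed_form(self, cro_regimen):
        ev, grid = self.make_eval(cro_regimen, 168.0)
        theta = np.array([[PK[k] for k in
                           ("CL", "V1", "Q", "V2", "f_gut", "k_t", "k_f")]])
        conc = ev.plasma_conc(ev.states(theta), theta)[0]
        ref = plasma_closed_form(PK["CL"], PK["V1"], PK["Q"], PK["V2"],
                                 cro_regimen, grid)
        assert np.allclose(conc, ref, rtol=1e-6, atol=1e-12)

    def test_mass_balance_and_fecal_fraction(self, single_infusion):
        # everything administered ends up somewhere; the fraction excreted
        # in feces converges to f_gut
        reg = single_infusion
        grid = make_grid(reg, 24.0 * 90, dt_sparse=24.0)
        ev = TransitPKEvaluator(reg, grid, track_elimination=True)
        theta = np.array([[PK[k] for k in
                           ("CL", "V1", "Q", "V2", "f_gut", "k_t", "k_f")]])
        st = ev.states(theta)[0]
        dosed = reg.dose_mg
        assert abs(st[-1].sum() - dosed) / dosed < 1e-6
        fecal_fraction = st[-1, -1] / dosed
        assert fecal_fraction == pytest.approx(PK["f_gut"], rel=1e-6)

    def test_states_stay_nonnegative(self, cro_regimen):
        ev, _ = self.make_eval(cro_regimen, 300.0)
        theta = np.array([[PK[k] for k in
                           ("CL", "V1", "Q", "V2", "f_gut", "k_t", "k_f")]])
        assert ev.states(theta).min() >= -1e-12

    def test_fgut_zero_means_no_fecal_drug(self, cro_regimen):
        pk = PKParameters(**{**PK, "f_gut": 0.0})
        tr = fecal_concentration(pk, cro_regimen, np.arange(0.0, 200.0, 4.0))
        assert np.all(tr.values == 0.0)

    def test_doubling_fecal_weight_halves_concentration(self, cro_regimen):
        t = np.arange(0.0, 200.0, 4.0)
        c1 = fecal_concentration(PKParameters(**PK), cro_regimen, t).values
        c2 = fecal_concentration(PKParameters(**PK, F_w=400.0),
                                 cro_regimen, t).values
        assert np.allclose(c2, c1 / 2.0, rtol=1e-10)

    def test_oral_route_conserves_mass(self):
        reg = Regimen("MXF", 400.0, route="oral", interval_h=24.0, n_days=2)
        grid = make_grid(reg, 24.0 * 60, dt_sparse=24.0)
        ev = TransitPKEvaluator(reg, grid, n_compartments=1,
                                track_elimination=True)
        theta = np.array([[12.0, 140.0, 0.0, 1.0, 0.025, 0.15, 0.026, 1.4]])
        st = ev.states(theta)[0]
        assert abs(st[-1].sum() - 2 * 400.0) / 800.0 < 1e-6


class TestParameterValidation:
    @pytest.mark.parametrize("bad", [
        dict(CL=-1.0), dict(f_gut=1.5), dict(k_t=0.0), dict(n_transit=5),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            PKParameters(**{**PK, **bad})

    def test_regimen_validation(self):
        with pytest.raises(ValueError):
            Regimen("X", -5.0)
        with pytest.raises(ValueError):
            Regimen("X", 5.0, interval_h=0.0)
        with pytest.raises(ValueError):
            Regimen("X", 5.0, route="sublingual")

    def test_dose_times_q8h(self):
        reg = Regimen("X", 100.0, interval_h=8.0, n_days=5, infusion_h=0.5)
        times = reg.dose_times()
        assert len(times) == 15
        assert times[0] == 0.0 and times[-1] == 112.0
        assert reg.end_of_treatment_h == 120.0
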