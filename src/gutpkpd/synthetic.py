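"""Synthetic phase-1 trials with known ground truth.

Emulates the design of a healthy-volunteer trial in which subjects receive
a 5-day IV antibiotic course (or no treatment), with rich plasma sampling
on days 1 and 5, daily stool collections through day 9 (plus days 12/16 for
ceftriaxone) and 16S diversity assessments up to day 37.  Data are drawn
from the same statistical model the estimation engine assumes: exponential
random effects, combined/constant residual errors, and left-censoring at
the assay LLOQs.  The generator is the test bed for the whole estimation
pipeline: ground truth is stored alongside every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import presets
from .data import Dataset, DoseEvent, ResponseSeries, SubjectRecord
from .diversity import OTUProfile
from .models import PKTransitBoundModel
from .pkmodels import TransitPKEvaluator, make_grid
from .saem import PopulationModel, SAEMFitter
from .sequential import fit_sequential_pkpd, pd_forcing_grid
from .turnover import ShannonTurnoverEvaluator

__all__ = [
    "ArmDesign", "TrialDesign", "GroundTruth", "default_design",
    "generate_trial", "geometric_abundances", "generate_otu_counts",
    "generate_otu_tables", "recovery_experiment",
]


@dataclass(frozen=True)
class ArmDesign:
    name: str
    drug: str | None          # None = untreated control
    n_subjects: int
    dav132_dose_g: float | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("arm size must be >= 1")


@dataclass(frozen=True)
class TrialDesign:
    arms: tuple
    n_antibiotic_days: int = 5
    diversity_days: tuple = tuple(presets.DIVERSITY_SAMPLING_DAYS)

    def __post_init__(self):
        if not self.arms:
            raise ValueError("design needs at least one arm")


def default_design(drugs=("CRO", "TZP", "CZA"), n_per_arm: int = 36,
                   n_control: int = 12) -> TrialDesign:
    """The analyzed no-DAV132 subset: one control arm plus one arm per drug."""
    arms = [ArmDesign("control", None, n_control)]
    arms += [ArmDesign(d, d, n_per_arm) for d in drugs]
    return TrialDesign(tuple(arms))


@dataclass
class GroundTruth:
    """Everything needed to regenerate a dataset bit-exactly."""

    pk_models: dict
    pd_models: dict
    pk_theta: dict            # (arm, compound) -> (n, p) individual parameters
    pd_theta: dict            # arm -> (n, 4) individual PD parameters
    seed: int
    design: TrialDesign


def _draw_theta(pop: PopulationModel, names, n, rng) -> np.ndarray:
    mu = pop.mu_array(names)
    om = pop.omega_array(names)
    return mu * np.exp(rng.standard_normal((n, len(names))) * om)


def generate_trial(design: TrialDesign, seed: int, *,
                   pk_truth: dict | None = None,
                   pd_truth: dict | None = None,
                   include_companions: bool = False):
    """Simulate one trial; returns ``(Dataset, GroundTruth)``.

    ``pk_truth``/``pd_truth`` map compound/drug to a
    :class:`PopulationModel`; the built-in presets are used by default.
    Values below the LLOQ are flagged CENS=1 with DV set to the LLOQ.
    """
    rng = np.random.default_rng(seed)
    n_days = design.n_antibiotic_days
    div_days = np.asarray(design.diversity_days, dtype=float)
    truth = GroundTruth({}, {}, {}, {}, seed, design)
    subjects = []

    for arm in design.arms:
        sids = [f"{arm.name}-{i + 1:03d}" for i in range(arm.n_subjects)]
        if arm.drug is None:
            pdm = (pd_truth or {}).get("control") or \
                PopulationModel({"SI0": presets.SI0_DEFAULT},
                                {"SI0": presets._PD_OMEGA["SI0"]},
                                {"shannon": presets.SHANNON_ERROR})
            si0 = _draw_theta(pdm, ("SI0",), arm.n_subjects, rng)[:, 0]
            err = pdm.errors["shannon"]
            truth.pd_theta[arm.name] = si0[:, None]
            truth.pd_models[arm.name] = pdm
            for i, sid in enumerate(sids):
                vals = si0[i] + err.sd(np.full(div_days.shape, si0[i])) * \
                    rng.standard_normal(len(div_days))
                obs = {"shannon": ResponseSeries(
                    24.0 * div_days, np.maximum(vals, 0.0),
                    np.zeros(len(div_days), bool),
                    np.full(len(div_days), np.nan))}
                subjects.append(SubjectRecord(sid, arm.name, obs, []))
            continue

        drug = arm.drug
        compounds = presets.COMPOUNDS[drug] if include_companions \
            else (presets.ACTIVE_MOIETY[drug],)
        plasma_t = presets.plasma_sampling_times(drug)
        fecal_t = presets.fecal_sampling_times(drug)
        arm_obs = {sid: {} for sid in sids}
        arm_doses = {sid: [] for sid in sids}
        cf_active = None
        active = presets.ACTIVE_MOIETY[drug]

        for compound in compounds:
            pkm = (pk_truth or {}).get(compound) or \
                presets.pk_population_model(compound)
            truth.pk_models[compound] = pkm
            names = tuple(pkm.mu)
            theta = _draw_theta(pkm, names, arm.n_subjects, rng)
            truth.pk_theta[(arm.name, compound)] = theta
            regimen = presets.default_regimen(compound, n_days)
            n_cpt = 1 if compound == "MXF" else 2
            t_end = float(max(plasma_t.max(), fecal_t.max())) + 1e-6
            grid = make_grid(regimen, t_end,
                             extra_times=np.concatenate([plasma_t, fecal_t]))
            ev = TransitPKEvaluator(regimen, grid, n_transit=3,
                                    n_compartments=n_cpt)
            # align theta columns with the evaluator's expectations
            cols = {n: theta[:, j] for j, n in enumerate(names)}
            full = np.column_stack([
                cols.get("CL"), cols.get("V1"),
                cols.get("Q", np.zeros(arm.n_subjects)),
                cols.get("V2", np.ones(arm.n_subjects)),
                cols.get("f_gut"), cols.get("k_t"), cols.get("k_f")])
            if regimen.route == "oral":
                full = np.column_stack([full, cols["ka"]])
            states = ev.states(full)
            cp = ev.plasma_conc(states, full)
            cfec = ev.fecal_conc(states, full)
            lloq_p = presets.plasma_lloq(compound)
            ip = np.searchsorted(grid, plasma_t - 1e-9)
            jf = np.searchsorted(grid, fecal_t - 1e-9)
            for i, sid in enumerate(sids):
                perr = pkm.errors["plasma"]
                f = cp[i, ip]
                yp = f + perr.sd(f) * rng.standard_normal(len(f))
                censp = yp < lloq_p
                yp = np.where(censp, lloq_p, np.maximum(yp, 0.0))
                ferr = pkm.errors["fecal"]
                g = cfec[i, jf]
                yf = g + ferr.sd(g) * rng.standard_normal(len(g))
                censf = yf < presets.FECAL_LLOQ
                yf = np.where(censf, presets.FECAL_LLOQ, np.maximum(yf, 0.0))
                tag = "" if len(compounds) == 1 else f":{compound}"
                arm_obs[sid][f"plasma{tag}"] = ResponseSeries(
                    plasma_t, yp, censp, np.full(len(yp), lloq_p))
                arm_obs[sid][f"fecal{tag}"] = ResponseSeries(
                    fecal_t, yf, censf, np.full(len(yf), presets.FECAL_LLOQ))
                if compound == compounds[0]:
                    rate = (regimen.infusion_rate_mg_h
                            if regimen.route == "iv_infusion" else 0.0)
                    arm_doses[sid] = [
                        DoseEvent(float(td), regimen.dose_mg, rate, 1)
                        for td in regimen.dose_times()]
            if compound == active:
                grid_pd = pd_forcing_grid(regimen,
                                          24.0 * float(div_days.max()) + 1e-6,
                                          24.0 * div_days)
                ev_pd = TransitPKEvaluator(regimen, grid_pd, n_transit=3,
                                           n_compartments=n_cpt)
                st = ev_pd.states(full)
                cf_active = (grid_pd, ev_pd.fecal_conc(st, full))

        pdm = (pd_truth or {}).get(drug) or presets.pd_population_model(drug)
        truth.pd_models[arm.name] = pdm
        pd_names = ("SI0", "kout", "Emax", "EC50")
        theta_pd = _draw_theta(pdm, pd_names, arm.n_subjects, rng)
        truth.pd_theta[arm.name] = theta_pd
        grid_pd, cf = cf_active
        turnover = ShannonTurnoverEvaluator(grid_pd / 24.0, cf)
        si = turnover.trajectories(theta_pd)
        jdx = np.searchsorted(np.round(grid_pd / 24.0, 9), div_days - 1e-9)
        serr = pdm.errors["shannon"]
        for i, sid in enumerate(sids):
            v = si[i, jdx]
            y = v + serr.sd(v) * rng.standard_normal(len(v))
            arm_obs[sid]["shannon"] = ResponseSeries(
                24.0 * div_days, np.maximum(y, 0.0),
                np.zeros(len(v), bool), np.full(len(v), np.nan))
        for sid in sids:
            subjects.append(SubjectRecord(sid, arm.name, arm_obs[sid],
                                          arm_doses[sid]))

    return Dataset(subjects), truth


# ---------------------------------------------------------------------------
# OTU tables whose realized Shannon index tracks a target trajectory
# ---------------------------------------------------------------------------

def _geometric_shannon(r: float, n: int) -> float:
    w = r ** np.arange(n)
    p = w / w.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def geometric_abundances(target_si: float, n_otus: int) -> np.ndarray:
    """Abundance vector p_i ~ r^i whose Shannon index equals ``target_si``.

    The one-parameter geometric family sweeps the entire feasible range
    (0, log2 n); the ratio r is found by bisection.
    """
    hmax = np.log2(n_otus)
    if not 0.0 < target_si <= hmax:
        raise ValueError(f"target Shannon {target_si} outside (0, {hmax:.3f}]")
    if target_si >= hmax - 1e-9:
        return np.full(n_otus, 1.0 / n_otus)
    r = brentq(lambda x: _geometric_shannon(x, n_otus) - target_si,
               1e-12, 1.0 - 1e-12, xtol=1e-12)
    w = r ** np.arange(n_otus)
    return w / w.sum()


def generate_otu_counts(target_si: float, n_otus: int, n_reads: int,
                        rng) -> np.ndarray:
    """Multinomial OTU counts with expected Shannon near ``target_si``."""
    return rng.multinomial(n_reads, geometric_abundances(target_si, n_otus))


def generate_otu_tables(si_by_sample: pd.DataFrame, *, n_otus: int = 100,
                        n_reads: int = 50_000, seed: int = 0):
    """OTU profiles for a (sample_id, shannon) table of target indices."""
    rng = np.random.default_rng(seed)
    ids = tuple(f"OTU{i + 1:04d}" for i in range(n_otus))
    return [OTUProfile(ids,
                       generate_otu_counts(row.shannon, n_otus, n_reads, rng),
                       row.sample_id)
            for row in si_by_sample.itertuples()]


# ---------------------------------------------------------------------------
# parameter-recovery experiments (the estimation pipeline's main test bed)
# ---------------------------------------------------------------------------

def _perturbed(pop: PopulationModel, rng, spread: float = 0.3,
               omega_init: float = 0.3) -> PopulationModel:
    mu = {k: v * float(np.exp(rng.uniform(-spread, spread)))
          for k, v in pop.mu.items()}
    omega = {k: (0.0 if k in pop.no_re else omega_init) for k in pop.omega}
    return PopulationModel(mu, omega, dict(pop.errors), pop.no_re)


def recovery_experiment(drug: str, n_replicates: int, seed: int, *,
                        n_per_arm: int = 36, n_control: int = 12,
                        pk_iters=(120, 80), pd_iters=(150, 100),
                        init_spread: float = 0.3) -> dict:
    """Replicate generate -> PK fit -> sequential PD fit, reporting recovery.

    Each replicate simulates a fresh trial (one antibiotic arm plus
    controls) from the preset truth, fits the PK model by SAEM on the
    treated subjects, carries the empirical-Bayes fecal predictions into
    the diversity fit, and records the estimated PD fixed effects.
    """
    active = presets.ACTIVE_MOIETY[drug]
    pd_true = presets.pd_population_model(drug)
    pk_true = presets.pk_population_model(active)
    estimates = {k: [] for k in ("SI0", "kout", "Emax", "EC50")}
    pk_estimates = {k: [] for k in pk_true.mu}
    n_failed = 0
    flags = []
    for rep in range(n_replicates):
        rep_rng = np.random.default_rng([seed, rep])
        gen_seed, pk_seed, pd_seed = rep_rng.integers(2 ** 31, size=3)
        design = default_design((drug,), n_per_arm, n_control)
        data, truth = generate_trial(design, int(gen_seed))
        pk_data = data.subset(arms=[drug], responses=["plasma", "fecal"])
        regimen = presets.default_regimen(active,
                                          design.n_antibiotic_days)
        n_cpt = 1 if active == "MXF" else 2

        def pk_builder(ds):
            return PKTransitBoundModel(ds, regimen, n_transit=3,
                                       n_compartments=n_cpt)

        pk_init = _perturbed(pk_true, rep_rng, init_spread)
        pk_fit = SAEMFitter(pk_builder, pk_init, n_burn=pk_iters[0],
                            n_smooth=pk_iters[1], compute_fim=False,
                            seed=int(pk_seed)).fit(pk_data).result_
        pd_init = _perturbed(pd_true, rep_rng, init_spread)
        pd_fit = fit_sequential_pkpd(pk_fit, data, pd_init,
                                     n_burn=pd_iters[0], n_smooth=pd_iters[1],
                                     seed=int(pd_seed), compute_fim=False)
        if not pd_fit.converged:
            n_failed += 1
        flags.append(pd_fit.flags)
        for k in estimates:
            estimates[k].append(pd_fit.mu[k])
        for k in pk_estimates:
            pk_estimates[k].append(pk_fit.mu[k])
    report = {
        "drug": drug,
        "n_replicates": n_replicates,
        "truth": dict(pd_true.mu),
        "estimates": {k: np.asarray(v) for k, v in estimates.items()},
        "pk_estimates": {k: np.asarray(v) for k, v in pk_estimates.items()},
        "median": {k: float(np.median(v)) for k, v in estimates.items()},
        "relative_bias": {
            k: float(np.median(v) / pd_true.mu[k] - 1.0)
            for k, v in estimates.items()},
        "n_nonconverged": n_failed,
        "flags": flags,
        "seed": seed,
    }
    return report
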