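"""Monte-Carlo simulation of antibiotic courses and PD impact indices.

For each virtual subject, population parameters are drawn from the
asymptotic (multivariate-normal, estimation-scale) distribution of the
estimates, individual parameters add exponential random effects, and the
deterministic fecal-concentration and Shannon-index trajectories are
summarized into impact indices:

==================  =========================================================
cmax_fecal          maximal fecal concentration (ug/g)
t_below_lloq        days after the end of treatment until the fecal
                    concentration falls below the assay LLOQ for good
nadir_loss          maximal loss of diversity, % of baseline
t_nadir             time of the nadir, days after treatment start
t_return95          days after the end of treatment until SI recovers to
                    95% of baseline (0 if it never drops below)
auc_change_0_42     integral of SI(t) - SI0 over days 0-42 (Shannon unit.day)
==================  =========================================================

Residual (assay) error is excluded from index computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import presets
from .dosing import Regimen
from .pkmodels import TransitPKEvaluator, make_grid
from .saem import FitResult, PopulationModel, nearest_positive_definite
from .trajectory import Trajectory
from .turnover import ShannonTurnoverEvaluator

__all__ = ["PDIndices", "compute_pd_indices", "sample_population",
           "simulate_drug_course", "run_scenarios", "INDEX_NAMES"]

INDEX_NAMES = ("cmax_fecal", "t_below_lloq", "nadir_loss", "t_nadir",
               "t_return95", "auc_change_0_42")


@dataclass(frozen=True)
class PDIndices:
    cmax_fecal: float
    t_below_lloq: float
    nadir_loss: float
    t_nadir: float
    t_return95: float
    auc_change_0_42: float

    def as_dict(self) -> dict:
        return asdict(self)


def _crossing_time(t, v, threshold, rising):
    """First linear-interpolated crossing of ``threshold`` in direction."""
    if rising:
        hit = np.nonzero(v >= threshold)[0]
    else:
        hit = np.nonzero(v <= threshold)[0]
    if len(hit) == 0:
        return np.nan
    j = hit[0]
    if j == 0:
        return t[0]
    t0, t1, v0, v1 = t[j - 1], t[j], v[j - 1], v[j]
    if v1 == v0:
        return t1
    return t0 + (threshold - v0) * (t1 - t0) / (v1 - v0)


def compute_pd_indices(si_traj: Trajectory, cf_traj: Trajectory,
                       regimen: Regimen, lloq: float = presets.FECAL_LLOQ,
                       horizon: float = 42.0) -> PDIndices:
    """Impact indices from one subject's SI and fecal-concentration curves.

    Both trajectories must cover [0, ``horizon``] days.  ``t_nadir`` is
    counted from treatment start; ``t_below_lloq`` and ``t_return95`` from
    the end of treatment (``n_days`` days).  Times are located by linear
    interpolation between grid points.
    """
    si = si_traj.to_days()
    cf = cf_traj.to_days()
    for tr, nm in ((si, "SI"), (cf, "fecal")):
        if tr.times.max() < horizon - 1e-9 or tr.times.min() > 1e-9:
            raise ValueError(f"{nm} trajectory does not cover [0, {horizon}] d")
    t_end = float(regimen.n_days)

    tmask = (si.times >= 0) & (si.times <= horizon + 1e-12)
    ts, vs = si.times[tmask], si.values[tmask]
    si0 = float(np.interp(0.0, si.times, si.values))
    j = int(np.argmin(vs))
    nadir_loss = float(np.clip(100.0 * (si0 - vs[j]) / si0, 0.0, 100.0))
    t_nadir = float(ts[j])

    thr = 0.95 * si0
    if vs.min() >= thr:
        t_return95 = 0.0
    else:
        tc = _crossing_time(ts[j:], vs[j:], thr, rising=True)
        t_return95 = float(max(tc - t_end, 0.0)) if np.isfinite(tc) else np.nan

    auc = float(np.trapezoid(vs - si0, ts))

    cmask = (cf.times >= 0) & (cf.times <= horizon + 1e-12)
    tc_, vc = cf.times[cmask], cf.values[cmask]
    cmax = float(vc.max())
    if cmax < lloq:
        t_below = 0.0
    else:
        above = np.nonzero(vc >= lloq)[0]
        k = above[-1]
        if k == len(vc) - 1:
            t_below = np.nan  # still quantifiable at the horizon
        else:
            tcross = _crossing_time(tc_[k:], vc[k:], lloq, rising=False)
            t_below = float(max(tcross - t_end, 0.0))
    return PDIndices(cmax, t_below, nadir_loss, t_nadir, t_return95, auc)


# ---------------------------------------------------------------------------
# sampling from the asymptotic distribution of the estimates
# ---------------------------------------------------------------------------

def _eta_cov(fit_like, names, re_names, rse_default):
    """Covariance of (log mu, log omega) on the estimation scale."""
    labels = [f"mu_{n}" for n in names] + [f"omega_{n}" for n in re_names]
    if isinstance(fit_like, FitResult) and fit_like.cov is not None:
        pos = {nm: i for i, nm in enumerate(fit_like.eta_names)}
        idx = [pos.get(nm) for nm in labels]
        cov = np.zeros((len(labels), len(labels)))
        for a, ia in enumerate(idx):
            for b, ib in enumerate(idx):
                if ia is not None and ib is not None:
                    cov[a, b] = fit_like.cov[ia, ib]
        return nearest_positive_definite(cov) if np.any(cov) else cov
    rse = getattr(fit_like, "rse", None) or {}
    sd = np.array([rse.get(nm, rse_default * 100.0) / 100.0 for nm in labels])
    return np.diag(sd ** 2)


def sample_population(fit_like, n: int, seed: int, *,
                      rse_default: float = 0.0) -> tuple:
    """Draw individual parameters for ``n`` virtual subjects.

    Population parameters (fixed effects and omegas, on the log scale) are
    drawn per subject from the asymptotic normal distribution of the
    estimates -- the stored covariance when available, otherwise a diagonal
    built from relative standard errors (``rse_default`` as fallback, as a
    fraction).  Individual log-parameters then add N(0, omega) random
    effects.  Returns ``(theta (n, p), names)``.
    """
    pm = fit_like.population_model() \
        if hasattr(fit_like, "population_model") else fit_like
    names = tuple(getattr(fit_like, "param_names", None) or pm.mu)
    rng = np.random.default_rng(seed)
    logmu = np.log(pm.mu_array(names))
    omega = pm.omega_array(names)
    re_names = [nm for nm, om in zip(names, omega) if om > 0]
    cov = _eta_cov(fit_like, names, re_names, rse_default)
    try:
        L = np.linalg.cholesky(cov) if np.any(cov) else None
    except np.linalg.LinAlgError:
        if np.linalg.eigvalsh(0.5 * (cov + cov.T)).min() < -1e-10:
            warnings.warn("asymptotic covariance not positive definite; "
                          "repaired")
        L = np.linalg.cholesky(nearest_positive_definite(cov))
    eta0 = np.concatenate([logmu, np.log(omega[omega > 0])]) \
        if re_names else logmu
    p = len(names)
    theta = np.empty((n, p))
    for i in range(n):
        eta = eta0 if L is None else eta0 + L @ rng.standard_normal(len(eta0))
        mu_i = np.exp(eta[:p])
        om_i = omega.copy()
        om_i[omega > 0] = np.exp(eta[p:])
        b = rng.standard_normal(p) * om_i
        theta[i] = mu_i * np.exp(b)
    return theta, names


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

#: published relative standard errors (%) of the PD susceptibility
#: estimates, used when simulating from the preset models
PD_RSE = {"TZP": {"mu_Emax": 1.0, "mu_EC50": 122.8},
          "CZA": {"mu_Emax": 22.4, "mu_EC50": 23.7},
          "CRO": {"mu_Emax": 39.1, "mu_EC50": 18.9},
          "MXF": {"mu_Emax": 20.0, "mu_EC50": 30.0}}


class _PresetFitLike:
    """Population model plus r.s.e. table, quacking like a fit for sampling."""

    def __init__(self, pop: PopulationModel, rse: dict):
        self._pm = pop
        self.rse = rse
        self.param_names = tuple(pop.mu)
        self.cov = None

    def population_model(self) -> PopulationModel:
        return self._pm


def preset_models(drug: str, *, pk_rse: float = 15.0, pd_rse_si0: float = 5.0):
    """(pk, pd) fit-like objects for a drug, built from the preset values."""
    active = presets.ACTIVE_MOIETY[drug]
    pk = presets.pk_population_model(active)
    pkf = _PresetFitLike(pk, {f"mu_{n}": pk_rse for n in pk.mu})
    pd = presets.pd_population_model(drug)
    rse = {"mu_SI0": pd_rse_si0, "mu_kout": 20.0}
    rse.update(PD_RSE[drug])
    pdf = _PresetFitLike(pd, rse)
    return pkf, pdf


def simulate_drug_course(drug: str, duration_days: int, n: int, seed: int, *,
                         pk_fit=None, pd_fit=None,
                         horizon: float = 42.0) -> pd.DataFrame:
    """Simulate ``n`` subjects on a standard course; per-subject indices.

    Returns a data frame with one row per subject (the sampled PD
    parameters and all impact indices).  No adsorbent co-administration.
    """
    if pk_fit is None or pd_fit is None:
        dflt = preset_models(drug)
        pk_fit = pk_fit or dflt[0]
        pd_fit = pd_fit or dflt[1]
    active = presets.ACTIVE_MOIETY[drug]
    regimen = presets.default_regimen(active, duration_days)
    theta_pk, pk_names = sample_population(pk_fit, n, seed)
    theta_pd, pd_names = sample_population(pd_fit, n, seed + 1)

    t_end_h = horizon * 24.0
    grid = make_grid(regimen, t_end_h, dt_dense=0.25, dt_sparse=2.4)
    n_cpt = 1 if active == "MXF" else 2
    ev = TransitPKEvaluator(regimen, grid, n_transit=3, n_compartments=n_cpt)
    cols = dict(zip(pk_names, theta_pk.T))
    full = np.column_stack([
        cols["CL"], cols["V1"], cols.get("Q", np.zeros(n)),
        cols.get("V2", np.ones(n)), cols["f_gut"], cols["k_t"], cols["k_f"]])
    if regimen.route == "oral":
        full = np.column_stack([full, cols["ka"]])
    states = ev.states(full)
    cf = ev.fecal_conc(states, full)
    grid_days = grid / 24.0
    si = ShannonTurnoverEvaluator(grid_days, cf).trajectories(
        theta_pd[:, [pd_names.index(k) for k in
                     ("SI0", "kout", "Emax", "EC50")]])
    rows = []
    for i in range(n):
        idx = compute_pd_indices(
            Trajectory(grid_days, si[i], "shannon", "day"),
            Trajectory(grid_days, np.maximum(cf[i], 0.0), "fecal_free", "day"),
            regimen, horizon=horizon)
        rows.append({**{k: theta_pd[i, j] for j, k in enumerate(pd_names)},
                     **idx.as_dict()})
    df = pd.DataFrame(rows)
    df.insert(0, "subject", np.arange(1, n + 1))
    df.insert(0, "duration_days", duration_days)
    df.insert(0, "drug", drug)
    return df


def summarize_indices(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Median / IQR / 10-90 percentiles of each index, NaN-aware.

    ``t_return95_cond`` is the median among subjects whose diversity
    actually dropped below 95% of baseline (the threshold index is 0 by
    convention otherwise, which degenerates at weak effects).
    """
    out = []
    for name in INDEX_NAMES:
        v = per_subject[name].to_numpy(float)
        ok = np.isfinite(v)
        q = np.percentile(v[ok], [50, 25, 75, 10, 90]) if ok.any() \
            else [np.nan] * 5
        out.append({"index": name, "median": q[0], "q25": q[1], "q75": q[2],
                    "q10": q[3], "q90": q[4], "n_missing": int((~ok).sum())})
    dropped = per_subject["nadir_loss"] > 5.0
    v = per_subject.loc[dropped, "t_return95"].to_numpy(float)
    v = v[np.isfinite(v)]
    out.append({"index": "t_return95_cond",
                "median": float(np.median(v)) if len(v) else np.nan,
                "q25": np.nan, "q75": np.nan, "q10": np.nan, "q90": np.nan,
                "n_missing": int(len(per_subject) - dropped.sum())})
    return pd.DataFrame(out)


def run_scenarios(drugs=("CRO", "TZP", "CZA", "MXF"),
                  durations=(3, 5, 7, 10, 14), n: int = 1000, seed: int = 1,
                  *, fits: dict | None = None, out_dir=None) -> pd.DataFrame:
    """Median [IQR] impact indices per drug x duration.

    ``fits`` may map a drug to a ``(pk_fit, pd_fit)`` pair; preset models
    are used otherwise.  Missing parameter sets are skipped with a warning.
    Writes summary/per-subject CSVs (and boxplot-style figures) to
    ``out_dir`` when given.
    """
    frames, summaries = [], []
    for d, drug in enumerate(drugs):
        try:
            pk_fit, pd_fit = (fits or {}).get(drug) or preset_models(drug)
        except KeyError:
            warnings.warn(f"no parameter set for {drug!r}; skipped")
            continue
        for k, dur in enumerate(durations):
            per = simulate_drug_course(drug, dur, n, seed + 97 * d + k,
                                       pk_fit=pk_fit, pd_fit=pd_fit)
            frames.append(per)
            s = summarize_indices(per)
            s.insert(0, "duration_days", dur)
            s.insert(0, "drug", drug)
            summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.concat(frames, ignore_index=True).to_csv(
            out / "per_subject_indices.csv", index=False)
        summary.to_csv(out / "summary_indices.csv", index=False)
        _plot_scenarios(pd.concat(frames, ignore_index=True), out)
    return summary


def _plot_scenarios(per_subject: pd.DataFrame, out_dir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(13, 7))
    for ax, name in zip(axes.ravel(), INDEX_NAMES):
        data, labels = [], []
        for (drug, dur), g in per_subject.groupby(["drug", "duration_days"]):
            if dur == 5:
                v = g[name].to_numpy(float)
                data.append(v[np.isfinite(v)])
                labels.append(drug)
        ax.boxplot(data, tick_labels=labels, whis=(10, 90), showfliers=False)
        ax.set_title(name)
    fig.suptitle("impact indices, 5-day course")
    fig.tight_layout()
    fig.savefig(f"{out_dir}/indices_boxplot.png", dpi=120)
    plt.close(fig)
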