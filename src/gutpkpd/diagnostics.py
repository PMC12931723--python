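"""Simulation-based model diagnostics: IWRES, NPDE and VPC.

NPDE: each observation's prediction-distribution error is its rank among
``n_sim`` model simulations, mid-rank corrected to (k + 0.5)/(n_sim + 1)
and mapped through the standard-normal quantile function.  Within a
subject, observations are first decorrelated with the mean and Cholesky
factor of the simulated covariance.  An observation below the LLOQ gets a
uniform draw below the simulated censoring quantile (its subject is left
undecorrelated).  Under the correct model, NPDE are iid standard normal.

VPC: percentile bands (default 5/50/95) of the simulations in equal-count
time bins, with a confidence interval across simulated replicates, overlaid
with the observed percentiles.  Numeric bands are the contract; plots are a
rendering of the returned table.

Diagnostics never mutate the fit or the data and are deterministic given
their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import ndtri

from .data import Dataset
from .saem import PopulationModel, simulate_from_model

__all__ = ["iwres", "npde", "vpc"]


def iwres(obs, individual_prediction, sd) -> np.ndarray:
    """Individually weighted residuals (obs - pred) / sd."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(individual_prediction, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    return (obs - pred) / sd


def _simulate_matrix(model, pop, dataset, n_sim, rng):
    responses = getattr(model, "responses", dataset.responses)
    sims = {r: np.empty((n_sim, len(dataset.flat(r)[0]))) for r in responses}
    for m in range(n_sim):
        one = simulate_from_model(model, pop, dataset, rng)
        for r in responses:
            sims[r][m] = one[r]
    return sims


def npde(dataset: Dataset, model, pop: PopulationModel, n_sim: int = 500,
         seed: int = 0) -> pd.DataFrame:
    """Normalized prediction distribution errors for every observation.

    Returns a frame with columns (subject_id, response, time, npde).
    """
    if n_sim < 100:
        raise ValueError("npde needs at least 100 simulations")
    rng = np.random.default_rng(seed)
    sims = _simulate_matrix(model, pop, dataset, n_sim, rng)
    responses = list(sims)
    flats = {r: dataset.flat(r) for r in responses}
    rows = []
    for i, subj in enumerate(dataset.subjects):
        y_parts, sim_parts, meta = [], [], []
        cens_any = False
        for r in responses:
            idx, t, y, cens, lloq = flats[r]
            sel = idx == i
            if not sel.any():
                continue
            y_parts.append(y[sel])
            sim_parts.append(sims[r][:, sel])
            cens_any = cens_any or bool(cens[sel].any())
            meta.extend((subj.subject_id, r, tt, cc, qq)
                        for tt, cc, qq in zip(t[sel], cens[sel], lloq[sel]))
        if not y_parts:
            continue
        yv = np.concatenate(y_parts)
        sm = np.hstack(sim_parts)               # (n_sim, m_i)
        if np.any(sm.std(axis=0) == 0):
            raise ValueError(
                f"degenerate simulations for subject {subj.subject_id!r}")
        if not cens_any and len(yv) > 1:
            mu = sm.mean(axis=0)
            cov = np.cov(sm, rowvar=False)
            cov += 1e-10 * np.eye(len(yv)) * max(np.trace(cov), 1.0)
            L = np.linalg.cholesky(cov)
            yd = solve_triangular(L, yv - mu, lower=True)
            sd_ = solve_triangular(L, (sm - mu).T, lower=True).T
        else:
            yd = yv
            sd_ = sm
        for j, (sid, r, tt, cc, qq) in enumerate(meta):
            if cc:  # censored: uniform below the simulated censoring quantile
                k = (sd_[:, j] < qq).sum()
                pde = rng.uniform(0.0, (k + 0.5) / (n_sim + 1.0))
                pde = max(pde, 0.5 / (n_sim + 1.0) * 1e-3)
            else:
                k = (sd_[:, j] < yd[j]).sum()
                pde = (k + 0.5) / (n_sim + 1.0)
            rows.append({"subject_id": sid, "response": r, "time": tt,
                         "npde": float(ndtri(pde))})
    return pd.DataFrame(rows)


def vpc(dataset: Dataset, model, pop: PopulationModel, n_sim: int = 500,
        bins: int = 8, seed: int = 0, response: str | None = None,
        percentiles=(5.0, 50.0, 95.0), ci: float = 95.0,
        plot_path=None) -> pd.DataFrame:
    """Visual-predictive-check bands for one response.

    Returns a frame with one row per (bin, percentile): the observed
    percentile, the simulated median band and its confidence interval.
    Empty bins are dropped with a warning.
    """
    if n_sim < 100:
        raise ValueError("vpc needs at least 100 simulations")
    rng = np.random.default_rng(seed)
    responses = getattr(model, "responses", dataset.responses)
    response = response or responses[0]
    sims = _simulate_matrix(model, pop, dataset, n_sim, rng)[response]
    idx, t, y, cens, lloq = dataset.flat(response)
    # equal-count bins on observation times
    qs = np.linspace(0, 100, bins + 1)
    edges = np.unique(np.percentile(t, qs))
    which = np.clip(np.searchsorted(edges, t, side="right") - 1,
                    0, len(edges) - 2)
    rows = []
    import warnings as _w
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            _w.warn(f"empty VPC bin [{edges[b]:.3g}, {edges[b+1]:.3g}] dropped")
            continue
        t_mid = float(np.median(t[sel]))
        for p in percentiles:
            obs_p = float(np.percentile(y[sel], p))
            sim_p = np.percentile(sims[:, sel], p, axis=1)
            lo, hi = np.percentile(sim_p, [(100 - ci) / 2, 100 - (100 - ci) / 2])
            rows.append({"bin": b, "t_lo": edges[b], "t_hi": edges[b + 1],
                         "t_mid": t_mid, "percentile": p, "observed": obs_p,
                         "simulated": float(np.median(sim_p)),
                         "ci_lo": float(lo), "ci_hi": float(hi),
                         "n_obs": int(sel.sum())})
    bands = pd.DataFrame(rows)
    if plot_path is not None:
        _plot_vpc(bands, response, plot_path)
    return bands


def _plot_vpc(bands: pd.DataFrame, response: str, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for p, g in bands.groupby("percentile"):
        ax.fill_between(g.t_mid, g.ci_lo, g.ci_hi, alpha=0.25,
                        label=f"sim {p:g}% CI")
        ax.plot(g.t_mid, g.observed, "o-", ms=4, label=f"obs {p:g}%")
    ax.set_xlabel("time (h)")
    ax.set_ylabel(response)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
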