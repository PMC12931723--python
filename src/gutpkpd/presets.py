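"""Built-in regimens, parameter sets and trial design constants.

Pharmacodynamic susceptibility parameters (Emax, EC50) are the published
population estimates for piperacillin, ceftazidime and ceftriaxone.
Structural PK values and the diversity turnover rates are this package's
own calibration: plausible two-compartment disposition parameters for each
drug, with the fecal sub-model (f_gut, k_t, k_f) tuned analytically so the
simulated fecal exposures match the published summaries (median fecal Cmax
about 3.5 ug/g for ceftriaxone and 80 ug/g for moxifloxacin after 5 days;
time below the fecal LLOQ about 2.5 d for piperacillin, 5 d for
ceftriaxone, 12 d for moxifloxacin), and SI0 = 4.0 log2 units with
kout = 0.1 /day so that nadir depth and its timing (about 2 days after the
end of treatment) sit in the published range.  See docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .charcoal import CharcoalParameters
from .dosing import IV_INFUSION, ORAL, Regimen
from .errmodels import ErrorModel
from .pkmodels import PKParameters
from .saem import PopulationModel
from .turnover import PDParameters

__all__ = [
    "DRUGS", "ACTIVE_MOIETY", "default_regimen", "pk_parameters",
    "pd_parameters", "charcoal_parameters", "plasma_lloq", "FECAL_LLOQ",
    "pk_population_model", "pd_population_model",
    "PLASMA_SAMPLING_OFFSETS_H", "FECAL_SAMPLING_DAYS",
    "DIVERSITY_SAMPLING_DAYS",
]

DRUGS = ("CRO", "TZP", "CZA", "MXF")

#: compound driving the pharmacodynamics for each treatment (the
#: beta-lactamase inhibitors tazobactam and avibactam have no PD effect)
ACTIVE_MOIETY = {"CRO": "CRO", "TZP": "TZP_piperacillin",
                 "CZA": "CZA_ceftazidime", "MXF": "MXF"}

COMPOUNDS = {"CRO": ("CRO",),
             "TZP": ("TZP_piperacillin", "TZP_tazobactam"),
             "CZA": ("CZA_ceftazidime", "CZA_avibactam"),
             "MXF": ("MXF",)}

_REGIMENS = {
    # drug, dose mg, route, interval h, infusion h
    "CRO": ("CRO", 1000.0, IV_INFUSION, 24.0, 0.5),
    "TZP_piperacillin": ("TZP_piperacillin", 4000.0, IV_INFUSION, 8.0, 0.5),
    "TZP_tazobactam": ("TZP_tazobactam", 500.0, IV_INFUSION, 8.0, 0.5),
    "CZA_ceftazidime": ("CZA_ceftazidime", 2000.0, IV_INFUSION, 8.0, 2.0),
    "CZA_avibactam": ("CZA_avibactam", 500.0, IV_INFUSION, 8.0, 2.0),
    "MXF": ("MXF", 400.0, ORAL, 24.0, 0.5),
}


def default_regimen(compound: str, n_days: int = 5) -> Regimen:
    """Standard-dose course of a compound (5-day default)."""
    drug, dose, route, interval, inf = _REGIMENS[compound]
    return Regimen(drug, dose, route=route, interval_h=interval,
                   n_days=n_days, infusion_h=inf)


_PK = {
    #                 CL     V1    Q    V2   f_gut   k_t    k_f   ka
    "CRO":             (0.95, 7.0, 0.6, 5.0, 6.0e-4, 0.20, 0.037, 0.0),
    "TZP_piperacillin": (14.0, 10.0, 5.0, 8.0, 5.0e-4, 0.25, 0.110, 0.0),
    "TZP_tazobactam":   (12.0, 10.0, 4.0, 8.0, 5.0e-4, 0.25, 0.110, 0.0),
    "CZA_ceftazidime":  (7.0, 11.0, 4.0, 7.0, 5.0e-4, 0.20, 0.045, 0.0),
    "CZA_avibactam":    (11.0, 12.0, 4.5, 8.0, 5.0e-4, 0.20, 0.045, 0.0),
    "MXF":              (12.0, 140.0, 0.0, 1.0, 2.5e-2, 0.15, 0.026, 1.4),
}


def pk_parameters(compound: str, n_transit: int = 3) -> PKParameters:
    CL, V1, Q, V2, f_gut, k_t, k_f, ka = _PK[compound]
    return PKParameters(CL=CL, V1=V1, Q=Q, V2=V2, f_gut=f_gut, k_t=k_t,
                        k_f=k_f, n_transit=n_transit, ka=ka,
                        n_compartments=1 if compound == "MXF" else 2)


# published susceptibility estimates (Emax as fraction, EC50 in ug/g);
# MXF values are illustrative placeholders for the fluoroquinolone arm
_PD = {"TZP": (0.78, 6.68), "CZA": (0.580, 10.90),
       "CRO": (0.071, 0.15), "MXF": (0.83, 2.0)}

SI0_DEFAULT = 4.0     # baseline Shannon index, log2 units
KOUT_DEFAULT = 0.1    # diversity turnover rate, 1/day


def pd_parameters(drug: str) -> PDParameters:
    emax, ec50 = _PD[drug]
    return PDParameters(SI0=SI0_DEFAULT, kout=KOUT_DEFAULT,
                        Emax=emax, EC50=ec50)


# adsorption constants (1/mg/h): ceftriaxone and piperacillin are the
# published extremes; the others are plausible placeholders, avibactam ~ 0
_KADS = {"CRO": 4.4e-5, "TZP_piperacillin": 0.32, "TZP_tazobactam": 0.10,
         "CZA_ceftazidime": 0.01, "CZA_avibactam": 0.0, "MXF": 0.01}


def charcoal_parameters(compound: str, dose_g: float = 7.5) -> CharcoalParameters:
    return CharcoalParameters(kt_DAV132=0.4, kf_Charc=0.03,
                              k_ads=_KADS.get(compound, 0.0),
                              dose_mg=dose_g * 1000.0)


def plasma_lloq(compound: str) -> float:
    return {"CRO": 0.05, "TZP_piperacillin": 0.05, "TZP_tazobactam": 0.05,
            "CZA_ceftazidime": 0.04, "CZA_avibactam": 0.0098,
            "MXF": 0.01}[compound]


FECAL_LLOQ = 0.04  # ug/g, all compounds


# ---------------------------------------------------------------------------
# trial sampling schedule (hours after the start of the first infusion of
# the corresponding day; "0" is the pre-dose sample)
# ---------------------------------------------------------------------------

PLASMA_SAMPLING_OFFSETS_H = {
    "CRO": {1: [0, 0.25, 0.5, 1, 2, 4, 6, 8, 12, 18, 24],
            5: [0, 0.25, 0.5, 1, 2, 3, 4, 6, 8, 24, 36, 48]},
    "TZP": {1: [0, 0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4, 6, 8],
            5: [0, 0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4, 6, 8, 12, 18]},
    "CZA": {1: [0, 1, 1.5, 2, 2.5, 3, 4, 6, 8],
            5: [0, 1, 1.5, 2, 2.5, 3, 4, 6, 8, 12, 18]},
    "MXF": {1: [0, 0.5, 1, 2, 4, 8, 12, 24],
            5: [0, 0.5, 1, 2, 4, 8, 24, 48]},
}

#: stool collections with drug assay (days); ceftriaxone adds days 12 and 16
FECAL_SAMPLING_DAYS = {"CRO": [1, 2, 3, 4, 5, 6, 7, 8, 9, 12, 16],
                       "default": [1, 2, 3, 4, 5, 6, 7, 8, 9]}

#: 16S profiling days (0 = pre-treatment)
DIVERSITY_SAMPLING_DAYS = [0, 3, 6, 9, 12, 16, 25, 37]


def plasma_sampling_times(drug: str) -> np.ndarray:
    """Absolute plasma sampling times (h) for a 5-day course of ``drug``."""
    offs = PLASMA_SAMPLING_OFFSETS_H[drug]
    day5_start = 96.0
    t = [np.asarray(offs[1], float), day5_start + np.asarray(offs[5], float)]
    return np.unique(np.concatenate(t))


def fecal_sampling_times(drug: str) -> np.ndarray:
    days = FECAL_SAMPLING_DAYS.get(drug, FECAL_SAMPLING_DAYS["default"])
    return 24.0 * np.asarray(days, float)


# ---------------------------------------------------------------------------
# population models (truth used by the synthetic-trial generator and as
# initial values for estimation)
# ---------------------------------------------------------------------------

_PK_OMEGA = {"CL": 0.25, "V1": 0.25, "Q": 0.30, "V2": 0.30,
             "f_gut": 1.0, "k_t": 0.25, "k_f": 0.40, "ka": 0.30}

PLASMA_ERROR = ErrorModel("combined", 0.02, 0.08)
FECAL_ERROR = ErrorModel("combined", 0.02, 0.25)
SHANNON_ERROR = ErrorModel("constant", 0.15)


def pk_population_model(compound: str) -> PopulationModel:
    pk = pk_parameters(compound)
    names = ("CL", "V1", "Q", "V2", "f_gut", "k_t", "k_f")
    mu = dict(zip(names, pk.as_array()))
    if pk.n_compartments == 1:
        mu.pop("Q"); mu.pop("V2")
    if _REGIMENS[compound][2] == ORAL:
        mu["ka"] = pk.ka
    omega = {n: _PK_OMEGA[n] for n in mu}
    return PopulationModel(mu, omega,
                           {"plasma": PLASMA_ERROR, "fecal": FECAL_ERROR})


#: interindividual variability of the PD parameters; the paper reports a
#: high variability of the piperacillin EC50
_PD_OMEGA = {"SI0": 0.10, "kout": 0.25, "Emax": 0.25, "EC50": 0.50}
_PD_OMEGA_EC50 = {"TZP": 1.0, "CZA": 0.50, "CRO": 0.50, "MXF": 0.50}


def pd_population_model(drug: str) -> PopulationModel:
    pd = pd_parameters(drug)
    mu = {"SI0": pd.SI0, "kout": pd.kout, "Emax": pd.Emax, "EC50": pd.EC50}
    omega = dict(_PD_OMEGA)
    omega["EC50"] = _PD_OMEGA_EC50[drug]
    return PopulationModel(mu, omega, {"shannon": SHANNON_ERROR})
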