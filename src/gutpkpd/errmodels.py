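"""Residual error models and the left-censored Gaussian likelihood.

The residual standard deviation follows the combined convention

    sd(f) = sigma_inter + sigma_slope * f

with the constant (slope = 0) and proportional (inter = 0) models as special
cases.  Observations flagged below the lower limit of quantification
contribute P(Y < LLOQ) = Phi((LLOQ - f) / sd) to the likelihood (M3-style
censoring; BLOQ values are never imputed as LLOQ/2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import log_ndtr

ERROR_KINDS = ("constant", "proportional", "combined")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ErrorModel:
    kind: str
    sigma_inter: float = 0.0
    sigma_slope: float = 0.0

    def __post_init__(self):
        if self.kind not in ERROR_KINDS:
            raise ValueError(f"unknown error model kind {self.kind!r}")
        if self.sigma_inter < 0 or self.sigma_slope < 0:
            raise ValueError("error parameters must be non-negative")
        if self.kind == "constant" and self.sigma_inter == 0:
            raise ValueError("constant error model needs sigma_inter > 0")
        if self.kind == "proportional" and self.sigma_slope == 0:
            raise ValueError("proportional error model needs sigma_slope > 0")

    def sd(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        if self.kind == "constant":
            return np.full_like(f, self.sigma_inter)
        if self.kind == "proportional":
            return self.sigma_slope * np.abs(f)
        return self.sigma_inter + self.sigma_slope * np.abs(f)

    @property
    def n_params(self) -> int:
        return 2 if self.kind == "combined" else 1

    def params(self) -> np.ndarray:
        if self.kind == "constant":
            return np.array([self.sigma_inter])
        if self.kind == "proportional":
            return np.array([self.sigma_slope])
        return np.array([self.sigma_inter, self.sigma_slope])

    def with_params(self, values) -> "ErrorModel":
        values = np.asarray(values, dtype=float)
        if self.kind == "constant":
            return replace(self, sigma_inter=float(values[0]))
        if self.kind == "proportional":
            return replace(self, sigma_slope=float(values[0]))
        return replace(self, sigma_inter=float(values[0]),
                       sigma_slope=float(values[1]))


def residual_sd(f_value, error_model: ErrorModel) -> np.ndarray:
    """Residual standard deviation at model prediction ``f_value``."""
    sd = error_model.sd(f_value)
    if np.any(sd <= 0):
        raise ValueError("residual sd is not positive at an observation")
    return sd


def censored_loglik(obs, prediction, sd, bloq=None, lloq=None) -> np.ndarray:
    """Per-observation Gaussian log-likelihood with left censoring.

    Quantified rows get the Normal log-density of ``obs``; rows with
    ``bloq`` True get log Phi((lloq - prediction) / sd).
    """
    obs = np.asarray(obs, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    z = (obs - prediction) / sd
    ll = -0.5 * (_LOG_2PI + z * z) - np.log(sd)
    if bloq is not None:
        bloq = np.asarray(bloq, dtype=bool)
        if bloq.any():
            lloq = np.broadcast_to(np.asarray(lloq, dtype=float), obs.shape)
            zc = (lloq - prediction) / sd
            ll = np.where(bloq, log_ndtr(zc), ll)
    return ll
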