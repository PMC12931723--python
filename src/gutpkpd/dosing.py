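"""Dosing regimens and their expansion into dose events.

Time is in hours throughout the PK layer; t = 0 is the start of the first
administration (day 1 of treatment).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

IV_INFUSION = "iv_infusion"
ORAL = "oral"

#: drugs understood by the built-in parameter presets
KNOWN_DRUGS = (
    "CRO",              # ceftriaxone
    "TZP_piperacillin",
    "TZP_tazobactam",
    "CZA_ceftazidime",
    "CZA_avibactam",
    "MXF",              # moxifloxacin (oral)
)


@dataclass(frozen=True)
class Regimen:
    """A repeated-dose antibiotic course.

    Parameters
    ----------
    drug : str
        Compound label (free-form; presets use :data:`KNOWN_DRUGS`).
    dose_mg : float
        Mass per administration (mg).
    route : {"iv_infusion", "oral"}
    interval_h : float
        Inter-dose interval (h); 24 for once daily, 8 for q8h.
    n_days : int
        Treatment duration in days.
    infusion_h : float
        Infusion duration (h), IV route only.
    start_h : float
        Clock time of the first administration (h).
    """

    drug: str
    dose_mg: float
    route: str = IV_INFUSION
    interval_h: float = 24.0
    n_days: int = 5
    infusion_h: float = 0.5
    start_h: float = 0.0

    def __post_init__(self):
        if self.dose_mg <= 0:
            raise ValueError("dose must be positive")
        if self.interval_h <= 0:
            raise ValueError("interval must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be a positive integer")
        if self.route not in (IV_INFUSION, ORAL):
            raise ValueError(f"unknown route {self.route!r}")
        if self.route == IV_INFUSION and not 0 < self.infusion_h <= self.interval_h:
            raise ValueError("infusion duration must lie in (0, interval]")

    @property
    def doses_per_day(self) -> int:
        n = 24.0 / self.interval_h
        if abs(n - round(n)) > 1e-9:
            raise ValueError("interval must divide 24 h")
        return int(round(n))

    @property
    def n_doses(self) -> int:
        return self.doses_per_day * self.n_days

    def dose_times(self) -> np.ndarray:
        """Start times of every administration (h)."""
        return self.start_h + self.interval_h * np.arange(self.n_doses)

    @property
    def last_dose_time_h(self) -> float:
        return float(self.dose_times()[-1])

    @property
    def end_of_treatment_h(self) -> float:
        """End of the course: ``start + 24 * n_days`` hours."""
        return self.start_h + 24.0 * self.n_days

    @property
    def infusion_rate_mg_h(self) -> float:
        if self.route != IV_INFUSION:
            raise ValueError("infusion rate undefined for oral dosing")
        return self.dose_mg / self.infusion_h

    def with_duration(self, n_days: int) -> "Regimen":
        return replace(self, n_days=n_days)


def dav132_regimen(dose_g: float = 7.5, n_days: int = 7, start_h: float = 0.0) -> Regimen:
    """DAV132 adsorbent, three times a day for 7 days, oral route."""
    return Regimen("DAV132", dose_g * 1000.0, route=ORAL,
                   interval_h=8.0, n_days=n_days, start_h=start_h)
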