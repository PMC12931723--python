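"""Time-series container shared by the structural models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KINDS = ("plasma", "fecal_total", "fecal_free", "charcoal", "shannon")


@dataclass
class Trajectory:
    """A sampled deterministic time course.

    ``times`` are strictly increasing; units are tagged ("h" or "day").
    Concentration and Shannon values are non-negative.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str
    time_unit: str = "h"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-d and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.time_unit not in ("h", "day"):
            raise ValueError("time_unit must be 'h' or 'day'")

    def to_days(self) -> "Trajectory":
        if self.time_unit == "day":
            return self
        return Trajectory(self.times / 24.0, self.values, self.kind, "day")

    def to_hours(self) -> "Trajectory":
        if self.time_unit == "h":
            return self
        return Trajectory(self.times * 24.0, self.values, self.kind, "h")

    def interp(self, t) -> np.ndarray:
        """Linear interpolation at times ``t`` (same unit)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)
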