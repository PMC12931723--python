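"""Longitudinal trial data containers and long-format CSV I/O.

The exchange format is a long table with columns

    ID, TIME, DV, RESPONSE, MDV, CENS, LLOQ, AMT, RATE, CMT, ARM

TIME in hours.  Observation rows have MDV=0 and a RESPONSE in {"plasma",
"fecal", "shannon"} (plasma ug/mL, fecal ug/g, shannon log2 units); rows
below the lower limit of quantification carry CENS=1 and DV=LLOQ.  Dosing
rows have MDV=1, AMT in mg and RATE in mg/h (0 for a bolus), CMT=1 for the
central/depot compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESPONSES = ("plasma", "fecal", "shannon")

COLUMNS = ["ID", "TIME", "DV", "RESPONSE", "MDV", "CENS", "LLOQ",
           "AMT", "RATE", "CMT", "ARM"]


@dataclass
class ResponseSeries:
    """Observations of one response for one subject."""

    times: np.ndarray
    values: np.ndarray
    cens: np.ndarray
    lloq: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.cens = np.asarray(self.cens, dtype=bool)
        self.lloq = np.asarray(self.lloq, dtype=float)
        n = len(self.times)
        if not (len(self.values) == len(self.cens) == len(self.lloq) == n):
            raise ValueError("response arrays must share one length")
        if np.any(self.cens & ~np.isfinite(self.lloq)):
            raise ValueError("censored observations must carry their LLOQ")

    @property
    def n(self) -> int:
        return len(self.times)


@dataclass
class DoseEvent:
    time: float
    amount: float
    rate: float = 0.0  # mg/h; 0 means bolus
    compartment: int = 1


@dataclass
class SubjectRecord:
    """All data of one subject: identifiers, dosing and observations."""

    subject_id: str
    arm: str
    observations: dict = field(default_factory=dict)  # response -> ResponseSeries
    doses: list = field(default_factory=list)

    def response(self, name: str) -> ResponseSeries:
        return self.observations[name]

    @property
    def n_obs(self) -> int:
        return sum(s.n for s in self.observations.values())


@dataclass
class Dataset:
    """An ordered collection of subjects with flat-array access per response."""

    subjects: list

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def subject_ids(self) -> list:
        return [s.subject_id for s in self.subjects]

    @property
    def responses(self) -> list:
        seen = []
        for s in self.subjects:
            for r in s.observations:
                if r not in seen:
                    seen.append(r)
        return seen

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    def flat(self, response: str):
        """Flat arrays (subj_idx, times, y, cens, lloq) for one response."""
        idx, t, y, c, q = [], [], [], [], []
        for i, s in enumerate(self.subjects):
            if response not in s.observations:
                continue
            series = s.observations[response]
            idx.append(np.full(series.n, i))
            t.append(series.times)
            y.append(series.values)
            c.append(series.cens)
            q.append(series.lloq)
        if not idx:
            empty = np.array([])
            return empty.astype(int), empty, empty, empty.astype(bool), empty
        return (np.concatenate(idx).astype(int), np.concatenate(t),
                np.concatenate(y), np.concatenate(c), np.concatenate(q))

    def subset(self, *, arms=None, subject_ids=None, responses=None) -> "Dataset":
        keep = []
        for s in self.subjects:
            if arms is not None and s.arm not in arms:
                continue
            if subject_ids is not None and s.subject_id not in subject_ids:
                continue
            obs = s.observations
            if responses is not None:
                obs = {r: v for r, v in obs.items() if r in responses}
            keep.append(SubjectRecord(s.subject_id, s.arm, dict(obs),
                                      list(s.doses)))
        return Dataset(keep)

    # -- long-format I/O ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        frames = []
        for s in self.subjects:  # subject order preserved
            rows = []
            for d in s.doses:
                rows.append((s.subject_id, d.time, np.nan, ".", 1, 0, np.nan,
                             d.amount, d.rate, d.compartment, s.arm))
            for r, series in s.observations.items():
                for t, y, c, q in zip(series.times, series.values,
                                      series.cens, series.lloq):
                    rows.append((s.subject_id, t, y, r, 0, int(c),
                                 q if np.isfinite(q) else np.nan,
                                 0.0, 0.0, 0, s.arm))
            df = pd.DataFrame(rows, columns=COLUMNS)
            frames.append(df.sort_values(["TIME", "RESPONSE"], kind="stable"))
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        bad = df.loc[(df.MDV == 0) & ~df.RESPONSE.isin(RESPONSES), "RESPONSE"]
        if len(bad):
            raise ValueError(f"unknown response(s): {sorted(set(bad))}")
        if not df.loc[df.MDV == 0, "CENS"].isin([0, 1]).all():
            raise ValueError("CENS must be 0 or 1")
        cens_rows = df[(df.MDV == 0) & (df.CENS == 1)]
        if cens_rows.LLOQ.isna().any():
            raise ValueError("censored rows must carry their LLOQ")
        subjects = []
        for sid, g in df.groupby("ID", sort=False):
            arm = str(g.ARM.iloc[0])
            doses = [DoseEvent(float(r.TIME), float(r.AMT), float(r.RATE),
                               int(r.CMT))
                     for r in g[g.MDV == 1].itertuples()]
            obs = {}
            for resp, gr in g[g.MDV == 0].groupby("RESPONSE", sort=False):
                gr = gr.sort_values("TIME", kind="stable")
                obs[resp] = ResponseSeries(
                    gr.TIME.to_numpy(float), gr.DV.to_numpy(float),
                    gr.CENS.to_numpy(int).astype(bool),
                    gr.LLOQ.to_numpy(float))
            subjects.append(SubjectRecord(str(sid), arm, obs, doses))
        return cls(subjects)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        return cls.from_frame(pd.read_csv(path))
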