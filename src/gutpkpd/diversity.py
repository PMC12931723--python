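"""Shannon diversity of OTU count profiles.

Alpha diversity of a fecal sample is summarized by the Shannon index computed
on operational-taxonomic-unit (OTU) relative abundances,

    SI = -sum_i p_i * log2(p_i),

a dimensionless quantity in log-base-2 (bit) units, bounded by log2 of the
number of OTUs present.  Before normalization, OTUs whose total count equals
one (singletons, likely sequencing artifacts) are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "OTUProfile",
    "ShannonValue",
    "EmptyProfileError",
    "suppress_singletons",
    "shannon_index",
    "read_otu_table",
    "write_otu_table",
    "shannon_table",
]


class EmptyProfileError(ValueError):
    """Raised when no OTU with positive count remains in a profile."""


@dataclass(frozen=True)
class OTUProfile:
    """OTU counts for one sample.

    Parameters
    ----------
    otu_ids : list of str
        OTU identifiers, one per count.
    counts : array of int
        Non-negative read counts per OTU.
    sample_id : str
        Sample identifier.
    """

    otu_ids: tuple
    counts: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or len(counts) != len(self.otu_ids):
            raise ValueError("counts and otu_ids must have equal length")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("OTU counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("OTU counts must be non-negative")
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        object.__setattr__(self, "counts", counts)

    @property
    def n_observed(self) -> int:
        """Number of OTUs with count > 0."""
        return int((self.counts > 0).sum())


class ShannonValue(NamedTuple):
    value: float
    sample_id: str


def suppress_singletons(profile: OTUProfile) -> OTUProfile:
    """Remove OTUs whose count equals exactly 1, preserving order.

    Raises
    ------
    EmptyProfileError
        If nothing with a positive count survives (Shannon undefined).
    """
    keep = profile.counts != 1
    counts = profile.counts[keep]
    ids = tuple(i for i, k in zip(profile.otu_ids, keep) if k)
    if not (counts > 0).any():
        raise EmptyProfileError(
            f"sample {profile.sample_id!r}: no OTU left after singleton suppression"
        )
    return OTUProfile(ids, counts, profile.sample_id)


def shannon_index(profile: OTUProfile, *, suppress: bool = False) -> ShannonValue:
    """Shannon index (log base 2) of a profile.

    Zero-count OTUs contribute nothing (the p*log2(p) -> 0 limit).  With
    ``suppress=True`` singletons are removed first, the convention used for
    16S profiles in this package.
    """
    if suppress:
        profile = suppress_singletons(profile)
    counts = profile.counts[profile.counts > 0].astype(float)
    if counts.size == 0:
        raise EmptyProfileError(f"sample {profile.sample_id!r}: empty profile")
    p = counts / counts.sum()
    si = float(-(p * np.log2(p)).sum())
    # clip the tiny negative rounding that a single-OTU profile can produce
    return ShannonValue(max(si, 0.0), profile.sample_id)


def read_otu_table(path) -> list[OTUProfile]:
    """Read a tab-delimited OTU table (rows = OTUs, columns = samples).

    The first column holds OTU identifiers; every other column is one sample
    of integer counts.  Returns one :class:`OTUProfile` per sample column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    profiles = []
    otu_ids = tuple(str(i) for i in df.index)
    for col in df.columns:
        raw = df[col]
        values = pd.to_numeric(raw, errors="coerce")
        bad = values.isna()
        if bad.any():
            row = raw.index[bad.argmax()]
            raise ValueError(f"non-numeric count at OTU {row!r}, sample {col!r}")
        arr = values.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            row = raw.index[int(np.argmax(arr != np.round(arr)))]
            raise ValueError(f"non-integer count at OTU {row!r}, sample {col!r}")
        arr = arr.astype(np.int64)
        if (arr < 0).any():
            row = raw.index[int(np.argmax(arr < 0))]
            raise ValueError(f"negative count at OTU {row!r}, sample {col!r}")
        profiles.append(OTUProfile(otu_ids, arr, str(col)))
    return profiles


def write_otu_table(profiles: list[OTUProfile], path) -> None:
    """Write profiles (sharing one OTU id set) as a tab-delimited table."""
    if not profiles:
        raise ValueError("nothing to write")
    ids = profiles[0].otu_ids
    for p in profiles:
        if p.otu_ids != ids:
            raise ValueError("profiles must share the same OTU ids")
    df = pd.DataFrame(
        {p.sample_id: p.counts for p in profiles},
        index=pd.Index(ids, name="otu_id"),
    )
    df.to_csv(path, sep="\t")


def shannon_table(profiles: list[OTUProfile], *, suppress: bool = True) -> pd.DataFrame:
    """Shannon index per sample as a (sample_id, shannon) data frame."""
    rows = [shannon_index(p, suppress=suppress) for p in profiles]
    return pd.DataFrame({"sample_id": [r.sample_id for r in rows],
                         "shannon": [r.value for r in rows]})
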