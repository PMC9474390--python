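"""Spike tables: all spike times with unit labels.

The substrate for burst detection, connectivity inference and QC. Times are in
seconds (float64), unit ids are non-negative integers. Rows are kept sorted by
(unit_id, t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpikeTable"]


@dataclass(frozen=True)
class SpikeTable:
    unit_id: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        uid = np.asarray(self.unit_id, dtype=np.int64)
        t = np.asarray(self.t, dtype=np.float64)
        if uid.shape != t.shape or uid.ndim != 1:
            raise ValueError("unit_id and t must be 1-D arrays of equal length")
        if t.size and t.min() < 0:
            raise ValueError("spike times must be non-negative")
        order = np.lexsort((t, uid))
        object.__setattr__(self, "unit_id", uid[order])
        object.__setattr__(self, "t", t[order])

    def __len__(self) -> int:
        return self.t.size

    @property
    def units(self) -> np.ndarray:
        """Sorted array of distinct unit ids present in the table."""
        return np.unique(self.unit_id)

    @property
    def n_units(self) -> int:
        return self.units.size

    def duration(self) -> float:
        """Last spike time (lower bound on the recording duration)."""
        return float(self.t.max()) if len(self) else 0.0

    def spikes_of(self, unit: int) -> np.ndarray:
        """Sorted spike times (s) of one unit."""
        lo = np.searchsorted(self.unit_id, unit, side="left")
        hi = np.searchsorted(self.unit_id, unit, side="right")
        return self.t[lo:hi]

    def select_units(self, keep) -> "SpikeTable":
        mask = np.isin(self.unit_id, np.asarray(list(keep), dtype=np.int64))
        return SpikeTable(self.unit_id[mask], self.t[mask])

    def firing_rates(self, duration: float) -> pd.Series:
        """Per-unit firing rate in Hz over ``duration`` seconds."""
        if duration <= 0:
            raise ValueError("duration must be positive")
        counts = pd.Series(self.unit_id).value_counts().sort_index()
        return counts / float(duration)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"unit_id": self.unit_id, "t_s": self.t})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpikeTable":
        return cls(df["unit_id"].to_numpy(), df["t_s"].to_numpy())

    @classmethod
    def empty(cls) -> "SpikeTable":
        return cls(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64))

    @classmethod
    def concat(cls, tables) -> "SpikeTable":
        tables = list(tables)
        if not tables:
            return cls.empty()
        return cls(
            np.concatenate([tb.unit_id for tb in tables]),
            np.concatenate([tb.t for tb in tables]),
        )
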