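"""Planar HD-MEA electrode geometry.

The electrode array is the coordinate frame for every spatial operation in the
pipeline (footprint peak channels, axonal path lengths, duplicate-unit radii).
A full-size array in the style of the CMOS chips used for organoid recordings
has 26,400 electrodes on a 120 x 220 rectangular lattice at 17.5 um pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ElectrodeArray", "generate_array", "read_electrode_map", "write_electrode_map"]

DEFAULT_PITCH_UM = 17.5
FULL_ARRAY_ROWS = 120
FULL_ARRAY_COLS = 220


@dataclass(frozen=True)
class ElectrodeArray:
    """Set of electrodes with planar positions in micrometers.

    Attributes
    ----------
    electrode_id
        Integer electrode indices, unique.
    x, y
        Positions in um.
    pitch
        Nominal center-to-center spacing in um (nearest-neighbor distance on a
        full rectangular grid).
    """

    electrode_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pitch: float = DEFAULT_PITCH_UM
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        eid = np.asarray(self.electrode_id, dtype=int)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (eid.shape == x.shape == y.shape):
            raise ValueError("electrode_id, x, y must have equal length")
        if len(np.unique(eid)) != eid.size:
            raise ValueError("electrode ids must be unique")
        pos = np.column_stack([x, y])
        if len(np.unique(pos, axis=0)) != eid.size:
            raise ValueError("electrode positions must be unique")
        object.__setattr__(self, "electrode_id", eid)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "_index", {int(e): i for i, e in enumerate(eid)})

    def __len__(self) -> int:
        return self.electrode_id.size

    def positions(self, electrode_ids=None) -> np.ndarray:
        """(n, 2) array of positions in um, optionally for a subset of ids."""
        if electrode_ids is None:
            return np.column_stack([self.x, self.y])
        idx = [self._index[int(e)] for e in electrode_ids]
        return np.column_stack([self.x[idx], self.y[idx]])

    def bounding_box(self) -> tuple[float, float]:
        """(extent_x, extent_y) of the array in um."""
        return float(self.x.max() - self.x.min()), float(self.y.max() - self.y.min())


def generate_array(rows: int, cols: int, pitch: float = DEFAULT_PITCH_UM) -> ElectrodeArray:
    """Rectangular electrode lattice of ``rows`` x ``cols`` at ``pitch`` um.

    Electrode ids run row-major from 0; electrode 0 sits at the origin.
    Deterministic given its arguments.
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"rows and cols must be >= 1, got {rows} x {cols}")
    if pitch <= 0:
        raise ValueError(f"pitch must be positive, got {pitch}")
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return ElectrodeArray(
        electrode_id=np.arange(rows * cols),
        x=(c.ravel() * pitch).astype(float),
        y=(r.ravel() * pitch).astype(float),
        pitch=float(pitch),
    )


def write_electrode_map(array: ElectrodeArray, path: str | Path) -> None:
    pd.DataFrame(
        {"electrode_id": array.electrode_id, "x_um": array.x, "y_um": array.y}
    ).to_csv(path, index=False)


def read_electrode_map(path: str | Path, pitch: float = DEFAULT_PITCH_UM) -> ElectrodeArray:
    df = pd.read_csv(path)
    required = {"electrode_id", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"electrode map {path} must have columns {sorted(required)}")
    return ElectrodeArray(
        electrode_id=df["electrode_id"].to_numpy(),
        x=df["x_um"].to_numpy(),
        y=df["y_um"].to_numpy(),
        pitch=pitch,
    )
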