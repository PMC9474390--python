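"""Readers and writers for on-disk artifacts.

Conventions used throughout the package: times are seconds (float64),
coordinates are um, amplitudes are uV, channel indices are 0-based, intervals
are end-exclusive. Tables travel as CSV, dense waveform arrays as HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .footprint import ElectricalFootprint
from .spiketable import SpikeTable

__all__ = [
    "read_spike_table",
    "write_spike_table",
    "read_ef_store",
    "write_ef_store",
    "write_ground_truth",
    "read_ground_truth",
]


def write_spike_table(spikes: SpikeTable, path: str | Path) -> None:
    """Write a spike table as CSV with header ``unit_id,t_s``."""
    spikes.to_dataframe().to_csv(path, index=False)


def read_spike_table(path: str | Path) -> SpikeTable:
    """Read and validate a ``unit_id,t_s`` CSV (or TSV) spike table.

    Rows are returned sorted by (unit_id, t). Malformed rows and negative
    times are reported with their 1-based line numbers (header = line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"unit_id", "t_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: header must contain columns {sorted(required)}")
    uid = pd.to_numeric(df["unit_id"], errors="coerce")
    t = pd.to_numeric(df["t_s"], errors="coerce")
    bad = df.index[uid.isna() | t.isna() | (uid != uid.round())]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"{path}: malformed rows at line(s) {lines}")
    neg = df.index[t < 0]
    if len(neg):
        lines = ", ".join(str(i + 2) for i in neg[:10])
        raise ValueError(f"{path}: negative spike times at line(s) {lines}")
    return SpikeTable(uid.to_numpy(dtype=np.int64), t.to_numpy(dtype=float))


def write_ef_store(efs, path: str | Path) -> None:
    """Write footprints to HDF5: group ``/ef/<unit_id>`` with datasets
    ``waveform`` (channels x samples, float32), ``channels`` (electrode ids)
    and ``channel_positions`` (um), and attributes ``fs_hz``, ``peak_channel``,
    ``n_spikes_averaged``."""
    with h5py.File(path, "w") as f:
        root = f.create_group("ef")
        for ef in efs:
            g = root.create_group(str(int(ef.unit_id)))
            g.create_dataset("waveform", data=np.asarray(ef.waveform, dtype=np.float32))
            g.create_dataset("channels", data=np.asarray(ef.channel_ids, dtype=np.int64))
            g.create_dataset("channel_positions", data=np.asarray(ef.channel_positions))
            g.attrs["fs_hz"] = float(ef.fs)
            g.attrs["peak_channel"] = int(ef.peak_channel)
            g.attrs["n_spikes_averaged"] = int(ef.n_spikes_averaged)


def read_ef_store(path: str | Path) -> list[ElectricalFootprint]:
    """Read an EF store; footprints are returned in ascending unit_id order.

    A group without the ``fs_hz`` attribute is a validation error.
    """
    out = []
    with h5py.File(path, "r") as f:
        if "ef" not in f:
            raise ValueError(f"{path}: missing /ef group")
        for key in sorted(f["ef"], key=int):
            g = f["ef"][key]
            if "fs_hz" not in g.attrs:
                raise ValueError(f"{path}: /ef/{key} lacks required attribute fs_hz")
            out.append(
                ElectricalFootprint(
                    unit_id=int(key),
                    waveform=g["waveform"][()],
                    channel_positions=g["channel_positions"][()],
                    fs=float(g.attrs["fs_hz"]),
                    channel_ids=g["channels"][()],
                    peak_channel=int(g.attrs.get("peak_channel", -1))
                    if "peak_channel" in g.attrs
                    else None,
                    n_spikes_averaged=int(g.attrs.get("n_spikes_averaged", 0)),
                )
            )
    return out


def write_ground_truth(gt, path: str | Path) -> None:
    """JSON sidecar holding the generative truths of a simulation."""
    d = {
        "unit_rate": gt.unit_rate,
        "burst_rate": gt.burst_rate,
        "burst_duration": gt.burst_duration,
        "burst_osc_freq": gt.burst_osc_freq,
        "burst_gain": gt.burst_gain,
        "true_velocity": gt.true_velocity,
        "axon_path": {str(k): [int(e) for e in v] for k, v in gt.axon_path.items()},
        "syn_graph": [list(e) for e in gt.syn_graph],
        "seed": gt.seed,
    }
    Path(path).write_text(json.dumps(d, indent=1))


def read_ground_truth(path: str | Path):
    from .synth import GroundTruth

    d = json.loads(Path(path).read_text())
    d["axon_path"] = {int(k): v for k, v in d.get("axon_path", {}).items()}
    d["syn_graph"] = [tuple(e) for e in d.get("syn_graph", [])]
    return GroundTruth(**d)
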