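"""Post-sorting quality control and electrical-footprint inference.

Two QC rules are applied to spike-sorted output before any analysis: units
with too many refractory-period violations are contaminated and dropped, and
near-coincident spikes of spatially co-located units (sorter duplicates) are
removed. QC only deletes rows; it never alters a spike time, and both filters
are idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .footprint import ElectricalFootprint, peak_channel_of
from .spiketable import SpikeTable

__all__ = [
    "refractory_filter",
    "activity_filter",
    "remove_duplicate_spikes",
    "spike_triggered_ef",
    "QCReport",
]


@dataclass
class QCReport:
    """Per-unit QC outcome: ISI-violation fraction, kept flag, spikes removed."""

    violation_fraction: dict = field(default_factory=dict)
    kept: dict = field(default_factory=dict)
    spikes_removed: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        units = sorted(set(self.violation_fraction) | set(self.kept) | set(self.spikes_removed))
        return {
            str(u): {
                "violation_fraction": self.violation_fraction.get(u),
                "kept": self.kept.get(u, True),
                "spikes_removed": self.spikes_removed.get(u, 0),
            }
            for u in units
        }


def refractory_filter(
    spikes: SpikeTable, refractory_ms: float = 1.0, max_fraction: float = 0.05
) -> tuple[SpikeTable, QCReport]:
    """Drop units whose fraction of inter-spike intervals in [0, 1) ms exceeds 5%.

    The violation fraction is (# ISIs < refractory_ms) / (# spikes), i.e. the
    mass of the first 1-ms ISI-histogram bin relative to the unit's spike
    count. Returns the filtered table and a report with per-unit fractions.
    """
    report = QCReport()
    keep_units = []
    for u in spikes.units:
        ts = spikes.spikes_of(u)
        if ts.size < 2:
            frac = 0.0
        else:
            isi = np.diff(ts)
            frac = float(np.count_nonzero(isi < refractory_ms * 1e-3) / ts.size)
        kept = frac <= max_fraction
        report.violation_fraction[int(u)] = frac
        report.kept[int(u)] = bool(kept)
        if not kept:
            report.spikes_removed[int(u)] = int(ts.size)
        if kept:
            keep_units.append(u)
    return spikes.select_units(keep_units), report


def activity_filter(spikes: SpikeTable, min_spikes: int = 50) -> tuple[SpikeTable, QCReport]:
    """Drop units with too little activity (< ``min_spikes`` per recording)."""
    report = QCReport()
    keep = []
    for u in spikes.units:
        n = spikes.spikes_of(u).size
        kept = n >= min_spikes
        report.kept[int(u)] = bool(kept)
        if not kept:
            report.spikes_removed[int(u)] = int(n)
        else:
            keep.append(u)
    return spikes.select_units(keep), report


def remove_duplicate_spikes(
    spikes: SpikeTable,
    efs,
    window_ms: float = 0.5,
    radius_um: float = 100.0,
) -> tuple[SpikeTable, QCReport]:
    """Remove sorter-duplicate spikes between co-located unit pairs.

    For every pair of units whose EF peak channels lie within ``radius_um``,
    spikes of the lower-trough-amplitude unit that fall within ``window_ms``
    of a spike of the higher-amplitude unit are dropped (the larger unit is
    taken as the true source; amplitude ties break toward the lower unit id).
    """
    ef_by_unit = {int(ef.unit_id): ef for ef in efs}
    missing = [int(u) for u in spikes.units if int(u) not in ef_by_unit]
    if missing:
        raise ValueError(f"no electrical footprint for unit(s) {missing}")
    units = [int(u) for u in spikes.units]
    trains = {u: spikes.spikes_of(u) for u in units}
    keep = {u: np.ones(trains[u].size, dtype=bool) for u in units}
    report = QCReport()
    win = window_ms * 1e-3
    for i, a in enumerate(units):
        for b in units[i + 1 :]:
            pa = ef_by_unit[a].peak_position()
            pb = ef_by_unit[b].peak_position()
            if np.linalg.norm(pa - pb) > radius_um:
                continue
            amp_a = ef_by_unit[a].trough_amplitudes()[ef_by_unit[a].peak_channel]
            amp_b = ef_by_unit[b].trough_amplitudes()[ef_by_unit[b].peak_channel]
            big, small = (a, b) if amp_a >= amp_b else (b, a)
            tb, ts = trains[big], trains[small]
            if tb.size == 0 or ts.size == 0:
                continue
            # nearest big-unit spike within the window
            idx = np.searchsorted(tb, ts)
            near = np.full(ts.size, np.inf)
            left = idx > 0
            near[left] = np.abs(ts[left] - tb[idx[left] - 1])
            right = idx < tb.size
            near[right] = np.minimum(near[right], np.abs(tb[idx[right]] - ts[right]))
            keep[small] &= ~(near <= win)
    ids, times = [], []
    for u in units:
        removed = int(np.count_nonzero(~keep[u]))
        report.spikes_removed[int(u)] = removed
        report.kept[int(u)] = True
        ids.append(np.full(int(keep[u].sum()), u, dtype=np.int64))
        times.append(trains[u][keep[u]])
    return SpikeTable(np.concatenate(ids), np.concatenate(times)), report


def spike_triggered_ef(
    traces: np.ndarray,
    spike_times: np.ndarray,
    fs: float,
    channel_positions: np.ndarray,
    unit_id: int = 0,
    pre_ms: float = 2.0,
    post_ms: float = 3.0,
    min_spikes: int = 30,
) -> ElectricalFootprint | None:
    """Electrical footprint by spike-triggered averaging.

    Averages ``traces`` (channels x samples, uV) in a window of ``pre_ms``
    before to ``post_ms`` after each spike; only spikes whose window lies
    fully inside the trace contribute. Returns None (with a warning) when
    fewer than ``min_spikes`` usable spikes remain.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_pre = int(round(pre_ms * 1e-3 * fs))
    n_post = int(round(post_ms * 1e-3 * fs))
    centers = np.round(np.asarray(spike_times, dtype=float) * fs).astype(int)
    ok = (centers - n_pre >= 0) & (centers + n_post < traces.shape[1])
    centers = centers[ok]
    if centers.size < min_spikes:
        warnings.warn(
            f"unit {unit_id}: only {centers.size} usable spikes (< {min_spikes}); skipped"
        )
        return None
    window = np.arange(-n_pre, n_post + 1)
    acc = traces[:, centers[:, None] + window[None, :]].mean(axis=1)
    return ElectricalFootprint(
        unit_id=unit_id,
        waveform=acc.astype(np.float32),
        channel_positions=channel_positions,
        fs=fs,
        peak_channel=peak_channel_of(acc),
        n_spikes_averaged=int(centers.size),
    )
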