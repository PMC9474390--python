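"""Synthetic HD-MEA ground-truth data.

Generates datasets with the statistical structure the analysis chain assumes:
sparse background firing with rare, seconds-long population bursts carrying an
oscillatory LFP component; per-unit electrical footprints whose latencies
follow an axonal path at a known conduction velocity with amplitude decaying
away from the peak channel; and a known sparse directed synaptic graph with
millisecond transmission delays.

Defaults mirror the activity regime of cerebral-organoid slices on HD-MEAs:
~0.38 Hz background firing per unit, population bursts at ~0.01 Hz lasting
~4 s with a ~14 Hz oscillation, and axonal conduction at ~0.4 m/s on a
17.5 um electrode pitch.

All randomness flows from one root seed through named substreams (per unit,
per edge, per channel), so enlarging a simulation never perturbs the parts
that were already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .footprint import ElectricalFootprint
from .geometry import ElectrodeArray
from .rng import substream
from .spiketable import SpikeTable

__all__ = [
    "GroundTruth",
    "generate_spike_network",
    "generate_ef",
    "spike_template",
    "generate_burst_lfp",
    "burst_windows",
    "random_axon_path",
]

#: ramp time (s) of the raised-cosine burst envelope
BURST_RAMP_S = 0.5
#: default multiplicative rate gain inside a burst
BURST_GAIN = 20.0
#: modulation depth of the within-burst oscillation
BURST_OSC_DEPTH = 0.8


@dataclass
class GroundTruth:
    """Generative truths of one synthetic recording.

    Parameters
    ----------
    unit_rate
        Background firing rate per unit, Hz.
    burst_rate
        Rate of population-burst initiation, Hz (Poisson arrivals).
    burst_duration
        Fixed burst length, s.
    burst_osc_freq
        Frequency (Hz) of the oscillatory rate modulation inside bursts.
    burst_gain
        Peak multiplicative rate gain inside a burst.
    true_velocity
        Axonal conduction velocity, m/s (per unit if an array is given).
    axon_path
        Ordered electrode-id list per unit (dict unit -> list).
    syn_graph
        Directed synaptic edges as (source, target, delay_ms, prob) tuples.
        Delays must be >= 1 ms so that injected connections survive the
        <1 ms-latency exclusion applied during connectivity inference.
    seed
        Root seed of all substreams.
    """

    unit_rate: float = 0.38
    burst_rate: float = 0.01
    burst_duration: float = 4.05
    burst_osc_freq: float = 14.33
    burst_gain: float = BURST_GAIN
    true_velocity: float = 0.41
    axon_path: dict = field(default_factory=dict)
    syn_graph: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for src, tgt, delay_ms, prob in self.syn_graph:
            if delay_ms < 1.0:
                raise ValueError(
                    f"synaptic delay {delay_ms} ms on edge {src}->{tgt} is < 1 ms; "
                    "such connections would be excluded by the short-latency rule"
                )
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"transmission probability {prob} outside [0, 1]")


def burst_windows(gt: GroundTruth, duration: float) -> np.ndarray:
    """(n, 2) array of burst [onset, offset) windows in s, Poisson-arriving.

    Deterministic given ``gt.seed``; windows may overlap the recording end but
    onsets always lie inside [0, duration).
    """
    rng = substream(gt.seed, "bursts")
    if gt.burst_rate <= 0 or duration <= 0:
        return np.empty((0, 2))
    n = rng.poisson(gt.burst_rate * duration)
    onsets = np.sort(rng.uniform(0.0, duration, size=n))
    return np.column_stack([onsets, onsets + gt.burst_duration])


def _burst_envelope(t: np.ndarray, windows: np.ndarray, osc_freq: float) -> np.ndarray:
    """Multiplicative rate factor at times ``t``: 1 outside bursts, up to
    ``burst_gain`` inside, with raised-cosine on/offset ramps and an
    oscillatory modulation of the burst excess."""
    env = np.zeros_like(t, dtype=float)
    osc = np.ones_like(t, dtype=float)
    for onset, offset in windows:
        inside = (t >= onset) & (t < offset)
        if not inside.any():
            continue
        tt = t[inside] - onset
        ramp = np.ones_like(tt)
        dur = offset - onset
        r = min(BURST_RAMP_S, dur / 2.0)
        rising = tt < r
        falling = tt > dur - r
        ramp[rising] = 0.5 * (1 - np.cos(np.pi * tt[rising] / r))
        ramp[falling] = 0.5 * (1 - np.cos(np.pi * (dur - tt[falling]) / r))
        env[inside] = np.maximum(env[inside], ramp)
        osc[inside] = 1.0 + BURST_OSC_DEPTH * np.sin(2 * np.pi * osc_freq * tt)
    return env, osc


def generate_spike_network(gt: GroundTruth, n_units: int, duration: float) -> SpikeTable:
    """Simulate ``n_units`` spike trains over ``duration`` seconds.

    Background spikes are homogeneous Poisson at ``gt.unit_rate`` per unit.
    During each burst window the rate is multiplied by a raised-cosine
    envelope reaching ``gt.burst_gain``, with the burst excess modulated at
    ``gt.burst_osc_freq`` (inhomogeneous Poisson, realized by thinning).
    For every ground-truth edge (i -> j, delay d, prob p) each source spike
    adds a target spike at t + d with probability p.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    windows = burst_windows(gt, duration)
    # peak achievable rate, for Poisson thinning
    rmax = gt.unit_rate * (1.0 + (gt.burst_gain - 1.0) * (1.0 + BURST_OSC_DEPTH))
    ids, times = [], []
    for u in range(n_units):
        rng = substream(gt.seed, "unit", u)
        if rmax <= 0:
            continue
        n_cand = rng.poisson(rmax * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        env, osc = _burst_envelope(cand, windows, gt.burst_osc_freq)
        rate = gt.unit_rate * (1.0 + (gt.burst_gain - 1.0) * env * osc)
        keep = rng.uniform(0.0, rmax, size=n_cand) < rate
        ts = cand[keep]
        ids.append(np.full(ts.size, u, dtype=np.int64))
        times.append(ts)
    base = SpikeTable(
        np.concatenate(ids) if ids else np.empty(0, dtype=np.int64),
        np.concatenate(times) if times else np.empty(0),
    )
    # synaptic transmission: one pass over the ground-truth edges (no cascades)
    extra_ids, extra_times = [], []
    for k, (src, tgt, delay_ms, prob) in enumerate(gt.syn_graph):
        rng = substream(gt.seed, "edge", k)
        src_t = base.spikes_of(src)
        fired = rng.uniform(size=src_t.size) < prob
        ts = src_t[fired] + delay_ms * 1e-3
        ts = ts[ts < duration]
        extra_ids.append(np.full(ts.size, tgt, dtype=np.int64))
        extra_times.append(ts)
    if extra_ids:
        return SpikeTable(
            np.concatenate([base.unit_id] + extra_ids),
            np.concatenate([base.t] + extra_times),
        )
    return base


# ---------------------------------------------------------------------------
# electrical footprints


def spike_template(t: np.ndarray, kind: str = "biphasic") -> np.ndarray:
    """Unit-amplitude extracellular spike template evaluated at times ``t`` (s).

    The trough (value -1) sits at t = 0; total extent ~1.5 ms. ``kind``
    selects a somatic biphasic shape (negative trough then positive peak) or a
    smaller-afterpeak triphasic axonal variant.
    """
    t = np.asarray(t, dtype=float)
    s1 = 0.15e-3  # trough width
    if kind == "biphasic":
        w = -np.exp(-0.5 * (t / s1) ** 2) + 0.45 * np.exp(-0.5 * ((t - 0.45e-3) / 0.3e-3) ** 2)
    elif kind == "triphasic":
        w = (
            0.35 * np.exp(-0.5 * ((t + 0.35e-3) / 0.15e-3) ** 2)
            - np.exp(-0.5 * (t / s1) ** 2)
            + 0.3 * np.exp(-0.5 * ((t - 0.4e-3) / 0.25e-3) ** 2)
        )
    elif kind == "monophasic":
        # wide negative-only deflection, somatic-like (kept narrow enough
        # that trough alignment on noisy waveforms stays sample-stable)
        w = -np.exp(-0.5 * (t / 0.25e-3) ** 2)
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    return w / np.abs(w.min())


def _cumulative_distance(array: ElectrodeArray, path) -> np.ndarray:
    pos = array.positions(path)
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(step)])


def generate_ef(
    array: ElectrodeArray,
    axon_path,
    velocity: float,
    peak_amp: float = 80.0,
    decay_const: float = 50.0,
    noise_sd: float = 1.0,
    fs: float = 20_000.0,
    unit_id: int = 0,
    latency_jitter_s: float = 0.0,
    template_kind: str = "biphasic",
    seed: int = 0,
) -> ElectricalFootprint:
    """Synthesize a propagating electrical footprint along ``axon_path``.

    Electrode k on the path carries a spike template whose trough lags the
    path origin by cumdist(k)/velocity (plus optional Gaussian latency jitter
    of SD ``latency_jitter_s``) and whose amplitude is
    ``peak_amp * exp(-cumdist(k)/decay_const)``. All other electrodes of
    ``array`` carry i.i.d. Gaussian noise of SD ``noise_sd`` only.

    The waveform window spans 2 ms before the first trough to 3 ms after the
    last, sampled at ``fs``.
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    path = list(axon_path)
    missing = [e for e in path if int(e) not in array._index]
    if missing:
        raise ValueError(f"path electrodes {missing} not in array")
    cum_um = _cumulative_distance(array, path)
    lat = cum_um * 1e-6 / velocity  # s
    if latency_jitter_s > 0:
        rng_j = substream(seed, "ef-jitter", unit_id)
        lat = lat + np.concatenate([[0.0], rng_j.normal(0.0, latency_jitter_s, lat.size - 1)])
    pre, post = 2e-3, 3e-3
    n_samples = int(round((pre + lat.max() + post) * fs)) + 1
    tgrid = np.arange(n_samples) / fs - pre
    rng = substream(seed, "ef-noise", unit_id)
    wf = rng.normal(0.0, noise_sd, size=(len(array), n_samples))
    path_rows = [array._index[int(e)] for e in path]
    for row, d_um, tau in zip(path_rows, cum_um, lat):
        amp = peak_amp * np.exp(-d_um / decay_const)
        wf[row] += amp * spike_template(tgrid - tau, kind=template_kind)
    return ElectricalFootprint(
        unit_id=unit_id,
        waveform=wf.astype(np.float32),
        channel_positions=array.positions(),
        fs=fs,
        channel_ids=array.electrode_id,
        n_spikes_averaged=0,
    )


def random_axon_path(
    array: ElectrodeArray,
    rows: int,
    cols: int,
    n_steps: int,
    rng: np.random.Generator,
    clearance_steps: int = 4,
):
    """Random lattice walk of ``n_steps`` nearest-neighbor steps on a
    ``rows x cols`` grid (as produced by :func:`generate_array`).

    The walk is mostly straight with occasional gentle 90-degree turns and is
    self-avoiding at the flow-graph reach scale: a new electrode must stay
    more than 3 pitches away from every path electrode more than
    ``clearance_steps`` steps back. (An axon doubling back within the 60 um
    electrode reach would make its own graph shortcut and is not a traceable
    path for the latency flow-graph method.) Consecutive electrodes are one
    pitch apart; returns a list of electrode ids.
    """
    r = int(rng.integers(rows // 3, 2 * rows // 3 + 1))
    c = int(rng.integers(cols // 3, 2 * cols // 3 + 1))
    path = [(r, c)]
    heading = rng.choice([(0, 1), (0, -1), (1, 0), (-1, 0)])
    heading = (int(heading[0]), int(heading[1]))
    for _ in range(n_steps):
        # mostly straight, occasional 90-degree turn: gently curved axons
        options = [heading] * 10 + [(heading[1], heading[0]), (-heading[1], -heading[0])]
        rng.shuffle(options)
        for dr, dc in options:
            nr, nc = path[-1][0] + dr, path[-1][1] + dc
            if not (0 <= nr < rows and 0 <= nc < cols):
                continue
            if any(
                abs(nr - pr) <= 3 and abs(nc - pc) <= 3
                for pr, pc in path[: max(0, len(path) - clearance_steps)]
            ):
                continue
            path.append((nr, nc))
            heading = (dr, dc)
            break
        else:
            break
    return [r_ * cols + c_ for r_, c_ in path]


# ---------------------------------------------------------------------------
# burst-gated LFP


def generate_burst_lfp(
    osc_freq: float,
    windows,
    duration: float,
    fs: float = 1000.0,
    aperiodic_exponent: float = 2.0,
    osc_amp: float = 5.0,
    noise_scale: float = 1.0,
    n_groups: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """LFP-like signals on ``n_groups`` electrode groups: 1/f^exponent
    background everywhere plus a sinusoid at ``osc_freq`` inside the burst
    ``windows`` (raised-cosine gated).

    Returns a (n_groups, n_samples) float array; each group models the mean
    signal over a handful of adjacent electrodes.
    """
    if fs < 2 * osc_freq:
        raise ValueError("fs must be at least twice the oscillation frequency")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-aperiodic_exponent / 2.0)
    out = np.empty((n_groups, n))
    gate = np.zeros(n)
    for onset, offset in np.asarray(windows, dtype=float).reshape(-1, 2):
        onset, offset = max(0.0, onset), min(duration, offset)
        if offset <= onset:
            continue
        i0, i1 = int(onset * fs), int(offset * fs)
        tt = t[i0:i1] - t[i0]
        dur = tt[-1] if len(tt) else 0.0
        r = min(BURST_RAMP_S, dur / 2.0) if dur > 0 else 0.0
        ramp = np.ones_like(tt)
        if r > 0:
            ramp = np.minimum(1.0, np.minimum(tt, dur - tt) / r)
        gate[i0:i1] = np.maximum(gate[i0:i1], ramp)
    osc = osc_amp * gate * np.sin(2 * np.pi * osc_freq * t)
    for g in range(n_groups):
        rng = substream(seed, "lfp", g)
        spec = shape * (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
        spec[0] = 0.0
        bg = np.fft.irfft(spec, n=n)
        bg *= noise_scale / max(bg.std(), 1e-30)
        out[g] = bg + osc
    return out
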