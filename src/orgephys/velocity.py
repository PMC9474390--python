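"""Axonal action-potential propagation velocity from electrical footprints.

The per-electrode trough times of an EF, taken relative to the peak channel,
form a latency map. Electrodes whose signal exceeds the noise floor and whose
trough occurs at or after the peak channel's are turned into a directed flow
graph: an edge i -> j exists when latency(i) < latency(j) and the electrodes
are at most 60 um apart. The graph is acyclic by construction, and the
shortest path (by cumulative Euclidean edge length) from the peak channel to
the most distant electrode of each flow-graph cluster traces a putative
axonal segment. Ordinary least squares of cumulative path distance on latency
then gives the conduction velocity in m/s; only fits with r^2 > 0.8 count as
reliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import signal, stats

from .footprint import ElectricalFootprint

__all__ = [
    "LatencyMap",
    "latency_map",
    "build_flow_graph",
    "extract_paths",
    "fit_velocity",
    "VelocityEstimate",
    "estimate_unit_velocity",
]

RESAMPLE_FS = 20_000.0


@dataclass
class LatencyMap:
    """Per-electrode trough latencies relative to the peak channel.

    latency_ms is NaN for masked-out electrodes; ``included`` marks
    electrodes above the noise floor with latency >= 0.
    """

    latency_ms: np.ndarray
    amplitude_uv: np.ndarray
    included: np.ndarray
    positions_um: np.ndarray
    peak_channel: int
    fs: float


def _parabolic_refine(x: np.ndarray, i: int) -> float:
    """Sub-sample trough position via a 3-point parabola around sample ``i``."""
    if i <= 0 or i >= x.size - 1:
        return float(i)
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (y0 - y2) / denom)


def latency_map(
    ef: ElectricalFootprint,
    noise_mad_factor: float = 5.0,
    subsample_interp: bool = False,
) -> LatencyMap | None:
    """Latency map of one EF.

    The EF is upsampled to 20 kHz if recorded slower. Per channel, the trough
    time is found and referenced to the peak channel; channels whose trough
    amplitude does not exceed ``noise_mad_factor`` x the MAD of the channel's
    pre-trough baseline, and channels with negative latency (signal before the
    peak channel), are masked out. Returns None when no electrode besides the
    peak survives.
    """
    wf = np.asarray(ef.waveform, dtype=float)
    fs = float(ef.fs)
    if fs < RESAMPLE_FS:
        up = int(round(RESAMPLE_FS / fs))
        wf = signal.resample_poly(wf, up, 1, axis=1)
        fs = fs * up
    trough_idx = wf.argmin(axis=1)
    peak = ef.peak_channel
    peak_idx = trough_idx[peak]
    amp = np.abs(wf.min(axis=1))
    # per-channel noise floor from the pre-trough baseline
    n_base = max(int(peak_idx - 0.5e-3 * fs), 2)
    baseline = wf[:, :n_base]
    mad = np.median(np.abs(baseline - np.median(baseline, axis=1, keepdims=True)), axis=1)
    # the short baseline makes per-channel MADs noisy; flooring them at the
    # across-channel median stops underestimated floors admitting noise troughs
    mad = np.maximum(mad, np.median(mad))
    floor = noise_mad_factor * 1.4826 * mad
    if subsample_interp:
        pos = np.array([_parabolic_refine(wf[c], int(trough_idx[c])) for c in range(wf.shape[0])])
        lat_ms = (pos - pos[peak]) / fs * 1e3
    else:
        lat_ms = (trough_idx - peak_idx) / fs * 1e3
    included = (amp > floor) & (lat_ms >= 0)
    included[peak] = True
    lat_ms = np.where(included, lat_ms, np.nan)
    lat_ms[peak] = 0.0
    if included.sum() < 2:
        return None
    return LatencyMap(
        latency_ms=lat_ms,
        amplitude_uv=amp,
        included=included,
        positions_um=np.asarray(ef.channel_positions, dtype=float),
        peak_channel=int(peak),
        fs=fs,
    )


def build_flow_graph(lmap: LatencyMap, max_edge_um: float = 60.0) -> nx.DiGraph:
    """Directed latency-ordered electrode graph.

    Nodes are included electrodes (channel indices); a directed edge i -> j
    exists iff latency(i) < latency(j) and the Euclidean distance between the
    electrodes is <= ``max_edge_um``. Edge attribute ``length`` is the
    distance in um. Strict latency ordering makes the graph acyclic.
    """
    nodes = np.flatnonzero(lmap.included)
    g = nx.DiGraph()
    pos = lmap.positions_um
    lat = lmap.latency_ms
    g.add_nodes_from((int(n), {"pos": pos[n]}) for n in nodes)
    for a_i, i in enumerate(nodes):
        for j in nodes[a_i + 1 :]:
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d > max_edge_um:
                continue
            if lat[i] < lat[j]:
                g.add_edge(int(i), int(j), length=d)
            elif lat[j] < lat[i]:
                g.add_edge(int(j), int(i), length=d)
    return g


def extract_paths(g: nx.DiGraph, peak: int) -> list[list[int]]:
    """Axonal segment paths from the peak channel.

    The electrodes reachable from ``peak`` are clustered into weakly connected
    components (after removing the peak itself); for each cluster, the
    shortest path (by cumulative edge length) from the peak to the cluster's
    electrode with maximal Euclidean distance from the peak is returned.
    Empty list when nothing is reachable.
    """
    if peak not in g:
        raise ValueError(f"peak channel {peak} not in flow graph")
    reach = nx.descendants(g, peak)
    if not reach:
        return []
    # break exact length ties toward the path visiting more electrodes, so a
    # straight chain is traced electrode by electrode (denser regression)
    eps = 1e-6
    lengths, spaths = nx.single_source_dijkstra(
        g, peak, weight=lambda u, v, d: d["length"] - eps
    )

    def dist_from_peak(n: int) -> float:
        pos_p, pos_n = g.nodes[peak].get("pos"), g.nodes[n].get("pos")
        if pos_p is None or pos_n is None:
            return lengths[n]  # no coordinates attached: cumulative length proxy
        return float(np.linalg.norm(np.asarray(pos_p) - np.asarray(pos_n)))

    sub = g.subgraph(reach).to_undirected(as_view=True)
    paths = []
    for comp in nx.connected_components(sub):
        comp = [n for n in comp if n in spaths]
        if not comp:
            continue
        target = max(comp, key=dist_from_peak)
        paths.append(spaths[target])
    return paths


def path_cumulative_distance(g: nx.DiGraph, path: list[int]) -> np.ndarray:
    """Cumulative edge length (um) along ``path``, starting at 0."""
    steps = [g[u][v]["length"] for u, v in zip(path[:-1], path[1:])]
    return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class VelocityEstimate:
    velocity_mps: float
    r2: float
    n_segments: int
    traced_um: float
    paths: list = field(default_factory=list)

    @property
    def included(self) -> bool:
        """Reliable-fit flag used for cohort statistics (r^2 > 0.8)."""
        return self.r2 > 0.8 and self.velocity_mps > 0


def fit_velocity(
    g: nx.DiGraph, paths: list[list[int]], lmap: LatencyMap, min_r2: float = 0.8
) -> VelocityEstimate | None:
    """OLS velocity fit over the pooled electrodes of all segment paths.

    Regresses cumulative path distance (m) on latency (s); the slope is the
    conduction velocity in m/s. Needs at least 3 pooled electrodes. The
    ``included`` flag of the returned estimate is True only for r^2 > 0.8.
    """
    xs, ys = [], []  # latency s, cumdist m
    traced = 0.0
    for path in paths:
        cum = path_cumulative_distance(g, path)
        traced = max(traced, cum[-1])
        for node, d in zip(path, cum):
            xs.append(lmap.latency_ms[node] * 1e-3)
            ys.append(d * 1e-6)
    if len(xs) < 3:
        return None
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.allclose(xs, xs[0]):
        return None
    res = stats.linregress(xs, ys)
    return VelocityEstimate(
        velocity_mps=float(res.slope),
        r2=float(res.rvalue**2),
        n_segments=len(paths),
        traced_um=float(traced),
        paths=paths,
    )


def estimate_unit_velocity(
    ef: ElectricalFootprint,
    noise_mad_factor: float = 5.0,
    max_edge_um: float = 60.0,
    subsample_interp: bool = False,
) -> VelocityEstimate | None:
    """Full chain for one unit: latency map -> flow graph -> paths -> OLS fit."""
    lmap = latency_map(ef, noise_mad_factor=noise_mad_factor, subsample_interp=subsample_interp)
    if lmap is None:
        return None
    g = build_flow_graph(lmap, max_edge_um=max_edge_um)
    paths = extract_paths(g, lmap.peak_channel)
    if not paths:
        return None
    return fit_velocity(g, paths, lmap)
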