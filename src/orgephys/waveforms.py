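"""Extracellular AP waveform clustering.

Peak-channel waveforms (at 20 kHz, high-pass filtered at 150 Hz, normalized to
trough amplitude -1) are cut to 61-point snippets spanning 1 ms before to 2 ms
after the trough. A fuzzy nearest-neighbor graph over the snippets (the
high-dimensional graph produced by the UMAP embedding step) is partitioned by
Louvain community detection; the modularity Q of that partition on the same
graph quantifies cluster separation. A resolution sweep (typically 20 seeded
iterations per resolution) characterizes how cluster count and Q trade off;
1.5 is the headline resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "WaveformSnippet",
    "prepare_snippets",
    "ClusterSolution",
    "neighbor_graph",
    "cluster_waveforms",
    "resolution_sweep",
]

SNIPPET_FS = 20_000.0
SNIPPET_PRE = 20  # samples before the trough (1 ms at 20 kHz)
SNIPPET_POST = 40  # samples after the trough (2 ms)
SNIPPET_LEN = SNIPPET_PRE + SNIPPET_POST + 1  # 61 points
HIGHPASS_HZ = 150.0


@dataclass(frozen=True)
class WaveformSnippet:
    """61-point, high-pass-filtered, trough-normalized peak-channel waveform."""

    unit_id: int
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size != SNIPPET_LEN:
            raise ValueError(f"snippet must have {SNIPPET_LEN} points, got {v.size}")
        object.__setattr__(self, "values", v)


def _highpass(wf: np.ndarray, fs: float) -> np.ndarray:
    sos = signal.butter(2, HIGHPASS_HZ, btype="highpass", fs=fs, output="sos")
    padlen = min(wf.shape[-1] - 1, 3 * (2 * 2 + 1))
    return signal.sosfiltfilt(sos, wf, padlen=padlen)


def prepare_snippets(efs) -> list[WaveformSnippet]:
    """Filtered, trough-aligned, normalized snippets from EF peak channels.

    EFs below 20 kHz are resampled up first. Units whose filtered peak-channel
    waveform has a zero trough (flat signal) are excluded with a warning.
    """
    out = []
    for ef in efs:
        wf = ef.peak_waveform()
        fs = float(ef.fs)
        if fs < SNIPPET_FS:
            up = int(round(SNIPPET_FS / fs))
            wf = signal.resample_poly(wf, up, 1)
            fs = fs * up
        filt = _highpass(wf, fs)
        trough = int(np.argmin(filt))
        if filt[trough] >= 0:
            warnings.warn(f"unit {ef.unit_id}: flat waveform (no trough); excluded")
            continue
        # center on the trough; edge-replicate when the window overruns
        padded = np.pad(filt, (SNIPPET_PRE, SNIPPET_POST), mode="edge")
        snip = padded[trough : trough + SNIPPET_LEN]
        snip = snip / np.abs(snip.min())
        out.append(WaveformSnippet(unit_id=int(ef.unit_id), values=snip))
    return out


@dataclass
class ClusterSolution:
    unit_ids: np.ndarray
    labels: np.ndarray
    resolution: float
    Q: float

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


def neighbor_graph(snippets, n_neighbors: int = 15, min_dist: float = 0.1, seed: int = 0):
    """Fuzzy nearest-neighbor graph over snippets from the embedding step.

    Returns a networkx Graph whose weighted edges are the fuzzy simplicial-set
    affinities computed by UMAP; clustering consumes this graph, not the 2-D
    coordinates.
    """
    import umap  # deferred: numba compilation is slow at import time

    X = np.vstack([s.values for s in snippets])
    n_neighbors = min(n_neighbors, X.shape[0] - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed, transform_seed=seed
        )
        reducer.fit(X)
    adj = reducer.graph_.tocoo()
    g = nx.Graph()
    g.add_nodes_from(range(X.shape[0]))
    for i, j, w in zip(adj.row, adj.col, adj.data):
        if i < j and w > 0:
            g.add_edge(int(i), int(j), weight=float(w))
    return g


def _louvain(g: nx.Graph, resolution: float, seed: int) -> tuple[np.ndarray, float]:
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    labels = np.empty(g.number_of_nodes(), dtype=int)
    for c, members in enumerate(sorted(comms, key=lambda s: -len(s))):
        for n in members:
            labels[n] = c
    q = float(nx.community.modularity(g, comms, weight="weight"))
    return labels, q


def cluster_waveforms(
    snippets,
    resolution: float = 1.5,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    graph: nx.Graph | None = None,
) -> ClusterSolution:
    """Louvain clustering of the snippet neighbor graph at one resolution.

    ``Q`` is the (resolution-1) modularity of the returned partition on the
    very graph that was clustered. Pass ``graph`` to reuse a prebuilt neighbor
    graph. Identical (degenerate) snippets collapse to a single cluster.
    """
    if len(snippets) < 2:
        raise ValueError("need at least 2 snippets")
    X = np.vstack([s.values for s in snippets])
    unit_ids = np.array([s.unit_id for s in snippets])
    if np.allclose(X, X[0]):
        return ClusterSolution(unit_ids, np.zeros(len(snippets), dtype=int), resolution, 0.0)
    if graph is None:
        graph = neighbor_graph(snippets, n_neighbors, min_dist, seed)
    labels, q = _louvain(graph, resolution, seed)
    return ClusterSolution(unit_ids=unit_ids, labels=labels, resolution=resolution, Q=q)


def resolution_sweep(
    snippets,
    resolutions,
    n_iter: int = 20,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """Repeated clustering per resolution with distinct seeds.

    The neighbor graph is built once; each of the ``n_iter`` iterations reruns
    Louvain with seed ``seed + iteration``. Returns a table with columns
    ``resolution, mean_Q, mean_n_clusters``.
    """
    g = neighbor_graph(snippets, n_neighbors, min_dist, seed)
    rows = []
    for res in resolutions:
        qs, ns = [], []
        for it in range(n_iter):
            labels, q = _louvain(g, res, seed + it)
            qs.append(q)
            ns.append(np.unique(labels).size)
        rows.append({"resolution": res, "mean_Q": np.mean(qs), "mean_n_clusters": np.mean(ns)})
    return pd.DataFrame(rows)
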