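import math
from collections import Counter

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgephys.connectivity import (
    DEFAULT_SCALES_MS,
    binarize,
    ccg,
    ccg_network,
    ccg_significance,
    modularity,
    scale_sweep,
    source_window_ms,
    te_network,
    te_significance,
    transfer_entropy,
)
from orgephys.spiketable import SpikeTable
from orgephys.synth import GroundTruth, generate_spike_network


def ccg_oracle(source, target, bin_ms=1.0, lag_ms=50.0):
    """Nested-loop coincidence count."""
    n_side = int(round(lag_ms / bin_ms))
    counts = np.zeros(2 * n_side + 1, dtype=int)
    for s in source:
        for t in target:
            d_ms = (t - s) * 1e3
            k = int(math.floor(d_ms / bin_ms + 0.5))
            if -n_side <= k <= n_side:
                counts[k + n_side] += 1
    return counts


def te_oracle(src, tgt, k=1, l=4, d=1):
    """Exhaustive joint-histogram plug-in TE."""
    t0 = max(k, d + l - 1)
    n = len(src)
    cnt = Counter()
    for t in range(t0, n):
        jh = tuple(tgt[t - k : t])
        ih = tuple(src[t - d - l + 1 : t - d + 1])
        cnt[(tgt[t], jh, ih)] += 1
    N = n - t0
    c_jh_ih, c_jt_jh, c_jh = Counter(), Counter(), Counter()
    for (jt, jh, ih), c in cnt.items():
        c_jh_ih[(jh, ih)] += c
        c_jt_jh[(jt, jh)] += c
        c_jh[jh] += c
    te = 0.0
    for (jt, jh, ih), c in cnt.items():
        te += c / N * math.log2(c * c_jh[jh] / (c_jh_ih[(jh, ih)] * c_jt_jh[(jt, jh)]))
    return te


class TestCCG:
    def test_identical_trains_all_mass_at_zero(self):
        t = np.array([1.0, 2.0, 5.0])
        lags, counts = ccg(t, t)
        assert counts[lags == 0.0] == 3
        assert counts.sum() == 3  # spacings exceed the +/-50 ms window

    def test_shifted_train_single_bin(self):
        t = np.array([1.0, 2.0, 5.0])
        lags, counts = ccg(t, t + 2e-3)
        assert counts.sum() == 3
        assert (lags[counts > 0] == [2.0]).all()

    def test_counts_match_nested_loop_oracle(self):
        rng = np.random.default_rng(0)
        a = np.sort(rng.uniform(0, 10, 150))
        b = np.sort(rng.uniform(0, 10, 120))
        lags, counts = ccg(a, b)
        np.testing.assert_array_equal(counts, ccg_oracle(a, b))

    def test_symmetry(self):
        """ccg(a,b) at +t equals ccg(b,a) at -t: count conservation."""
        rng = np.random.default_rng(1)
        a = np.sort(rng.uniform(0, 5, 80))
        b = np.sort(rng.uniform(0, 5, 90))
        _, ab = ccg(a, b)
        _, ba = ccg(b, a)
        np.testing.assert_array_equal(ab, ba[::-1])

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            ccg(np.array([]), np.array([1.0]))


def poisson_sf_oracle(k, lam):
    """P(X >= k) by direct pmf summation (independent of scipy.stats)."""
    p, total = math.exp(-lam), 0.0
    for i in range(k):
        total += p
        p *= lam / (i + 1)
    return 1.0 - total


class TestCCGSignificance:
    def test_flat_ccg_not_significant(self):
        lags = np.arange(-50.0, 51.0)
        counts = np.full(101, 5)
        res = ccg_significance(lags, counts)
        assert not res.significant

    def test_injected_coupling_significant_exact_poisson(self):
        """Peak at +2 ms over a flat baseline: p matches a direct Poisson-tail
        summation and clears alpha = 0.001."""
        lags = np.arange(-50.0, 51.0)
        counts = np.full(101, 4)
        counts[lags == 2.0] = 30
        res = ccg_significance(lags, counts)
        lam = res.baseline[lags == 2.0][0]
        assert res.p == pytest.approx(poisson_sf_oracle(30, lam), rel=1e-9)
        assert res.significant and res.peak_lag_ms == 2.0

    def test_sub_ms_peak_excluded(self):
        lags = np.arange(-50.0, 51.0)
        counts = np.full(101, 4)
        counts[lags == 0.0] = 500
        res = ccg_significance(lags, counts)
        assert res.excluded_short_latency and not res.significant


class TestTransferEntropy:
    def test_matches_exhaustive_oracle_on_toys(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            src = rng.integers(0, 2, 64).astype(np.uint8)
            tgt = rng.integers(0, 2, 64).astype(np.uint8)
            assert abs(
                transfer_entropy(src, tgt) - te_oracle(src.tolist(), tgt.tolist())
            ) <= 1e-12

    def test_deterministic_copy_one_bit(self):
        """j_t = i_{t-1} with p(1) = 0.5: TE = 1 bit up to plug-in bias."""
        rng = np.random.default_rng(3)
        src = rng.integers(0, 2, 100_000).astype(np.uint8)
        tgt = np.zeros_like(src)
        tgt[1:] = src[:-1]
        assert transfer_entropy(src, tgt) == pytest.approx(1.0, abs=1e-3)

    def test_independent_sequences_near_zero(self):
        rng = np.random.default_rng(4)
        src = (rng.random(100_000) < 0.02).astype(np.uint8)
        tgt = (rng.random(100_000) < 0.02).astype(np.uint8)
        assert transfer_entropy(src, tgt) < 5e-4  # plug-in bias bound at n=1e5

    def test_target_independent_of_everything_zero(self):
        src = np.tile([1, 0, 1, 1, 0, 0], 50).astype(np.uint8)
        tgt = np.zeros(300, dtype=np.uint8)
        assert transfer_entropy(src, tgt) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        src = (rng.random(500) < 0.2).astype(np.uint8)
        tgt = (rng.random(500) < 0.2).astype(np.uint8)
        assert transfer_entropy(src, tgt) >= 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            transfer_entropy(np.zeros(4, np.uint8), np.zeros(4, np.uint8))


class TestTESignificance:
    def test_coupled_pair_strongly_significant(self):
        """Copy with p = 0.8 at 1-bin delay: z far above the 3.09 cutoff."""
        rng = np.random.default_rng(5)
        src = (rng.random(60_000) < 0.05).astype(np.uint8)
        tgt = np.zeros_like(src)
        copied = (rng.random(60_000) < 0.8) & (src == 1)
        tgt[1:] = copied[:-1]
        res = te_significance(src, tgt, bin_ms=1.0, seed=0)
        assert res.significant and res.z > 10

    def test_independent_pair_not_significant(self):
        rng = np.random.default_rng(6)
        src = (rng.random(50_000) < 0.02).astype(np.uint8)
        tgt = (rng.random(50_000) < 0.02).astype(np.uint8)
        res = te_significance(src, tgt, bin_ms=1.0, seed=1)
        assert not res.significant

    def test_degenerate_surrogates_flagged(self):
        src = np.zeros(1000, dtype=np.uint8)
        src[[100, 500]] = 1
        tgt = np.zeros(1000, dtype=np.uint8)
        res = te_significance(src, tgt, bin_ms=1.0, seed=2)
        assert res.degenerate and not res.significant


class TestNetworks:
    def test_source_window_scale6(self):
        """Bin 35 ms with 4 source-history bins at delay 1: window 35-140 ms."""
        assert source_window_ms(35.0, 4, 1) == (35.0, 140.0)

    def test_scale_ladder_anchors(self):
        assert DEFAULT_SCALES_MS[1] == 1.6
        assert DEFAULT_SCALES_MS[5] == 35.0
        assert DEFAULT_SCALES_MS[0] == 1.0 and DEFAULT_SCALES_MS[-1] == 160.0

    def test_single_unit_empty_graph(self):
        st_ = SpikeTable(np.zeros(20, int), np.linspace(0.1, 9.9, 20))
        graphs = scale_sweep(st_, 10.0, scales_ms=(1.0, 16.0), n_surrogates=5)
        assert all(g.density == 0.0 for g in graphs)

    def test_planted_ccg_edges_recovered(self):
        """Injected 2-4 ms connections at p = 0.4 over 1 Hz background:
        CCG inference recalls >= 0.8 of them at precision >= 0.9."""
        edges = [(i, i + 10, 2.0 + (i % 3), 0.4) for i in range(10)]
        gt = GroundTruth(unit_rate=1.0, burst_rate=0.0, syn_graph=edges, seed=9)
        spikes = generate_spike_network(gt, 20, 600.0)
        graph = ccg_network(spikes)
        found = set(graph.significant_edges())
        true = {(a, b) for a, b, _, _ in edges}
        recall = len(found & true) / len(true)
        precision = len(found & true) / max(len(found), 1)
        assert recall >= 0.8
        assert precision >= 0.9

    def test_te_finds_planted_edge(self):
        gt = GroundTruth(
            unit_rate=2.0, burst_rate=0.0, syn_graph=[(0, 1, 2.0, 0.6)], seed=12
        )
        spikes = generate_spike_network(gt, 2, 600.0)
        graph = te_network(spikes, 600.0, bin_ms=1.6, seed=3)
        assert (0, 1) in graph.significant_edges()
        assert graph.source_window_ms == (1.6, 6.4)


class TestModularity:
    def test_single_clique_zero(self):
        g = nx.complete_graph(6)
        assert modularity(g) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_5cliques_exactly_half(self):
        """Closed form for two equal disjoint modules: Q = 0.5."""
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        assert modularity(g) == pytest.approx(0.5, abs=1e-12)

    def test_matches_direct_formula(self):
        """Louvain's Q equals the double-loop modularity formula evaluated on
        the partition it returns."""
        g = nx.planted_partition_graph(3, 8, 0.9, 0.05, seed=1)
        comms = nx.community.louvain_communities(g, seed=0)
        label = {}
        for c, members in enumerate(comms):
            for n in members:
                label[n] = c
        m = g.number_of_edges()
        A = nx.to_numpy_array(g)
        k = A.sum(axis=1)
        nodes = list(g.nodes())
        q = 0.0
        for i, u in enumerate(nodes):
            for j, v in enumerate(nodes):
                if label[u] == label[v]:
                    q += A[i, j] - k[i] * k[j] / (2 * m)
        q /= 2 * m
        assert nx.community.modularity(g, comms) == pytest.approx(q, abs=1e-12)

    def test_planted_modules_recovered(self):
        """4 planted modules: Louvain partition purity >= 95%."""
        g = nx.planted_partition_graph(4, 12, 0.9, 0.02, seed=3)
        comms = nx.community.louvain_communities(g, seed=0)
        correct = 0
        for comm in comms:
            truth = [n // 12 for n in comm]
            correct += max(np.bincount(truth))
        assert correct / 48 >= 0.95

    def test_empty_graph_undefined(self):
        g = nx.empty_graph(5)
        assert modularity(g) is None


class TestEdgeDistances:
    def test_distances_reported_per_significant_edge(self):
        from orgephys.connectivity import edge_distances_um
        from orgephys.footprint import ElectricalFootprint

        def ef(uid, x):
            wf = np.zeros((1, 30), dtype=np.float32)
            wf[0, 15] = -50.0
            return ElectricalFootprint(uid, wf, [[x, 0.0]], 20_000.0)

        gt = GroundTruth(
            unit_rate=2.0, burst_rate=0.0, syn_graph=[(0, 1, 2.0, 0.6)], seed=12
        )
        spikes = generate_spike_network(gt, 2, 600.0)
        graph = ccg_network(spikes)
        dists = edge_distances_um(graph, [ef(0, 0.0), ef(1, 300.0)])
        assert dists == [(0, 1, 300.0)]

    def test_missing_footprint_rejected(self):
        from orgephys.connectivity import edge_distances_um
        from orgephys.footprint import ElectricalFootprint

        gt = GroundTruth(
            unit_rate=2.0, burst_rate=0.0, syn_graph=[(0, 1, 2.0, 0.6)], seed=12
        )
        spikes = generate_spike_network(gt, 2, 600.0)
        graph = ccg_network(spikes)
        wf = np.zeros((1, 30), dtype=np.float32)
        wf[0, 15] = -50.0
        only0 = [ElectricalFootprint(0, wf, [[0.0, 0.0]], 20_000.0)]
        with pytest.raises(ValueError, match="unit 1"):
            edge_distances_um(graph, only0)
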