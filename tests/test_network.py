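import numpy as np
import pytest

from spikedyn.io import Raster
from spikedyn.network import (
    Candidate,
    NetworkConfig,
    TEEdge,
    TENetwork,
    bivariate_te,
    infer_network,
    infer_parents_greedy,
    information_regression,
    network_metrics,
    prefilter_parents,
)
from spikedyn.synthetic import (
    CouplingEdge,
    GeneratorConfig,
    gen_coupled_raster,
    gen_xor_triad,
)

FAST = NetworkConfig(n_surrogates=100, seed=0)


def _raster(rows, ids=None):
    rows = np.asarray(rows, dtype=np.uint8)
    return Raster(rows, 1.0, ids or [f"n{i}" for i in range(len(rows))])


class TestBivariateTE:
    def test_noiseless_copy_is_one_bit(self, rng):
        x = rng.integers(0, 2, 50_000).astype(np.uint8)
        y = np.roll(x, 1)
        te, p = bivariate_te(x, y, 1)
        assert te == pytest.approx(1.0, abs=0.01)
        assert p < 1e-10

    def test_noisy_copy_matches_closed_form(self, rng):
        flip = 0.1
        x = rng.integers(0, 2, 100_000).astype(np.uint8)
        y = np.roll(x, 1) ^ (rng.random(100_000) < flip)
        te, _ = bivariate_te(x, y.astype(np.uint8), 1)
        h2 = -(flip * np.log2(flip) + (1 - flip) * np.log2(1 - flip))
        assert te == pytest.approx(1 - h2, abs=0.01)

    def test_constant_series_degenerate(self):
        te, p = bivariate_te(np.zeros(1000, np.uint8), np.zeros(1000, np.uint8), 1)
        assert te == 0.0
        assert p == 1.0


class TestPrefilter:
    def test_strong_edge_recovered_at_true_lag(self):
        cfg = GeneratorConfig(
            n_neurons=3,
            duration_ms=100_000,
            base_rate=15.0,
            coupling_graph=[CouplingEdge(0, 2, lag_bins=4, transmission=0.9)],
            seed=10,
        )
        ras, _ = gen_coupled_raster(cfg)
        cands = prefilter_parents(ras, "n2", FAST)
        assert [c.source for c in cands] == ["n0"]
        assert cands[0].lag_bins == 4

    def test_constant_target_empty(self):
        ras = _raster([np.random.default_rng(0).integers(0, 2, 5000),
                       np.zeros(5000, dtype=np.uint8)])
        assert prefilter_parents(ras, "n1", FAST) == []

    def test_independent_sources_rarely_pass(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            ras = _raster((r.random((5, 20_000)) < 0.02).astype(np.uint8))
            hits += len(prefilter_parents(ras, "n0", FAST))
        # 80 source screenings at source-level alpha 0.05
        assert hits <= 10


class TestGreedySelection:
    def test_redundant_copies_yield_single_parent(self, rng):
        parent = (rng.random(80_000) < 0.05).astype(np.uint8)
        noise = rng.random(80_000)
        target = np.zeros(80_000, dtype=np.uint8)
        target[1:] = parent[:-1] & (noise[1:] < 0.7)
        ras = _raster([parent, parent.copy(), target])
        cands = [Candidate("n0", 1, 0.1, 0.0), Candidate("n1", 1, 0.1, 0.0)]
        edges = infer_parents_greedy(ras, "n2", cands, FAST, rng=rng)
        assert len(edges) == 1

    def test_xor_parents_both_selected(self, rng):
        # Sparse parents make each marginally informative, so the prefilter
        # passes them; the greedy stage must keep both.
        ras = gen_xor_triad(100_000, parent_p=0.1, noise_p=0.05, seed=11)
        cands = prefilter_parents(ras, "target", FAST)
        assert {c.source for c in cands} >= {"parent1", "parent2"}
        edges = infer_parents_greedy(ras, "target", cands, FAST, rng=rng)
        assert {e.source for e in edges} == {"parent1", "parent2"}

    def test_no_candidates_no_edges(self, rng):
        ras = _raster((rng.random((2, 5000)) < 0.05).astype(np.uint8))
        assert infer_parents_greedy(ras, "n0", [], FAST, rng=rng) == []

    def test_inference_is_deterministic(self):
        cfg = GeneratorConfig(
            n_neurons=4,
            duration_ms=30_000,
            base_rate=15.0,
            coupling_graph=[CouplingEdge(0, 2, 1, 0.8), CouplingEdge(1, 3, 2, 0.8)],
            seed=12,
        )
        ras, _ = gen_coupled_raster(cfg)
        a = infer_network(ras, FAST).edge_table()
        b = infer_network(ras, FAST).edge_table()
        assert a.equals(b)


def _directed_clustering_oracle(edges, nodes):
    """Brute-force directed clustering (all triangle motifs) over node triples."""
    a = {(u, v) for u, v in edges}
    out = {}
    for i in nodes:
        nbrs = {j for j in nodes if j != i and ((i, j) in a or (j, i) in a)}
        d_tot = sum(((i, j) in a) + ((j, i) in a) for j in nodes if j != i)
        d_bi = sum(((i, j) in a and (j, i) in a) for j in nodes if j != i)
        T = 0
        for j in nbrs:
            for h in nbrs:
                if j == h:
                    continue
                T += (((i, j) in a) + ((j, i) in a)) * (
                    ((i, h) in a) + ((h, i) in a)
                ) * (((j, h) in a) + ((h, j) in a))
        denom = 2 * (d_tot * (d_tot - 1) - 2 * d_bi)
        out[i] = T / denom if denom > 0 else 0.0
    return out


def _net(edge_pairs, nodes):
    edges = [TEEdge(u, v, 1, 0.1, 0.1, 0.01) for u, v in edge_pairs]
    return TENetwork(list(nodes), edges)


class TestNetworkMetrics:
    def test_closed_triangle_clusters_fully(self):
        # A directed 3-cycle realizes 2 of the 4 possible triangle motifs per
        # node (0.5 under the directed convention); its undirected projection
        # and the fully reciprocal triangle both cluster at 1.
        cycle = _net([("a", "b"), ("b", "c"), ("c", "a")], "abc")
        assert (network_metrics(cycle)["clustering"] == 0.5).all()
        assert (network_metrics(cycle, "undirected")["clustering"] == 1.0).all()
        recip = _net(
            [(u, v) for u in "abc" for v in "abc" if u != v], "abc"
        )
        assert (network_metrics(recip)["clustering"] == 1.0).all()

    def test_star_hub_has_zero_clustering(self):
        net = _net([("h", x) for x in "abcde"], "habcde")
        m = network_metrics(net).set_index("neuron_id")
        assert m.loc["h", "clustering"] == 0.0
        assert m.loc["h", "in_degree"] == 0

    def test_six_node_digraph_matches_brute_force(self, rng):
        nodes = list("abcdef")
        pairs = [
            (u, v)
            for u in nodes
            for v in nodes
            if u != v and rng.random() < 0.35
        ]
        m = network_metrics(_net(pairs, nodes)).set_index("neuron_id")
        oracle = _directed_clustering_oracle(pairs, nodes)
        for n in nodes:
            assert m.loc[n, "clustering"] == pytest.approx(oracle[n], abs=1e-12)

    def test_inflow_and_degree_sum_edges(self):
        net = _net([("a", "c"), ("b", "c")], "abc")
        m = network_metrics(net).set_index("neuron_id")
        assert m.loc["c", "in_degree"] == 2
        assert m.loc["c", "total_inflow"] == pytest.approx(0.2)


class TestInformationRegression:
    def test_additivity_exact_on_random_data(self, rng):
        for _ in range(10):
            target = (rng.random(800) < 0.3).astype(np.uint8)
            parents = [
                ((rng.random(800) < 0.2).astype(np.uint8), int(rng.integers(1, 5)))
                for _ in range(2)
            ]
            reg = information_regression(target, [1, 2], parents)
            assert reg["H"] == pytest.approx(
                reg["ais"] + reg["mte"] + reg["h_mu"], abs=1e-12
            )
            assert reg["ais"] >= -1e-12
            assert reg["mte"] >= -1e-12

    def test_pure_copy_channel_decomposition(self, rng):
        x = rng.integers(0, 2, 20_000).astype(np.uint8)
        y = np.roll(x, 2)
        reg = information_regression(y, [1], [(x, 2)])
        assert reg["H"] == pytest.approx(1.0, abs=0.01)
        assert reg["mte"] == pytest.approx(1.0, abs=0.01)
        assert reg["h_mu"] == pytest.approx(0.0, abs=1e-9)


class TestCircularShiftProperty:
    def test_rotation_preserves_circular_autocorrelation(self, rng):
        y = (rng.random(4096) < 0.1).astype(float)
        shifted = np.roll(y, 1234)
        f = np.fft.rfft(y - y.mean())
        g = np.fft.rfft(shifted - shifted.mean())
        np.testing.assert_allclose(
            np.fft.irfft(f * np.conj(f)), np.fft.irfft(g * np.conj(g)), atol=1e-8
        )
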