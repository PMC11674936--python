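import numpy as np
import pytest
from scipy.special import xlogy

from spikedyn.io import Raster
from spikedyn.network import TEEdge, TENetwork
from spikedyn.pid import (
    broja_decomposition,
    broja_unique,
    enumerate_triads,
    estimate_triad_pmf,
    pid_table,
)


def gate_pmf(f):
    p = np.zeros((2, 2, 2))
    for y1 in (0, 1):
        for y2 in (0, 1):
            p[y1, y2, f(y1, y2)] = 0.25
    return p


def broja_grid_oracle(pmf, n_grid=401):
    """Exhaustive dense-grid search over the marginal-preserving polytope.

    Independent of the package solver: enumerates the feasible 2-D box and
    evaluates I_Q(X; Y1 | Y2) directly on every grid distribution.
    """
    pmf = pmf / pmf.sum()
    a = pmf.sum(axis=1)  # P(y1, x)
    b = pmf.sum(axis=0)  # P(y2, x)
    s = pmf.sum(axis=(0, 1))
    lo = np.maximum(0.0, a[1] + b[1] - s)
    hi = np.minimum(a[1], b[1])
    best = np.inf
    for q0 in np.linspace(lo[0], hi[0], n_grid if hi[0] > lo[0] else 1):
        for q1 in np.linspace(lo[1], hi[1], n_grid if hi[1] > lo[1] else 1):
            q = np.empty((2, 2, 2))
            q[1, 1] = [q0, q1]
            q[1, 0] = a[1] - [q0, q1]
            q[0, 1] = b[1] - [q0, q1]
            q[0, 0] = s - a[1] - b[1] + [q0, q1]
            q = np.clip(q, 0, None)
            # I(X; Y1 | Y2) = H(X|Y2) - H(X|Y1,Y2)
            pxy2 = q.sum(axis=0)
            py2 = pxy2.sum(axis=1)
            h_x_y2 = (-xlogy(pxy2, pxy2).sum() + xlogy(py2, py2).sum()) / np.log(2)
            pyy = q.sum(axis=2)
            h_x_yy = (-xlogy(q, q).sum() + xlogy(pyy, pyy).sum()) / np.log(2)
            best = min(best, h_x_y2 - h_x_yy)
    return max(0.0, best)


class TestBrojaGates:
    def test_copy_gate_is_pure_unique(self):
        r = broja_decomposition(gate_pmf(lambda a, b: a))
        assert r.unique1 == pytest.approx(1.0, abs=1e-6)
        assert r.redundancy == pytest.approx(0.0, abs=1e-6)
        assert r.unique2 == pytest.approx(0.0, abs=1e-6)
        assert r.synergy == pytest.approx(0.0, abs=1e-6)

    def test_xor_gate_is_pure_synergy(self):
        r = broja_decomposition(gate_pmf(lambda a, b: a ^ b))
        assert r.synergy == pytest.approx(1.0, abs=1e-6)
        assert max(r.redundancy, r.unique1, r.unique2) < 1e-6

    def test_and_gate_matches_grid_oracle(self):
        pmf = gate_pmf(lambda a, b: a & b)
        r = broja_decomposition(pmf)
        assert r.synergy == pytest.approx(0.5, abs=1e-3)
        assert r.redundancy == pytest.approx(0.311278, abs=1e-3)
        assert r.unique1 == pytest.approx(broja_grid_oracle(pmf), abs=1e-3)


@pytest.fixture(scope="module")
def random_pmfs():
    rng = np.random.default_rng(77)
    return [rng.dirichlet(np.ones(8)).reshape(2, 2, 2) for _ in range(50)]


class TestBrojaRandomPmfs:

    def test_agrees_with_grid_oracle(self, random_pmfs):
        for pmf in random_pmfs:
            assert broja_unique(pmf) == pytest.approx(
                broja_grid_oracle(pmf, 201), abs=1e-3
            )

    def test_nonnegativity_and_marginal_identities(self, random_pmfs):
        for pmf in random_pmfs:
            r = broja_decomposition(pmf)
            assert min(r.atoms().values()) >= -1e-6
            i1 = _mi2(pmf.sum(axis=1))
            i2 = _mi2(pmf.sum(axis=0))
            ij = _mi2(pmf.reshape(4, 2))
            assert r.redundancy + r.unique1 == pytest.approx(i1, abs=1e-6)
            assert r.redundancy + r.unique2 == pytest.approx(i2, abs=1e-6)
            assert sum(r.atoms().values()) == pytest.approx(ij, abs=1e-6)

    def test_relabel_invariance(self, random_pmfs):
        # Flipping 0<->1 on any variable maps the polytope onto itself.
        for pmf in random_pmfs[:10]:
            base = broja_decomposition(pmf)
            for axis in range(3):
                flipped = broja_decomposition(np.flip(pmf, axis=axis))
                assert flipped.synergy == pytest.approx(base.synergy, abs=1e-6)
                assert flipped.redundancy == pytest.approx(base.redundancy, abs=1e-6)


def _mi2(joint):
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p * np.log2(p / (px * py))
    return float(np.where(p > 0, t, 0.0).sum())


class TestTriadPmf:
    def test_hand_built_raster_matches_hand_count(self):
        y1 = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 1], dtype=np.uint8)
        y2 = np.array([0, 1, 1, 0, 0, 1, 0, 0, 1, 0, 1, 1], dtype=np.uint8)
        x = np.array([0, 0, 1, 1, 1, 0, 0, 1, 0, 1, 1, 0], dtype=np.uint8)
        ras = Raster(np.stack([y1, y2, x]), 1.0, ["a", "b", "t"])
        triad = estimate_triad_pmf(ras, "a", 1, "b", 2, "t", min_overlap=5)
        # Hand alignment at t0 = 2: (y1[t-1], y2[t-2], x[t]) for t = 2..11.
        counts = np.zeros((2, 2, 2))
        for t in range(2, 12):
            counts[y1[t - 1], y2[t - 2], x[t]] += 1
        np.testing.assert_allclose(triad.pmf, counts / counts.sum(), atol=1e-12)

    def test_deterministic_xor_concentrates_on_consistent_outcomes(self, rng):
        n = 4000
        y1 = rng.integers(0, 2, n).astype(np.uint8)
        y2 = rng.integers(0, 2, n).astype(np.uint8)
        x = np.zeros(n, dtype=np.uint8)
        x[1:] = y1[:-1] ^ y2[:-1]
        ras = Raster(np.stack([y1, y2, x]), 1.0, ["a", "b", "t"])
        triad = estimate_triad_pmf(ras, "a", 1, "b", 1, "t")
        for y1v in (0, 1):
            for y2v in (0, 1):
                assert triad.pmf[y1v, y2v, 1 - (y1v ^ y2v)] == 0.0
                assert triad.pmf[y1v, y2v, y1v ^ y2v] == pytest.approx(0.25, abs=0.03)

    def test_independent_neurons_product_pmf(self, rng):
        n = 60_000
        mat = (rng.random((3, n)) < 0.3).astype(np.uint8)
        ras = Raster(mat, 1.0, ["a", "b", "t"])
        triad = estimate_triad_pmf(ras, "a", 1, "b", 1, "t")
        marg = [triad.pmf.sum(axis=tuple(j for j in range(3) if j != i)) for i in range(3)]
        product = np.einsum("i,j,k->ijk", *marg)
        np.testing.assert_allclose(triad.pmf, product, atol=0.01)

    def test_short_overlap_raises(self):
        ras = Raster(np.zeros((3, 50), dtype=np.uint8), 1.0, ["a", "b", "t"])
        with pytest.raises(ValueError, match="overlap"):
            estimate_triad_pmf(ras, "a", 1, "b", 1, "t")


class TestEnumerateTriads:
    def _network(self, parent_map):
        edges = [
            TEEdge(src, tgt, 1, 0.1, 0.1, 0.01)
            for tgt, srcs in parent_map.items()
            for src in srcs
        ]
        nodes = sorted({n for t, s in parent_map.items() for n in [t, *s]})
        return TENetwork(nodes, edges)

    def test_four_parents_give_six_motifs(self):
        net = self._network({"t": ["a", "b", "c", "d"]})
        assert len(enumerate_triads(net)) == 6

    def test_low_in_degree_gives_none(self):
        net = self._network({"t": ["a"], "u": []})
        assert enumerate_triads(net) == []

    def test_count_matches_binomial_oracle(self, rng):
        import math

        parent_map = {
            f"t{i}": [f"s{j}" for j in range(int(rng.integers(0, 6)))]
            for i in range(8)
        }
        net = self._network(parent_map)
        expected = sum(math.comb(len(s), 2) for s in parent_map.values())
        assert len(enumerate_triads(net)) == expected


class TestPidTable:
    def test_xor_network_triad_is_synergistic(self, rng):
        n = 50_000
        y1 = rng.integers(0, 2, n).astype(np.uint8)
        y2 = rng.integers(0, 2, n).astype(np.uint8)
        x = np.zeros(n, dtype=np.uint8)
        x[1:] = y1[:-1] ^ y2[:-1]
        ras = Raster(np.stack([y1, y2, x]), 1.0, ["a", "b", "t"])
        net = TENetwork(
            ["a", "b", "t"],
            [TEEdge("a", "t", 1, 0.5, 0.5, 0.01), TEEdge("b", "t", 1, 0.5, 0.5, 0.01)],
        )
        table = pid_table(ras, net)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["synergy"] == pytest.approx(1.0, abs=0.01)
        assert row["syn_normalized"] == pytest.approx(1.0, abs=0.01)
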