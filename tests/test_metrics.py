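"""Graph metrics against independent brute-force oracles and known spectra."""

import itertools

import numpy as np
import pytest

from remnantnet.metrics import (
    clustering_coefficient,
    eigenvector_centrality,
    metric_shift,
    modularity,
    modularity_q,
    path_length,
    regional_shift,
    spectral_radius,
    synchronizability,
    weighted_degree,
)
from remnantnet.network import WeightedNetwork
from conftest import random_symmetric


def net(w):
    return WeightedNetwork(np.asarray(w, float))


def complete_net(n, w=1.0):
    m = np.full((n, n), w)
    np.fill_diagonal(m, 0.0)
    return net(m)


# ---------------------------------------------------------------- oracles
def clustering_oracle(w):
    """Exhaustive (j, h) triangle enumeration with max-weight scaling."""
    ww = w / w.max()
    n = len(w)
    out = np.zeros(n)
    for i in range(n):
        b = np.count_nonzero(w[i])
        if b < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    acc += (ww[i, j] * ww[i, h] * ww[j, h]) ** (1 / 3)
        out[i] = acc / (b * (b - 1))
    return out


def floyd_warshall_oracle(w):
    n = len(w)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    off = d[~np.eye(n, dtype=bool)]
    return off[np.isfinite(off)].mean()


def q_oracle(w, c, gamma=1.0):
    """Direct double-sum evaluation of the modularity formula."""
    k = w.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    for i in range(len(w)):
        for j in range(len(w)):
            if c[i] == c[j]:
                q += w[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def partitions(collection):
    """All set partitions (Bell-number enumeration)."""
    if len(collection) == 1:
        yield [collection]
        return
    first = collection[0]
    for smaller in partitions(collection[1:]):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
        yield [[first]] + smaller


# ----------------------------------------------------------------- tests
class TestWeightedDegree:
    def test_triangle_and_isolated(self):
        w = np.zeros((4, 4))
        w[np.ix_([0, 1, 2], [0, 1, 2])] = 1 - np.eye(3)
        k = weighted_degree(net(w))
        np.testing.assert_allclose(k, [2, 2, 2, 0])

    def test_row_sum_oracle(self, small_net):
        np.testing.assert_allclose(
            weighted_degree(small_net),
            [small_net.weights[i].sum() for i in range(8)],
            atol=1e-14,
        )

    def test_monotone_under_edge_removal(self, small_net):
        w = small_net.weights.copy()
        w[0, 1] = w[1, 0] = 0.0
        assert np.all(weighted_degree(net(w)) <= weighted_degree(small_net) + 1e-15)


class TestClustering:
    def test_complete_graph_is_one(self):
        np.testing.assert_allclose(clustering_coefficient(complete_net(5)), 1.0)

    def test_path_graph_triangle_free(self):
        w = np.zeros((4, 4))
        for i in range(3):
            w[i, i + 1] = w[i + 1, i] = 1.0
        np.testing.assert_allclose(clustering_coefficient(net(w)), 0.0)

    def test_exhaustive_triangle_oracle(self, rng):
        g = random_symmetric(6, rng)
        np.testing.assert_allclose(
            clustering_coefficient(g), clustering_oracle(g.weights), atol=1e-12
        )


class TestEigenvectorCentrality:
    def test_ring_is_uniform(self):
        n = 6
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
        np.testing.assert_allclose(
            eigenvector_centrality(net(w)), 1 / np.sqrt(n), atol=1e-10
        )

    def test_star_center_leaf_ratio(self):
        # K_{1,4}: dominant eigenvector has center/leaf ratio sqrt(4) = 2
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        ec = eigenvector_centrality(net(w))
        assert ec[0] / ec[1] == pytest.approx(2.0, abs=1e-10)

    def test_dense_eigensolver_oracle(self, rng):
        g = random_symmetric(6, rng)
        vals, vecs = np.linalg.eig(g.weights)
        v = np.abs(vecs[:, np.argmax(vals.real)].real)
        np.testing.assert_allclose(
            eigenvector_centrality(g), v / np.linalg.norm(v), atol=1e-10
        )

    def test_unit_norm_and_nonnegative(self, small_net):
        ec = eigenvector_centrality(small_net)
        assert np.linalg.norm(ec) == pytest.approx(1.0, abs=1e-12)
        assert np.all(ec >= 0)


class TestModularity:
    def test_two_cliques_closed_form(self):
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i, j in itertools.combinations(block, 2):
                w[i, j] = w[j, i] = 1.0
        q, c = modularity(net(w), seed=0, n_restarts=10)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len(set(c[:4])) == 1 and len(set(c[4:])) == 1 and c[0] != c[7]

    def test_q_evaluation_matches_double_sum(self, small_net, rng):
        c = rng.integers(0, 3, 8)
        assert modularity_q(small_net, c) == pytest.approx(
            q_oracle(small_net.weights, c), abs=1e-12
        )

    def test_planted_blocks_exhaustive_search(self, rng):
        n = 8
        w = rng.uniform(0.0, 0.05, (n, n))
        w[:4, :4] += 0.9
        w[4:, 4:] += 0.9
        w = np.triu(w, 1)
        w = w + w.T
        g = net(w)
        q, c = modularity(g, seed=1, n_restarts=20)
        best_q = max(
            modularity_q(g, _labels(p, n)) for p in partitions(list(range(n)))
        )
        assert q == pytest.approx(best_q, abs=1e-10)
        assert len(set(c[:4])) == 1 and len(set(c[4:])) == 1 and c[0] != c[7]

    def test_singleton_partition_nonpositive(self, small_net):
        assert modularity_q(small_net, np.arange(8)) <= 0


def _labels(partition, n):
    lab = np.empty(n, dtype=int)
    for k, block in enumerate(partition):
        lab[block] = k
    return lab


class TestPathLength:
    def test_unit_path_hand_enumeration(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        # ordered-pair distances: 1,1,1,1,2,2 -> mean 4/3
        assert path_length(net(w)) == pytest.approx(4 / 3)

    def test_doubling_weights_halves_length(self, small_net):
        L1 = path_length(small_net)
        L2 = path_length(
            WeightedNetwork(2 * small_net.weights, kind="SI")
        )
        assert L2 == pytest.approx(L1 / 2, rel=1e-12)

    def test_floyd_warshall_oracle(self, rng):
        g = random_symmetric(7, rng)
        assert path_length(g) == pytest.approx(
            floyd_warshall_oracle(g.weights), abs=1e-12
        )

    def test_disconnected_pairs_excluded_with_warning(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        with pytest.warns(UserWarning, match="unreachable"):
            assert path_length(net(w)) == pytest.approx(1.0)


class TestSpectralRadius:
    def test_two_node(self):
        w = np.array([[0.0, 0.7], [0.7, 0.0]])
        assert spectral_radius(net(w)) == pytest.approx(0.7)

    def test_complete_graph(self):
        assert spectral_radius(complete_net(6)) == pytest.approx(5.0)

    def test_dense_eigensolver_oracle(self, rng):
        g = random_symmetric(6, rng, positive=False)
        assert spectral_radius(g) == pytest.approx(
            max(abs(np.linalg.eigvals(g.weights))), abs=1e-10
        )


class TestSynchronizability:
    def test_complete_graph_is_one(self):
        assert synchronizability(complete_net(5)) == pytest.approx(1.0)

    def test_four_cycle(self):
        w = np.zeros((4, 4))
        for i in range(4):
            w[i, (i + 1) % 4] = w[(i + 1) % 4, i] = 1.0
        assert synchronizability(net(w)) == pytest.approx(0.5)

    def test_laplacian_oracle(self, small_net):
        L = np.diag(small_net.weights.sum(1)) - small_net.weights
        vals = np.sort(np.linalg.eigvalsh(L))
        assert synchronizability(small_net) == pytest.approx(
            vals[1] / vals[-1], abs=1e-12
        )

    def test_disconnected_errors(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(ValueError, match="components"):
            synchronizability(net(w))


class TestShifts:
    def test_scalar_examples(self):
        assert metric_shift(2.0, 2.0) == 0.0
        assert metric_shift(2.0, 1.0) == -50.0
        with pytest.raises(ValueError):
            metric_shift(0.0, 1.0)

    def test_regional_elementwise(self):
        np.testing.assert_allclose(
            regional_shift([2.0, 4.0], [1.0, 4.0]), [-50.0, 0.0]
        )

    def test_zero_baseline_region_flagged(self):
        with pytest.warns(UserWarning, match="zero baseline"):
            out = regional_shift([0.0, 2.0], [1.0, 3.0])
        assert np.isnan(out[0]) and out[1] == 50.0


@pytest.mark.parametrize(
    "fn",
    [
        weighted_degree,
        clustering_coefficient,
        eigenvector_centrality,
        path_length,
        spectral_radius,
        synchronizability,
    ],
)
def test_permutation_invariance(fn, rng):
    g = random_symmetric(7, rng)
    perm = rng.permutation(7)
    gp = WeightedNetwork(g.weights[np.ix_(perm, perm)])
    a, b = fn(g), fn(gp)
    if np.ndim(a):
        np.testing.assert_allclose(np.asarray(a)[perm], b, atol=1e-9)
    else:
        assert a == pytest.approx(b, abs=1e-9)
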