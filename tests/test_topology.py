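"""Hub-topology metrics against brute-force reference implementations."""

import itertools

import numpy as np
import pytest

from msnbiotype.topology import (
    consensus_partition,
    degree_centrality,
    nodal_efficiency,
    participation_coefficient,
    threshold_network,
)
from msnbiotype.synthetic import fibonacci_sphere


def random_weighted_graph(rng, n, density=0.6):
    a = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    w = rng.uniform(0.05, 1.0, len(iu[0])) * (rng.random(len(iu[0])) < density)
    a[iu] = w
    return a + a.T


def brute_degree(adj):
    return np.array([sum(adj[i, j] for j in range(len(adj)) if j != i) for i in range(len(adj))])


def brute_efficiency(adj):
    """Floyd-Warshall all-pairs shortest paths on lengths 1/w."""
    n = len(adj)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j in itertools.product(range(n), range(n)):
        if i != j and adj[i, j] > 0:
            d[i, j] = 1.0 / adj[i, j]
    for k, i, j in itertools.product(range(n), range(n), range(n)):
        if d[i, k] + d[k, j] < d[i, j]:
            d[i, j] = d[i, k] + d[k, j]
    out = np.zeros(n)
    for i in range(n):
        inv = [1.0 / d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j]) and d[i, j] > 0]
        out[i] = sum(inv) / (n - 1)
    return out


def brute_participation(adj, part):
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        k_i = sum(adj[i, j] for j in range(n) if j != i)
        if k_i == 0:
            continue
        acc = 0.0
        for s in set(part):
            k_is = sum(adj[i, j] for j in range(n) if j != i and part[j] == s)
            acc += (k_is / k_i) ** 2
        out[i] = 1.0 - acc
    return out


class TestThreshold:
    def test_sparsity_one_keeps_everything(self):
        a = random_weighted_graph(np.random.default_rng(0), 6, density=1.0)
        assert np.allclose(threshold_network(a, 1.0), a)

    def test_keeps_the_three_largest_of_six(self):
        a = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        a[iu] = [0.9, 0.1, 0.8, 0.2, 0.7, 0.3]
        a += a.T
        t = threshold_network(a, 0.5)
        kept = t[iu]
        assert np.count_nonzero(kept) == 3
        assert set(kept[kept > 0]) == {0.9, 0.8, 0.7}

    def test_idempotent(self):
        a = random_weighted_graph(np.random.default_rng(1), 8)
        once = threshold_network(a, 0.4)
        assert np.array_equal(threshold_network(once, 0.4), once)

    def test_tie_break_lexicographic(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        a[0, 2] = a[2, 0] = 0.5
        a[1, 2] = a[2, 1] = 0.5
        t = threshold_network(a, 1 / 3)
        assert t[0, 1] == 0.5 and t[0, 2] == 0.0 and t[1, 2] == 0.0

    def test_invalid_sparsity(self):
        with pytest.raises(ValueError):
            threshold_network(np.eye(3), 0.0)


class TestMetrics:
    def test_degree_hand_example(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        a[0, 2] = a[2, 0] = 0.3
        assert degree_centrality(a)[0] == pytest.approx(0.8)

    def test_empty_graph_all_zero(self):
        assert np.all(degree_centrality(np.zeros((5, 5))) == 0)
        assert np.all(nodal_efficiency(np.zeros((5, 5))) == 0)

    def test_path_graph_efficiency(self):
        # A-B-C unit weights: E(A) = (1 + 1/2)/2 = 0.75
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        e = nodal_efficiency(a)
        assert e[0] == pytest.approx(0.75)
        assert e[1] == pytest.approx(1.0)

    def test_complete_graph_efficiency_is_one(self):
        a = np.ones((6, 6)) - np.eye(6)
        assert np.allclose(nodal_efficiency(a), 1.0)

    def test_participation_all_within_module(self):
        a = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        assert np.allclose(participation_coefficient(a, np.zeros(3, dtype=int)), 0.0)

    def test_participation_even_split(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        a[0, 2] = a[2, 0] = 0.5
        pc = participation_coefficient(a, np.array([0, 0, 1]))
        assert pc[0] == pytest.approx(0.5)

    def test_isolated_node_zero_by_convention(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        assert participation_coefficient(a, np.array([0, 1, 2]))[2] == 0.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        adj = random_weighted_graph(rng, n)
        part = rng.integers(0, 3, n)
        assert np.allclose(degree_centrality(adj), brute_degree(adj), atol=1e-10)
        assert np.allclose(nodal_efficiency(adj), brute_efficiency(adj), atol=1e-10)
        assert np.allclose(
            participation_coefficient(adj, part), brute_participation(adj, part), atol=1e-10
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(99)
        adj = random_weighted_graph(rng, 9)
        part = rng.integers(0, 3, 9)
        perm = rng.permutation(9)
        adj_p = adj[np.ix_(perm, perm)]
        part_p = part[perm]
        assert np.allclose(degree_centrality(adj_p), degree_centrality(adj)[perm])
        assert np.allclose(nodal_efficiency(adj_p), nodal_efficiency(adj)[perm])
        assert np.allclose(
            participation_coefficient(adj_p, part_p),
            participation_coefficient(adj, part)[perm],
        )

    def test_weakening_a_node_never_increases_degree_or_efficiency(self):
        rng = np.random.default_rng(7)
        adj = random_weighted_graph(rng, 8, density=1.0)
        weakened = adj.copy()
        weakened[3, :] *= 0.5
        weakened[:, 3] *= 0.5
        assert degree_centrality(weakened)[3] <= degree_centrality(adj)[3]
        assert nodal_efficiency(weakened)[3] <= nodal_efficiency(adj)[3] + 1e-12


class TestConsensusPartition:
    def test_two_cliques(self):
        a = np.zeros((8, 8))
        a[:4, :4] = 1.0
        a[4:, 4:] = 1.0
        np.fill_diagonal(a, 0)
        labels = consensus_partition([a], seed=0)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        true = np.repeat(np.arange(4), 10)
        a = np.where(true[:, None] == true[None, :], 0.9, 0.05) * rng.uniform(
            0.7, 1.3, (40, 40)
        )
        a = np.triu(a, 1)
        a += a.T
        labels = consensus_partition([a], seed=1)
        assert adjusted_rand_score(true, labels) >= 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        graphs = [random_weighted_graph(rng, 20) for _ in range(3)]
        l1 = consensus_partition(graphs, seed=5)
        l2 = consensus_partition(graphs, seed=5)
        assert np.array_equal(l1, l2)

    def test_matches_generator_modules(self, processed_cohort):
        from sklearn.metrics import adjusted_rand_score

        part = processed_cohort["partition"]
        true = processed_cohort["geometry"].true_module
        assert adjusted_rand_score(true, part) >= 0.9
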