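"""Thresholding, binary graph metrics, rewired nulls, AUC summaries."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import random_symmetric
from hofcnet.graphmetrics import (
    ThresholdedGraph,
    auc_over_sparsity,
    global_metrics,
    nodal_metrics,
    rewired_nulls,
    small_world,
    threshold_by_sparsity,
)


def graph_from_edges(n, edges):
    adj = np.zeros((n, n))
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1.0
    return ThresholdedGraph(adjacency=adj, weights=adj.copy(),
                            sparsity=1.0, achieved_sparsity=1.0)


def brute_force_distances(adj):
    """All-pairs BFS by explicit frontier expansion."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    for s in range(n):
        d[s, s] = 0
        frontier = [s]
        level = 0
        while frontier:
            level += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if d[s, v] == np.inf:
                        d[s, v] = level
                        nxt.append(v)
            frontier = nxt
    return d


def brute_force_betweenness(adj):
    """Exhaustive shortest-path enumeration over all simple paths."""
    n = adj.shape[0]
    g = nx.from_numpy_array(adj)
    d = brute_force_distances(adj)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(d[s, t]):
            continue
        geodesics = [p for p in nx.all_simple_paths(g, s, t, cutoff=int(d[s, t]))
                     if len(p) - 1 == d[s, t]]
        for path in geodesics:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(geodesics)
    return bc


class TestThresholdBySparsity:
    def test_edge_count_on_90_node_matrix(self, rng):
        m = random_symmetric(rng, 90, scale=0.3) + 0.5  # mostly positive
        np.fill_diagonal(m, 0.0)
        g = threshold_by_sparsity(m, 0.10)
        assert g.n_edges == 400  # floor(0.10 * 4005)

    def test_full_sparsity_keeps_complete_graph(self, rng):
        m = np.abs(random_symmetric(rng, 10)) + 0.01
        np.fill_diagonal(m, 0.0)
        g = threshold_by_sparsity(m, 1.0)
        assert g.n_edges == 45

    def test_strongest_edges_retained_with_weights(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 0.9
        m[2, 3] = m[3, 2] = 0.8
        m[0, 2] = m[2, 0] = 0.1
        g = threshold_by_sparsity(m, 2 / 6)
        assert g.n_edges == 2
        assert g.adjacency[0, 1] == 1 and g.adjacency[2, 3] == 1
        assert g.weights[0, 1] == pytest.approx(0.9)

    def test_tied_values_resolved_deterministically(self):
        m = np.zeros((6, 6))
        for i, j in itertools.combinations(range(6), 2):
            m[i, j] = m[j, i] = 0.5  # every edge tied
        sets = set()
        for _ in range(5):
            g = threshold_by_sparsity(m, 0.4)
            iu, ju = np.nonzero(np.triu(g.adjacency))
            sets.add(tuple(zip(iu.tolist(), ju.tolist())))
        assert len(sets) == 1

    def test_negative_edges_excluded_by_default(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = -0.9
        m[2, 3] = m[3, 2] = 0.2
        g = threshold_by_sparsity(m, 1.0)
        assert g.n_edges == 1
        g_abs = threshold_by_sparsity(m, 2 / 6, edge_sign="absolute")
        assert g_abs.adjacency[0, 1] == 1


class TestGlobalMetrics:
    def test_complete_graph_k10(self):
        g = graph_from_edges(10, itertools.combinations(range(10), 2))
        gm = global_metrics(g)
        assert gm.cp == pytest.approx(1.0)
        assert gm.lp == pytest.approx(1.0)
        assert gm.eglob == pytest.approx(1.0)
        assert gm.eloc == pytest.approx(1.0)

    def test_ring_lattice_closed_form_clustering(self):
        # Watts-Strogatz ring, N=20, k=4: Cp = 3(k-2) / (4(k-1)) = 0.5
        n, k = 20, 4
        edges = [(i, (i + d) % n) for i in range(n) for d in range(1, k // 2 + 1)]
        gm = global_metrics(graph_from_edges(n, edges))
        assert gm.cp == pytest.approx(0.5)

    def test_path_graph_by_pair_enumeration(self):
        # distances {1, 1, 2}: Lp = 4/3, Eglob = (1 + 1 + 1/2)/3 = 5/6
        gm = global_metrics(graph_from_edges(3, [(0, 1), (1, 2)]))
        assert gm.lp == pytest.approx(4 / 3)
        assert gm.eglob == pytest.approx(5 / 6)

    def test_matches_networkx_on_random_graphs(self, rng):
        for _ in range(5):
            m = random_symmetric(rng, 12) + 0.2
            np.fill_diagonal(m, 0.0)
            g = threshold_by_sparsity(m, 0.35)
            gx = g.to_networkx()
            if g.n_edges == 0 or not nx.is_connected(gx):
                continue
            gm = global_metrics(g)
            assert gm.cp == pytest.approx(nx.average_clustering(gx), abs=1e-12)
            assert gm.lp == pytest.approx(
                nx.average_shortest_path_length(gx), abs=1e-12)
            assert gm.eglob == pytest.approx(
                nx.global_efficiency(gx), abs=1e-12)

    def test_empty_graph_rejected(self):
        g = graph_from_edges(5, [])
        with pytest.raises(ValueError, match="no edges"):
            global_metrics(g)


class TestNodalMetrics:
    def test_star_graph(self):
        g = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        nm = nodal_metrics(g)
        assert nm.dc[0] == 4
        assert nm.bc[0] == pytest.approx(6.0)  # C(4, 2) leaf pairs
        assert nm.ne[0] == pytest.approx(1.0)
        assert np.allclose(nm.bc[1:], 0.0)

    def test_path_middle_node_betweenness(self):
        nm = nodal_metrics(graph_from_edges(3, [(0, 1), (1, 2)]))
        assert nm.bc[1] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_8_node_graphs(self, rng):
        for _ in range(4):
            m = random_symmetric(rng, 8) + 0.15
            np.fill_diagonal(m, 0.0)
            g = threshold_by_sparsity(m, 0.4)
            if g.n_edges == 0:
                continue
            nm = nodal_metrics(g)
            assert np.allclose(nm.bc, brute_force_betweenness(g.adjacency),
                               atol=1e-12)
            d = brute_force_distances(g.adjacency)
            with np.errstate(divide="ignore"):
                inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
            assert np.allclose(nm.ne, inv.sum(axis=1) / 7, atol=1e-12)

    def test_degree_sum_twice_edge_count(self, rng):
        m = random_symmetric(rng, 30) + 0.1
        np.fill_diagonal(m, 0.0)
        for s in (0.1, 0.2, 0.3):
            g = threshold_by_sparsity(m, s)
            assert nodal_metrics(g).dc.sum() == 2 * g.n_edges

    def test_complete_graph_zero_betweenness(self):
        g = graph_from_edges(6, itertools.combinations(range(6), 2))
        assert np.allclose(nodal_metrics(g).bc, 0.0)


class TestRewiredNulls:
    def test_degree_sequence_preserved(self, rng):
        m = random_symmetric(rng, 20) + 0.2
        np.fill_diagonal(m, 0.0)
        g = threshold_by_sparsity(m, 0.25)
        for null in rewired_nulls(g, 3, seed=4):
            assert np.array_equal(np.sort(null.degrees()), np.sort(g.degrees()))

    def test_rewiring_destroys_lattice_triangles(self):
        n, k = 30, 4
        edges = [(i, (i + d) % n) for i in range(n) for d in range(1, k // 2 + 1)]
        g = graph_from_edges(n, edges)
        cp = global_metrics(g).cp
        null_cp = np.mean([global_metrics(h).cp
                           for h in rewired_nulls(g, 5, seed=0)])
        assert null_cp < cp

    def test_same_seed_identical_ensemble(self, rng):
        m = random_symmetric(rng, 15) + 0.2
        np.fill_diagonal(m, 0.0)
        g = threshold_by_sparsity(m, 0.3)
        a = rewired_nulls(g, 3, seed=9)
        b = rewired_nulls(g, 3, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.adjacency, y.adjacency)


class TestSmallWorld:
    def test_self_null_normalizes_to_one(self):
        g = graph_from_edges(6, [(0, 1), (1, 2), (2, 0), (2, 3), (3, 4),
                                 (4, 5), (5, 3)])
        sw = small_world(g, [g])
        assert sw.gamma == pytest.approx(1.0)
        assert sw.lambda_ == pytest.approx(1.0)
        assert sw.sigma == pytest.approx(1.0)

    def test_sigma_lambda_gamma_identity(self, rng):
        m = random_symmetric(rng, 25) + 0.2
        np.fill_diagonal(m, 0.0)
        g = threshold_by_sparsity(m, 0.25)
        sw = small_world(g, rewired_nulls(g, 4, seed=2))
        assert sw.sigma * sw.lambda_ == pytest.approx(sw.gamma, abs=1e-12)


class TestAucOverSparsity:
    def test_constant_metric_rectangle(self):
        grid = np.round(np.arange(6, 41) / 100, 2)
        assert auc_over_sparsity(np.full(grid.size, 2.0), grid) == \
            pytest.approx(0.34 * 2.0)

    def test_identity_metric_integrates_quadratically(self):
        grid = np.round(np.arange(6, 41) / 100, 2)
        assert auc_over_sparsity(grid, grid) == pytest.approx(0.0782)

    def test_missing_value_names_sparsity(self):
        grid = np.array([0.06, 0.07, 0.08])
        with pytest.raises(ValueError, match="0.07"):
            auc_over_sparsity([1.0, np.nan, 2.0], grid)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            auc_over_sparsity([1.0], [0.1])


def test_eglob_monotone_in_sparsity(rng):
    m = random_symmetric(rng, 40) + 0.1
    np.fill_diagonal(m, 0.0)
    eglobs = [global_metrics(threshold_by_sparsity(m, s)).eglob
              for s in (0.1, 0.2, 0.3, 0.4)]
    assert np.all(np.diff(eglobs) >= -1e-12)
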