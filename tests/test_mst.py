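import numpy as np
import pytest

from oracles import (
    min_spanning_tree_total,
    random_symmetric_weights,
    tree_bc_bruteforce,
    tree_diameter_bruteforce,
)
from plinet.graph import WeightedGraph
from plinet.mst import (
    SpanningTree,
    betweenness,
    kappa,
    kruskal_mst,
    leaf_metrics,
    tree_diameter,
    tree_hierarchy,
    tree_metrics,
)


def _graph_from_dist(dist):
    w = np.zeros_like(dist)
    nz = dist > 0
    w[nz] = 1.0 / dist[nz]
    np.fill_diagonal(w, 0.0)
    labels = tuple(chr(ord("A") + i) for i in range(dist.shape[0]))
    return WeightedGraph(labels=labels, weights=np.clip(w, 0, 1))


def _path(n):
    return SpanningTree(labels=tuple(str(i) for i in range(n)),
                        edges=[(i, i + 1, 1.0) for i in range(n - 1)])


def _star(n):
    return SpanningTree(labels=tuple(str(i) for i in range(n)),
                        edges=[(0, i, 1.0) for i in range(1, n)])


def _random_tree(rng, n):
    edges = []
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edges.append((u, v, 1.0))
    return SpanningTree(labels=tuple(str(i) for i in range(n)), edges=edges)


class TestKruskal:
    def test_four_node_example_total(self):
        # distances AB:1 AC:2 AD:5 BC:2 BD:3 CD:4 -> optimal total 6
        d = np.array([
            [0, 1, 2, 5],
            [1, 0, 2, 3],
            [2, 2, 0, 4],
            [5, 3, 4, 0]], dtype=float)
        t = kruskal_mst(_graph_from_dist(d))
        assert t.total_distance == pytest.approx(6.0)
        assert t.total_distance == pytest.approx(min_spanning_tree_total(d))

    def test_chain_graph_forced_topology(self):
        n = 5
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 0.9
        g = WeightedGraph(labels=tuple("ABCDE"), weights=w)
        t = kruskal_mst(g)
        assert sorted((i, j) for i, j, _ in t.edges) == [(i, i + 1) for i in range(4)]

    def test_uniform_distance_total_is_tie_invariant(self):
        w = np.full((6, 6), 0.5)
        np.fill_diagonal(w, 0.0)
        t = kruskal_mst(WeightedGraph(labels=tuple("ABCDEF"), weights=w))
        assert t.total_distance == pytest.approx(5 * 2.0)

    def test_minimality_against_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 8))
            w = random_symmetric_weights(rng, n, 0.1, 1.0)
            g = WeightedGraph(labels=tuple(str(i) for i in range(n)), weights=w)
            t = kruskal_mst(g)
            assert t.total_distance == pytest.approx(
                min_spanning_tree_total(g.distances))

    def test_deterministic_under_ties(self):
        w = np.full((5, 5), 0.4)
        np.fill_diagonal(w, 0.0)
        g = WeightedGraph(labels=tuple("ABCDE"), weights=w)
        assert kruskal_mst(g).edges == kruskal_mst(g).edges


class TestTreeMetrics:
    def test_path_and_star_diameter(self):
        assert tree_diameter(_path(5)) == 4
        assert tree_diameter(_star(5)) == 2

    def test_diameter_matches_bruteforce(self, rng):
        for _ in range(10):
            t = _random_tree(rng, int(rng.integers(4, 10)))
            edges = [(i, j) for i, j, _ in t.edges]
            assert tree_diameter(t) == tree_diameter_bruteforce(edges, t.n_nodes)

    def test_leaf_metrics_path_star(self):
        assert leaf_metrics(_path(6)) == (2, 2 / 6)
        assert leaf_metrics(_star(6)) == (5, 5 / 6)

    def test_bc_path3_and_star(self):
        _, norm = betweenness(_path(3))
        np.testing.assert_allclose(norm, [0, 1, 0])
        _, norm = betweenness(_star(6))
        assert norm[0] == pytest.approx(1.0)
        assert np.all(norm[1:] == 0)

    def test_bc_matches_path_enumeration(self, rng):
        for _ in range(10):
            t = _random_tree(rng, int(rng.integers(4, 11)))
            raw, _ = betweenness(t)
            edges = [(i, j) for i, j, _ in t.edges]
            np.testing.assert_allclose(raw, tree_bc_bruteforce(edges, t.n_nodes))

    def test_bc_sum_equals_interior_crossings(self, rng):
        """Sum of raw BC equals total path length minus one per pair."""
        from oracles import tree_paths
        t = _random_tree(rng, 9)
        raw, _ = betweenness(t)
        paths = tree_paths([(i, j) for i, j, _ in t.edges], 9)
        expected = sum(len(paths[(s, u)]) - 2 for s in range(9) for u in range(s + 1, 9))
        assert raw.sum() == pytest.approx(expected)

    @pytest.mark.parametrize("m", list(range(3, 26)))
    def test_star_hierarchy_is_half(self, m):
        assert tree_hierarchy(_star(m)) == pytest.approx(0.5)

    def test_path_hierarchy_vanishes_with_size(self):
        th = [tree_hierarchy(_path(m)) for m in (4, 8, 16, 32)]
        assert all(a > b for a, b in zip(th, th[1:]))
        assert th[-1] < 0.1

    def test_path_equals_star_at_three_nodes(self):
        assert tree_hierarchy(_path(3)) == pytest.approx(tree_hierarchy(_star(3)))

    def test_kappa_hand_values(self):
        assert kappa(_path(5)) == pytest.approx(14 / 8)
        assert kappa(_star(5)) == pytest.approx(2.5)

    def test_star_vs_path_ordering(self):
        """A star is a more integrated backbone than a path at equal size."""
        ms, mp = tree_metrics(_star(10)), tree_metrics(_path(10))
        assert ms.leaf_fraction > mp.leaf_fraction
        assert ms.kappa > mp.kappa
        assert ms.diameter < mp.diameter

    def test_tree_invariants_on_random_graphs(self, rng):
        import networkx as nx
        for _ in range(10):
            n = int(rng.integers(3, 12))
            w = random_symmetric_weights(rng, n, 0.05, 1.0)
            t = kruskal_mst(WeightedGraph(labels=tuple(str(i) for i in range(n)),
                                          weights=w))
            G = nx.Graph((i, j) for i, j, _ in t.edges)
            G.add_nodes_from(range(n))
            assert len(t.edges) == n - 1
            assert nx.is_connected(G)
            assert nx.is_tree(G)
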