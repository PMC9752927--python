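"""Minimum-spanning-tree backbone of the PLI network.

The MST on 1/PLI edge distances (Kruskal's algorithm) extracts the
strongest-connection backbone without any threshold choice.  Tree
summaries:

* diameter D — largest hop distance between two tree nodes,
* leaf number / fraction LN, LF — nodes of degree 1,
* betweenness centrality BC — fraction of all tree paths through a node,
* tree hierarchy TH = LN / (2 m BC_max) — integration/overload trade-off,
* kappa — degree-distribution broadness, <k^2> / <k>.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .graph import WeightedGraph


@dataclass
class SpanningTree:
    labels: tuple[str, ...]
    edges: list[tuple[int, int, float]]  # (i, j, source distance), i < j

    def __post_init__(self) -> None:
        m = len(self.labels)
        if len(self.edges) != m - 1:
            raise ValueError(f"a spanning tree on {m} nodes needs {m - 1} edges")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    @property
    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j, _ in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    @property
    def total_distance(self) -> float:
        return float(sum(d for _, _, d in self.edges))


@dataclass
class TreeMetrics:
    diameter: int
    diameter_norm: float
    leaf_number: int
    leaf_fraction: float
    bc: np.ndarray            # normalized, in [0, 1]
    bc_raw: np.ndarray        # unnormalized pair counts
    bc_max: float
    tree_hierarchy: float
    kappa: float
    m_edges: int
    band: str = ""
    node_set: str = "whole"
    subject_id: str = ""


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def kruskal_mst(g: WeightedGraph) -> SpanningTree:
    """Kruskal MST on the 1/PLI distance matrix.

    Ties are broken by the lexicographic label pair so the tree is
    deterministic across runs and platforms.
    """
    m = g.n_nodes
    if m < 2:
        raise ValueError("MST needs at least 2 nodes")
    dist = g.distances
    candidates = sorted(
        ((dist[i, j], g.labels[i], g.labels[j], i, j)
         for i in range(m) for j in range(i + 1, m)),
        key=lambda e: (e[0], e[1], e[2]),
    )
    uf = _UnionFind(m)
    edges: list[tuple[int, int, float]] = []
    for d, _, _, i, j in candidates:
        if uf.union(i, j):
            edges.append((i, j, float(d)))
            if len(edges) == m - 1:
                break
    return SpanningTree(labels=g.labels, edges=edges)


def _bfs_hops(adj: list[list[int]], start: int) -> np.ndarray:
    hops = np.full(len(adj), -1, dtype=int)
    hops[start] = 0
    q = deque([start])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if hops[v] < 0:
                hops[v] = hops[u] + 1
                q.append(v)
    return hops


def tree_diameter(t: SpanningTree) -> int:
    """Largest hop distance between any two tree nodes (two-pass BFS)."""
    adj = t.adjacency
    far = int(np.argmax(_bfs_hops(adj, 0)))
    return int(_bfs_hops(adj, far).max())


def leaf_metrics(t: SpanningTree) -> tuple[int, float]:
    """Leaf number (degree-1 nodes) and leaf fraction LN / M."""
    ln = int((t.degrees == 1).sum())
    return ln, ln / t.n_nodes


def betweenness(t: SpanningTree) -> tuple[np.ndarray, np.ndarray]:
    """Raw and normalized betweenness centrality of every tree node.

    On a tree every pair (s, t) has exactly one path, so the raw BC of a
    node v is the number of pairs whose path passes through v: removing
    v splits the tree into components of sizes c_1..c_d, and the
    crossing pairs number ((M-1)^2 - sum c_k^2) / 2.  Normalization is
    by (M-1)(M-2)/2, the number of pairs excluding v.
    """
    m = t.n_nodes
    adj = t.adjacency
    raw = np.zeros(m)
    for v in range(m):
        seen = {v}
        comp_sizes = []
        for root in adj[v]:
            if root in seen:
                continue
            size = 0
            q = deque([root])
            seen.add(root)
            while q:
                u = q.popleft()
                size += 1
                for w in adj[u]:
                    if w not in seen:
                        seen.add(w)
                        q.append(w)
            comp_sizes.append(size)
        total = m - 1
        raw[v] = (total**2 - sum(c**2 for c in comp_sizes)) / 2
    denom = (m - 1) * (m - 2) / 2
    norm = raw / denom if denom > 0 else np.zeros(m)
    return raw, norm


def tree_hierarchy(t: SpanningTree) -> float:
    """TH = LN / (2 m BC_max) with m = M - 1 edges and normalized BC_max.

    With this normalization a star of any size has TH = 1/2 exactly,
    while a path's TH tends to 0 as it grows.
    """
    if t.n_nodes < 3:
        raise ValueError("tree hierarchy needs at least 3 nodes")
    ln, _ = leaf_metrics(t)
    _, bc_norm = betweenness(t)
    bc_max = float(bc_norm.max())
    if bc_max <= 0:
        raise ValueError("degenerate tree: BC_max is 0")
    return ln / (2 * len(t.edges) * bc_max)


def kappa(t: SpanningTree) -> float:
    """Degree-distribution broadness <k^2> / <k> over tree node degrees."""
    deg = t.degrees.astype(float)
    return float((deg**2).mean() / deg.mean())


def tree_metrics(t: SpanningTree, band: str = "", node_set: str = "whole",
                 subject_id: str = "") -> TreeMetrics:
    """All MST summary metrics of one tree."""
    d = tree_diameter(t)
    ln, lf = leaf_metrics(t)
    raw, norm = betweenness(t)
    return TreeMetrics(
        diameter=d,
        diameter_norm=d / (t.n_nodes - 1),
        leaf_number=ln,
        leaf_fraction=lf,
        bc=norm,
        bc_raw=raw,
        bc_max=float(norm.max()),
        tree_hierarchy=tree_hierarchy(t) if t.n_nodes >= 3 else float("nan"),
        kappa=kappa(t),
        m_edges=len(t.edges),
        band=band,
        node_set=node_set,
        subject_id=subject_id,
    )
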