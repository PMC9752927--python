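"""Independent brute-force oracles used to validate the fast implementations.

Every function here is written as the most literal possible evaluation
of its definition (double loops, exhaustive enumeration) and shares no
code with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def pli_sign_mean(phases: np.ndarray) -> np.ndarray:
    """Literal sign-mean PLI: double loop over channel pairs and samples."""
    n_ch, n_samp = phases.shape
    out = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(n_ch):
            if i == j:
                continue
            total = 0.0
            for t in range(n_samp):
                d = phases[i, t] - phases[j, t]
                while d <= -np.pi:
                    d += 2 * np.pi
                while d > np.pi:
                    d -= 2 * np.pi
                total += np.sign(d)
            out[i, j] = abs(total / n_samp)
    return out


def floyd_warshall(dist: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the textbook triple loop."""
    n = dist.shape[0]
    sp = dist.astype(float).copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if sp[i, k] + sp[k, j] < sp[i, j]:
                    sp[i, j] = sp[i, k] + sp[k, j]
    return sp


def clustering_triple_loop(w: np.ndarray) -> float:
    """Geometric-mean weighted clustering by explicit triangle enumeration."""
    n = w.shape[0]
    cs = []
    for i in range(n):
        neigh = [j for j in range(n) if j != i and w[i, j] > 0]
        k = len(neigh)
        if k < 2:
            cs.append(0.0)
            continue
        total = 0.0
        for j in neigh:
            for h in neigh:
                if j != h:
                    total += (w[i, j] * w[i, h] * w[j, h]) ** (1 / 3)
        cs.append(total / (k * (k - 1)))
    return float(np.mean(cs))


def all_spanning_trees(n: int):
    """Every labeled spanning tree on n nodes via Pruefer sequences."""
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        edges = []
        seq_list = list(seq)
        leaves = sorted(v for v in range(n) if degree[v] == 1)
        for v in seq_list:
            leaf = leaves.pop(0)
            edges.append((leaf, v))
            degree[v] -= 1
            if degree[v] == 1:
                # insert keeping sorted order
                import bisect
                bisect.insort(leaves, v)
        edges.append((leaves[0], leaves[1]))
        yield edges


def min_spanning_tree_total(dist: np.ndarray) -> float:
    """Minimum total distance over every enumerated spanning tree."""
    n = dist.shape[0]
    best = np.inf
    for edges in all_spanning_trees(n):
        total = sum(dist[i, j] for i, j in edges)
        best = min(best, total)
    return float(best)


def tree_paths(edges: list[tuple[int, int]], n: int) -> dict:
    """The unique path between every node pair, by DFS walk."""
    adj = {v: [] for v in range(n)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    paths = {}
    for s in range(n):
        stack = [(s, [s])]
        while stack:
            u, path = stack.pop()
            paths[(s, u)] = path
            for v in adj[u]:
                if v not in path:
                    stack.append((v, path + [v]))
    return paths


def tree_diameter_bruteforce(edges, n) -> int:
    paths = tree_paths(edges, n)
    return max(len(p) - 1 for p in paths.values())


def tree_bc_bruteforce(edges, n) -> np.ndarray:
    """Raw betweenness: count node pairs whose path crosses each node."""
    paths = tree_paths(edges, n)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            for v in paths[(s, t)][1:-1]:
                bc[v] += 1
    return bc


def modularity_double_loop(w: np.ndarray, labels: list[int]) -> float:
    """Literal evaluation of the weighted modularity formula."""
    two_m = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def max_modularity_exhaustive(w: np.ndarray) -> float:
    """Maximum modularity over every set partition of the nodes."""
    n = w.shape[0]
    best = -np.inf
    for groups in set_partitions(list(range(n))):
        labels = [0] * n
        for gi, g in enumerate(groups):
            for v in g:
                labels[v] = gi
        best = max(best, modularity_double_loop(w, labels))
    return best


def participation_double_loop(w: np.ndarray, labels: list[int]) -> np.ndarray:
    """Literal participation coefficient P_i = 1 - sum_s (kappa_is/k_i)^2."""
    n = w.shape[0]
    modules = sorted(set(labels))
    pc = np.zeros(n)
    for i in range(n):
        k_i = sum(w[i, j] for j in range(n))
        total = 0.0
        for s in modules:
            kappa = sum(w[i, j] for j in range(n) if labels[j] == s)
            total += (kappa / k_i) ** 2
        pc[i] = 1 - total
    return pc


def random_symmetric_weights(rng: np.random.Generator, n: int,
                             low: float = 0.02, high: float = 1.0) -> np.ndarray:
    """Random symmetric PLI-like weight matrix with zero diagonal."""
    w = rng.uniform(low, high, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w
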