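"""Weighted classical network metrics on PLI graphs.

Electrodes are the nodes; the PLI between a pair is the edge weight
(an affinity) and its reciprocal 1/PLI the edge distance.  Summaries:

* mean PLI — average functional coupling over all pairs,
* clustering coefficient CC — local segregation (triangle density),
* characteristic path length PL — global integration (mean shortest
  1/PLI distance); lower PL means a more integrated network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

#: Zero-PLI edges are capped at this affinity so distances stay finite;
#: the resulting distance (1e6) never wins a shortest path.
EPS_WEIGHT = 1e-6


@dataclass
class WeightedGraph:
    """Complete weighted graph on electrode labels.

    ``weights`` holds the PLI affinities (symmetric, zero diagonal,
    entries in [0, 1]); ``distances`` the capped reciprocals.
    """

    labels: tuple[str, ...]
    weights: np.ndarray
    node_set: str = "whole"
    eps: float = EPS_WEIGHT

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match labels")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("PLI weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def distances(self) -> np.ndarray:
        d = 1.0 / np.maximum(self.weights, self.eps)
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class WeightedNetworkMetrics:
    mean_pli: float
    cc: float
    pl: float
    band: str = ""
    node_set: str = "whole"
    subject_id: str = ""


def build_graph(cm: ConnectivityMatrix, node_set: list[str] | None = None,
                tag: str | None = None) -> WeightedGraph:
    """Induced subgraph of the PLI matrix on *node_set* (default: all labels)."""
    if node_set is None:
        node_set = list(cm.labels)
        tag = tag or "whole"
    unknown = [l for l in node_set if l not in cm.labels]
    if unknown:
        raise ValueError(f"node set labels not in matrix: {unknown!r}")
    idx = [cm.labels.index(l) for l in node_set]
    w = cm.pli[np.ix_(idx, idx)].copy()
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(labels=tuple(node_set), weights=w, node_set=tag or "custom")


def mean_pli(g: WeightedGraph) -> float:
    """Mean of the upper-triangle PLI weights."""
    if g.n_nodes < 2:
        raise ValueError("mean PLI needs at least 2 nodes")
    iu = np.triu_indices(g.n_nodes, k=1)
    return float(g.weights[iu].mean())


def clustering_coefficient(g: WeightedGraph, norm: str | None = None) -> float:
    """Weighted clustering coefficient (network average).

    Per node the geometric-mean triangle intensity

        C_i = sum_{j,k} (w_ij w_ik w_jk)^(1/3) / (k_i (k_i - 1)),

    averaged over nodes.  PLI weights already live in [0, 1], so with
    ``norm=None`` (default) CC is bounded in [0, 1] and increases with
    any weight; ``norm="max"`` rescales weights by the graph maximum
    first (the Onnela convention for unbounded weights).
    """
    if g.n_nodes < 3:
        raise ValueError("clustering needs at least 3 nodes")
    w = g.weights.copy()
    if norm == "max":
        wmax = w.max()
        if wmax > 0:
            w = w / wmax
    elif norm is not None:
        raise ValueError(f"unknown normalization {norm!r}")
    cube = np.linalg.matrix_power(np.cbrt(w), 3)
    triangles = np.diag(cube)  # 2x the per-node sum over ordered (j, k)
    degree = (w > 0).sum(axis=1)
    denom = degree * (degree - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return float(c.mean())


def characteristic_path_length(g: WeightedGraph) -> float:
    """Mean shortest-path 1/PLI distance over all ordered node pairs."""
    if g.n_nodes < 2:
        raise ValueError("path length needs at least 2 nodes")
    sp = shortest_path(g.distances, method="D", directed=False)
    if not np.all(np.isfinite(sp)):
        raise ValueError("graph is disconnected: infinite pairwise distance")
    iu = np.triu_indices(g.n_nodes, k=1)
    return float(sp[iu].mean())


def network_metrics(cm: ConnectivityMatrix, node_set: list[str] | None = None,
                    tag: str | None = None, cc_norm: str | None = None) -> WeightedNetworkMetrics:
    """Mean PLI, CC and PL of the (sub)network induced by *node_set*."""
    g = build_graph(cm, node_set, tag)
    return WeightedNetworkMetrics(
        mean_pli=mean_pli(g),
        cc=clustering_coefficient(g, norm=cc_norm),
        pl=characteristic_path_length(g),
        band=cm.band,
        node_set=g.node_set,
        subject_id=cm.subject_id,
    )
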