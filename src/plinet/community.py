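"""Community structure of the weighted PLI network.

Modularity of a partition (Newman, weighted):

    Q = 1/(2M) * sum_ij (a_ij - k_i k_j / (2M)) * delta(C_i, C_j)

with a_ij the PLI weight, k_i the node strength, 2M the total weight
counted in both directions and delta = 1 when i and j share a module.
Q = 0 for the trivial single-module partition; larger Q means a
crisper division into modules.

The participation coefficient of node i,

    P_i = 1 - sum_s (kappa_is / k_i)^2,

with kappa_is the strength of i's links into module s, is 0 when all of
the node's weight stays inside its own module and approaches 1 when the
weight spreads evenly over many modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import WeightedGraph


@dataclass
class Partition:
    """Node -> module assignment; module ids are contiguous from 1."""

    assignment: tuple[int, ...]
    q: float = float("nan")

    def __post_init__(self) -> None:
        mods = sorted(set(self.assignment))
        if mods != list(range(1, len(mods) + 1)):
            raise ValueError("module ids must be contiguous from 1")

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment))

    @classmethod
    def from_groups(cls, groups, n_nodes: int, q: float = float("nan")) -> "Partition":
        assignment = [0] * n_nodes
        for module_id, members in enumerate(groups, start=1):
            for node in members:
                assignment[node] = module_id
        if 0 in assignment:
            raise ValueError("every node must be assigned to a module")
        return cls(assignment=tuple(assignment), q=q)


@dataclass
class CommunityMetrics:
    q: float
    pc: np.ndarray
    mean_pc: float
    n_modules: int
    band: str = ""
    node_set: str = "whole"
    subject_id: str = ""


def modularity(g: WeightedGraph, partition: Partition) -> float:
    """Weighted Newman modularity of *partition* on *g*."""
    w = g.weights
    if len(partition.assignment) != g.n_nodes:
        raise ValueError("partition size does not match graph")
    two_m = w.sum()
    if two_m <= 0:
        raise ValueError("graph has zero total weight")
    k = w.sum(axis=1)
    labels = np.asarray(partition.assignment)
    same = labels[:, None] == labels[None, :]
    q = ((w - np.outer(k, k) / two_m) * same).sum() / two_m
    return float(q)


def _set_partitions(items: list[int]):
    """All set partitions of *items* (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def _exhaustive_best(g: WeightedGraph) -> Partition:
    best_q, best_groups = -np.inf, None
    for groups in _set_partitions(list(range(g.n_nodes))):
        p = Partition.from_groups(groups, g.n_nodes)
        q = modularity(g, p)
        if q > best_q:
            best_q, best_groups = q, groups
    return Partition.from_groups(best_groups, g.n_nodes, q=best_q)


def detect_communities(g: WeightedGraph, seed: int = 0, n_restarts: int = 20,
                       exact_max_nodes: int = 8) -> Partition:
    """Partition locally maximizing modularity, deterministic given *seed*.

    Graphs with at most *exact_max_nodes* nodes are solved exactly by
    enumerating every set partition; larger graphs use seeded Louvain
    restarts keeping the best-Q partition.  When no split beats the
    trivial partition, the single module is returned (Q = 0).
    """
    if g.n_nodes <= exact_max_nodes:
        best = _exhaustive_best(g)
    else:
        G = nx.from_numpy_array(g.weights)
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(n_restarts):
            comms = nx.community.louvain_communities(
                G, weight="weight", seed=int(rng.integers(2**31 - 1))
            )
            p = Partition.from_groups([sorted(c) for c in comms], g.n_nodes)
            q = modularity(g, p)
            if best is None or q > best.q:
                best = Partition(assignment=p.assignment, q=q)
    if best.q <= 1e-12:
        return Partition(assignment=(1,) * g.n_nodes, q=0.0)
    return best


def participation_coefficient(g: WeightedGraph, partition: Partition) -> np.ndarray:
    """Per-node participation coefficient; NaN (with a warning) for isolated nodes."""
    w = g.weights
    labels = np.asarray(partition.assignment)
    k = w.sum(axis=1)
    pc = np.empty(g.n_nodes)
    for i in range(g.n_nodes):
        if k[i] == 0:
            warnings.warn(
                f"node {g.labels[i]!r} is isolated; participation coefficient undefined",
                stacklevel=2,
            )
            pc[i] = np.nan
            continue
        total = 0.0
        for s in range(1, partition.n_modules + 1):
            kappa_is = w[i, labels == s].sum()
            total += (kappa_is / k[i]) ** 2
        pc[i] = 1.0 - total
    return pc


def community_metrics(g: WeightedGraph, seed: int = 0, band: str = "",
                      subject_id: str = "") -> CommunityMetrics:
    """Detect modules and summarize Q and participation coefficients."""
    part = detect_communities(g, seed=seed)
    pc = participation_coefficient(g, part)
    return CommunityMetrics(
        q=part.q,
        pc=pc,
        mean_pc=float(np.nanmean(pc)),
        n_modules=part.n_modules,
        band=band,
        node_set=g.node_set,
        subject_id=subject_id,
    )
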