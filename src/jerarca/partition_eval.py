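"""Scoring of nested dendrogram cuts and selection of the optimal partition.

The rooted dendrogram is scanned from the root toward the leaves: opening an
internal node splits its cluster in two, so a tree with n leaves yields n
nested partitions (1, 2, ..., n clusters).  Every partition is scored with
Newman–Girvan modularity Q and with H, the negative decimal logarithm of the
upper-tail cumulative hypergeometric probability of seeing at least the
observed number of intracluster links if the observed links fell at random
among all possible node pairs.  The best partition per index is returned
(ties prefer fewer clusters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .graph_io import Graph
from .iterative import Partition
from .trees import TreeNode

__all__ = [
    "PartitionScore",
    "scan_partitions",
    "modularity_q",
    "hypergeometric_h",
    "log10_hypergeom_tail",
    "best_partitions",
]


@dataclass(frozen=True)
class PartitionScore:
    """A candidate cut of the dendrogram with its evaluation.

    ``h_inputs`` records the quadruple behind H: F (possible node pairs),
    n_obs (observed edges), M (possible intracluster pairs under the
    partition) and p (observed intracluster edges).
    """

    partition: Partition
    num_clusters: int
    Q: float
    H: float
    h_inputs: tuple[int, int, int, int]  # (F, n_obs, M, p)


def _node_depth_order(root: TreeNode) -> list[tuple[TreeNode, float]]:
    """Internal nodes with their root distances, sorted by increasing depth
    (ties keep pre-order position, so parents always precede children)."""
    out: list[tuple[float, int, TreeNode]] = []
    counter = 0

    stack: list[tuple[TreeNode, float]] = [(root, 0.0)]
    order: list[tuple[TreeNode, float, int]] = []
    while stack:
        node, depth = stack.pop()
        if node.is_leaf:
            continue
        idx = counter
        counter += 1
        order.append((node, depth, idx))
        for child, length in reversed(node.children):
            stack.append((child, depth + length))
    out = sorted(((depth, idx, node) for node, depth, idx in order),
                 key=lambda t: (t[0], t[1]))
    return [(node, depth) for depth, idx, node in out]


def scan_partitions(t: TreeNode, g: Graph) -> list[Partition]:
    """Nested partitions generated by opening internal nodes from the root
    down, in order of increasing distance from the root."""
    leaf_set = frozenset(t.leaf_names())
    if leaf_set != frozenset(g.nodes):
        raise ValueError("dendrogram leaves do not match graph nodes")
    partitions: list[Partition] = []
    # frontier maps an open tree node to the leaf labels below it
    leafsets: dict[int, frozenset[str]] = {}

    def collect(node: TreeNode) -> frozenset[str]:
        if id(node) in leafsets:
            return leafsets[id(node)]
        s = (
            frozenset((node.name,))
            if node.is_leaf
            else frozenset().union(*(collect(c) for c, _ in node.children))
        )
        leafsets[id(node)] = s
        return s

    collect(t)
    frontier: list[TreeNode] = [t]
    partitions.append(Partition.from_blocks([leafsets[id(t)]]))
    for node, _depth in _node_depth_order(t):
        pos = frontier.index(node)
        frontier[pos : pos + 1] = [c for c, _ in node.children]
        partitions.append(
            Partition.from_blocks([leafsets[id(f)] for f in frontier])
        )
    return partitions


def modularity_q(g: Graph, p: Partition) -> float:
    """Newman–Girvan modularity: sum over clusters of
    intra-edge fraction minus squared degree fraction."""
    if g.num_edges == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    if p.nodes != frozenset(g.nodes):
        raise ValueError("partition node set does not match the graph")
    labels = p.labels_for(g.nodes)
    e0, e1 = g.edge_index_arrays()
    m = g.num_edges
    nblocks = p.num_clusters
    intra = np.bincount(
        labels[e0], weights=(labels[e0] == labels[e1]).astype(float), minlength=nblocks
    )
    degsum = np.bincount(labels, weights=g.degrees().astype(float), minlength=nblocks)
    return float(np.sum(intra / m - (degsum / (2.0 * m)) ** 2))


def log10_hypergeom_tail(F: int, n_obs: int, M: int, p_intra: int) -> float:
    """log10 of P(X >= p_intra) for X hypergeometric: n_obs draws from F
    slots of which M are marked.  Evaluated as a log-space sum of pmf terms
    so it survives astronomically small tails."""
    if not (0 <= M <= F):
        raise ValueError("need 0 <= M <= F")
    if not (0 <= n_obs <= F):
        raise ValueError("need 0 <= n_obs <= F")
    hi = min(n_obs, M)
    lo = max(p_intra, max(0, n_obs - (F - M)))
    if p_intra > hi:
        raise ValueError("observed intracluster links exceed the possible maximum")
    if lo <= max(0, n_obs - (F - M)):
        return 0.0  # the whole support is in the tail
    x = np.arange(lo, hi + 1, dtype=np.float64)
    log_terms = (
        _log_comb(M, x)
        + _log_comb(F - M, n_obs - x)
        - _log_comb(F, n_obs)
    )
    return float(logsumexp(log_terms)) / np.log(10.0)


def _log_comb(n: float | np.ndarray, k: float | np.ndarray) -> np.ndarray:
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _h_inputs(g: Graph, p: Partition) -> tuple[int, int, int, int]:
    k = g.num_nodes
    F = k * (k - 1) // 2
    n_obs = g.num_edges
    labels = p.labels_for(g.nodes)
    sizes = np.bincount(labels, minlength=p.num_clusters)
    M = int(np.sum(sizes * (sizes - 1) // 2))
    e0, e1 = g.edge_index_arrays()
    p_intra = int(np.sum(labels[e0] == labels[e1]))
    return F, n_obs, M, p_intra


def hypergeometric_h(g: Graph, p: Partition) -> float:
    """H index: −log10 of the probability of observing by chance at least
    the realized number of intracluster links.  Larger is 'more unexpected',
    i.e. a better partition."""
    if p.nodes != frozenset(g.nodes):
        raise ValueError("partition node set does not match the graph")
    F, n_obs, M, p_intra = _h_inputs(g, p)
    if M > F or p_intra > n_obs:
        raise ValueError("inconsistent hypergeometric inputs")
    return -log10_hypergeom_tail(F, n_obs, M, p_intra)


def _score(g: Graph, p: Partition) -> PartitionScore:
    F, n_obs, M, p_intra = _h_inputs(g, p)
    return PartitionScore(
        partition=p,
        num_clusters=p.num_clusters,
        Q=modularity_q(g, p),
        H=-log10_hypergeom_tail(F, n_obs, M, p_intra),
        h_inputs=(F, n_obs, M, p_intra),
    )


def best_partitions(t: TreeNode, g: Graph) -> tuple[PartitionScore, PartitionScore]:
    """Score every scanned partition with both indices and return the argmax
    for Q and for H.  On ties the partition with fewer clusters wins and,
    among equal sizes, the first encountered."""
    scores = [_score(g, p) for p in scan_partitions(t, g)]
    best_q = scores[0]
    best_h = scores[0]
    for s in scores[1:]:
        if s.Q > best_q.Q:
            best_q = s
        if s.H > best_h.H:
            best_h = s
    return best_q, best_h
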