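"""Planted-partition caveman graphs with controlled degradation.

The benchmark graph is a disjoint union of equal-size complete subgraphs
(a variation of connected-caveman graphs).  Degradation at d% first removes
round(d% of the edges) uniformly at random, then shuffles round(d% of the
remaining edges): each shuffle move deletes one uniformly chosen edge and
inserts a new edge between a uniformly chosen pair of currently
non-adjacent nodes.  Edge count is conserved by shuffling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .graph_io import Graph
from .iterative import Partition

__all__ = [
    "PlantedGraph",
    "make_caveman",
    "degrade",
    "misclassified_count",
    "write_membership",
]


@dataclass(frozen=True)
class PlantedGraph:
    """A graph together with its ground-truth community structure."""

    graph: Graph
    planted: Partition
    degradation_pct: float = 0.0


def make_caveman(num_clusters: int, cluster_size: int) -> PlantedGraph:
    """Disjoint union of ``num_clusters`` complete graphs on ``cluster_size``
    nodes each; node labels encode the community (c<ci>_<k>)."""
    if num_clusters < 1 or cluster_size < 2:
        raise ValueError("need num_clusters >= 1 and cluster_size >= 2")
    nodes: list[str] = []
    blocks: list[list[str]] = []
    edges: list[tuple[str, str]] = []
    for ci in range(num_clusters):
        members = [f"c{ci:02d}_{k:03d}" for k in range(cluster_size)]
        nodes.extend(members)
        blocks.append(members)
        for a in range(cluster_size):
            for b in range(a + 1, cluster_size):
                edges.append((members[a], members[b]))
    g = Graph.from_edges(edges, nodes=nodes)
    return PlantedGraph(graph=g, planted=Partition.from_blocks(blocks))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def degrade(
    pg: PlantedGraph, pct: float, rng: np.random.Generator | int | None = None
) -> PlantedGraph:
    """Remove round(pct% · E0) edges, then apply round(pct% · E1) shuffle
    moves to the remainder (E1 = post-removal count).  The planted partition
    is left untouched."""
    if not (0.0 <= pct <= 100.0):
        raise ValueError("degradation percentage must be in [0, 100]")
    if pct == 0.0:
        return replace(pg, degradation_pct=0.0)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g = pg.graph
    n = g.num_nodes
    e0, e1 = g.edge_index_arrays()
    edges = np.stack([e0, e1], axis=1).astype(np.int64)
    E0 = len(edges)
    n_remove = _round_half_away(pct / 100.0 * E0)
    keep_mask = np.ones(E0, dtype=bool)
    keep_mask[rng.choice(E0, size=n_remove, replace=False)] = False
    edges = edges[keep_mask]
    E1 = len(edges)

    adj = np.zeros((n, n), dtype=bool)
    adj[edges[:, 0], edges[:, 1]] = True
    adj[edges[:, 1], edges[:, 0]] = True
    edge_list = [tuple(e) for e in edges]

    n_shuffle = _round_half_away(pct / 100.0 * E1)
    max_edges = n * (n - 1) // 2
    for _ in range(n_shuffle):
        if not edge_list:
            break
        k = int(rng.integers(0, len(edge_list)))
        a, b = edge_list[k]
        edge_list[k] = edge_list[-1]
        edge_list.pop()
        adj[a, b] = adj[b, a] = False
        if len(edge_list) >= max_edges:  # pragma: no cover - saturation guard
            raise RuntimeError("graph saturated; cannot insert a new edge")
        while True:
            u = int(rng.integers(0, n))
            v = int(rng.integers(0, n))
            if u != v and not adj[u, v]:
                break
        adj[u, v] = adj[v, u] = True
        edge_list.append((min(u, v), max(u, v)))

    labels = pg.graph.nodes
    new_graph = Graph.from_edges(
        [(labels[a], labels[b]) for a, b in edge_list], nodes=labels
    )
    return PlantedGraph(graph=new_graph, planted=pg.planted, degradation_pct=pct)


def misclassified_count(recovered: Partition, planted: Partition) -> int:
    """Minimum number of nodes to reassign so the two partitions coincide:
    nodes left unmatched by a maximum-weight matching of recovered clusters
    to planted clusters on shared-member counts."""
    if recovered.nodes != planted.nodes:
        raise ValueError("partitions cover different node sets")
    nodes = sorted(recovered.nodes)
    ra = recovered.labels_for(nodes)
    pa = planted.labels_for(nodes)
    nr, npl = recovered.num_clusters, planted.num_clusters
    contingency = np.zeros((nr, npl), dtype=np.int64)
    np.add.at(contingency, (ra, pa), 1)
    rows, cols = linear_sum_assignment(contingency, maximize=True)
    return len(nodes) - int(contingency[rows, cols].sum())


def write_membership(p: Partition, path) -> None:
    """Ground-truth membership table: node TAB community id (1-based)."""
    with open(path, "w") as fh:
        for ci, block in enumerate(p.blocks, start=1):
            for v in sorted(block):
                fh.write(f"{v}\t{ci}\n")
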