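"""Randomized single-iteration partitioners and secondary-distance accumulation.

Three algorithms turn one shuffle of the graph into a partition:

* ``uv`` — greedy clique growth from the first unit of a randomly ordered
  list (clusters are cliques);
* ``r``  — random pairwise merging of clique-blocks, with a blind phase that
  switches to an exhaustive block-mergeability matrix after ``n`` consecutive
  failed picks (clusters are cliques);
* ``s``  — collapse of a random seed with all its remaining neighbours
  (clusters are stars: every member is linked to the seed).

Repeating an algorithm many times and counting, for each pair of nodes, the
fraction of iterations in which the pair fell into different clusters yields
the *secondary distance* matrix fed to tree construction.  Only directly
connected units may ever be co-clustered (the permissiveness coefficient is
fixed at its maximum), which is why the adjacency matrix alone suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _kernels
from .graph_io import Graph

__all__ = [
    "AFFINITY_COEFFICIENT",
    "ALGORITHMS",
    "Partition",
    "PairSeparationCounts",
    "SecondaryDistanceMatrix",
    "uvcluster_iteration",
    "rcluster_iteration",
    "scluster_iteration",
    "accumulate",
    "secondary_distances",
    "default_iterations",
]

#: Permissiveness of the clustering process, fixed at its maximum: only
#: directly connected units are ever placed in the same cluster.  Not
#: user-settable.
AFFINITY_COEFFICIENT: int = 100

#: Valid iterative-algorithm codes (CLI order).
ALGORITHMS: tuple[str, ...] = ("uv", "r", "s")


@dataclass(frozen=True)
class Partition:
    """Assignment of every node to exactly one cluster."""

    blocks: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for b in self.blocks:
            if not b:
                raise ValueError("empty block in partition")
            if seen & b:
                raise ValueError("blocks are not disjoint")
            seen |= b
        object.__setattr__(self, "_nodes", frozenset(seen))

    @property
    def nodes(self) -> frozenset[str]:
        return self._nodes  # type: ignore[attr-defined]

    @property
    def num_clusters(self) -> int:
        return len(self.blocks)

    @property
    def assignment(self) -> dict[str, int]:
        return {v: i for i, b in enumerate(self.blocks) for v in b}

    @classmethod
    def from_labels(cls, nodes: Sequence[str], labels: np.ndarray) -> "Partition":
        """Build from a per-node integer label array (block order = order of
        first appearance of each label)."""
        order: dict[int, list[str]] = {}
        for v, lab in zip(nodes, labels):
            order.setdefault(int(lab), []).append(v)
        return cls(tuple(frozenset(b) for b in order.values()))

    @classmethod
    def from_blocks(cls, blocks: Iterable[Iterable[str]]) -> "Partition":
        return cls(tuple(frozenset(b) for b in blocks))

    def labels_for(self, nodes: Sequence[str]) -> np.ndarray:
        """Integer labels aligned with an explicit node order."""
        a = self.assignment
        return np.asarray([a[v] for v in nodes], dtype=np.int64)


@dataclass
class PairSeparationCounts:
    """Per-pair count of iterations in which the two nodes were clustered
    separately (symmetric, zero diagonal)."""

    nodes: tuple[str, ...]
    counts: np.ndarray
    iterations_done: int = 0

    @classmethod
    def zeros(cls, nodes: Sequence[str]) -> "PairSeparationCounts":
        n = len(nodes)
        return cls(tuple(nodes), np.zeros((n, n), dtype=np.int64), 0)

    def to_distances(self) -> "SecondaryDistanceMatrix":
        if self.iterations_done < 1:
            raise ValueError("no iterations accumulated")
        d = self.counts / float(self.iterations_done)
        np.fill_diagonal(d, 0.0)
        return SecondaryDistanceMatrix(self.nodes, d)


@dataclass
class SecondaryDistanceMatrix:
    """Fraction of iterations in which each pair was clustered separately."""

    nodes: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.nodes)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match node list")


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _check_nonempty(g: Graph) -> None:
    if g.num_nodes == 0:
        raise ValueError("graph has no nodes")


def uvcluster_iteration(g: Graph, rng: np.random.Generator | int | None = None) -> Partition:
    """One UVCluster iteration; every block is a clique of ``g``."""
    _check_nonempty(g)
    labels = _kernels.uv_labels(g.adjacency, _as_rng(rng))
    return Partition.from_labels(g.nodes, labels)


def rcluster_iteration(g: Graph, rng: np.random.Generator | int | None = None) -> Partition:
    """One RCluster iteration; every block is a clique of ``g``."""
    _check_nonempty(g)
    labels = _kernels.r_labels(g.adjacency, _as_rng(rng), g.num_nodes)
    return Partition.from_labels(g.nodes, labels)


def scluster_iteration(g: Graph, rng: np.random.Generator | int | None = None) -> Partition:
    """One SCluster iteration; every block contains a seed adjacent to all
    other members."""
    _check_nonempty(g)
    labels = _kernels.s_labels(g.adjacency, _as_rng(rng))
    return Partition.from_labels(g.nodes, labels)


_ITERATION_KERNELS = {
    "uv": lambda adj, rng, n: _kernels.uv_labels(adj, rng),
    "r": _kernels.r_labels,
    "s": lambda adj, rng, n: _kernels.s_labels(adj, rng),
}


def accumulate(counts: PairSeparationCounts, p: Partition) -> PairSeparationCounts:
    """Record one iteration: increment counts for every pair of nodes placed
    in different blocks of ``p`` (in place; also returned)."""
    if p.nodes != frozenset(counts.nodes):
        raise ValueError("partition node set does not match the counts matrix")
    labels = p.labels_for(counts.nodes)
    counts.counts += labels[:, None] != labels[None, :]
    counts.iterations_done += 1
    return counts


def secondary_distances(
    g: Graph,
    algorithm: str,
    iterations: int,
    rng: np.random.Generator | int | None = None,
) -> SecondaryDistanceMatrix:
    """Run ``iterations`` independent iterations of the chosen algorithm and
    return the matrix of pair-separation fractions.

    Deterministic for a given seeded generator.  Cross-component pairs
    always separate, so their distance is exactly 1.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown iterative algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    _check_nonempty(g)
    rng = _as_rng(rng)
    kernel = _ITERATION_KERNELS[algorithm]
    n = g.num_nodes
    adj = g.adjacency
    counts = np.zeros((n, n), dtype=np.int64)
    for _ in range(iterations):
        labels = kernel(adj, rng, n)
        _kernels.accumulate_separation(counts, labels)
    counts = counts + counts.T
    d = counts / float(iterations)
    return SecondaryDistanceMatrix(g.nodes, d)


def default_iterations(g: Graph, factor: int = 10) -> int:
    """Suggested iteration count: ``factor`` (default 10) times the number
    of nodes."""
    return factor * g.num_nodes
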