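"""Edge-list parsing and the canonical in-memory graph representation.

The input format is a plain-text file with one undirected edge per line:
the labels of the two linked nodes separated by a tab or space.  Lines
starting with ``#`` are treated as comments.  The graph is simple and
unweighted: duplicate edges (in either orientation) collapse to one, and
self-loops are dropped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Graph",
    "GraphInputError",
    "read_edge_list",
    "write_edge_list",
    "adjacency_submatrix",
]


class GraphInputError(ValueError):
    """Raised for unreadable or malformed edge-list input."""


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph with named nodes and a dense 0/1 adjacency matrix.

    Parameters
    ----------
    nodes:
        Ordered unique node labels.  The adjacency matrix rows/columns
        follow this order, as do all matrices derived downstream.
    edges:
        Unordered pairs of labels; stored internally as a frozenset of
        2-element frozensets.
    """

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    adjacency: np.ndarray = field(compare=False, repr=False, default=None)
    index: dict[str, int] = field(compare=False, repr=False, default=None)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphInputError("duplicate node labels")
        index = {lab: i for i, lab in enumerate(self.nodes)}
        n = len(self.nodes)
        adj = np.zeros((n, n), dtype=np.uint8)
        for e in self.edges:
            pair = tuple(e)
            if len(pair) != 2:
                raise GraphInputError(f"self-loop or malformed edge: {pair}")
            try:
                i, j = index[pair[0]], index[pair[1]]
            except KeyError as exc:
                raise GraphInputError(f"edge endpoint {exc} not in node list") from None
            adj[i, j] = adj[j, i] = 1
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "index", index)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Sequence[str] | None = None
    ) -> "Graph":
        """Build a graph from (u, v) pairs; node order is first appearance
        unless an explicit node list (which may include isolated nodes) is given."""
        seen: dict[str, None] = {}
        eset: set[frozenset[str]] = set()
        for u, v in edges:
            if u == v:
                warnings.warn(f"self-loop on {u!r} dropped", stacklevel=2)
                seen.setdefault(u)
                continue
            seen.setdefault(u)
            seen.setdefault(v)
            eset.add(frozenset((u, v)))
        if nodes is None:
            nodes = tuple(seen)
        else:
            nodes = tuple(nodes)
            missing = set(seen) - set(nodes)
            if missing:
                raise GraphInputError(f"edge endpoints not in node list: {sorted(missing)}")
        return cls(nodes=nodes, edges=frozenset(eset))

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def edge_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges as two parallel integer index arrays (deterministic order)."""
        cached = getattr(self, "_edge_arrays", None)
        if cached is not None:
            return cached
        pairs = sorted(
            (min(self.index[a], self.index[b]), max(self.index[a], self.index[b]))
            for a, b in (tuple(e) for e in self.edges)
        )
        if not pairs:
            result = (np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp))
        else:
            arr = np.asarray(pairs, dtype=np.intp)
            result = (arr[:, 0], arr[:, 1])
        object.__setattr__(self, "_edge_arrays", result)
        return result

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def neighbors(self, label: str) -> list[str]:
        row = self.adjacency[self.index[label]]
        return [self.nodes[j] for j in np.flatnonzero(row)]


def read_edge_list(path: str | Path) -> Graph:
    """Parse a two-column whitespace-delimited edge list into a :class:`Graph`.

    Each non-empty, non-comment line must carry at least two tokens; extra
    tokens are ignored with a warning (so weighted lists read as unweighted).
    Duplicate and reversed-duplicate lines collapse; self-loops are dropped
    with a warning.  Node order is order of first appearance in the file.
    """
    path = Path(path)
    if not path.is_file():
        raise GraphInputError(f"input file not found: {path}")
    edges: list[tuple[str, str]] = []
    extra_warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GraphInputError(
                    f"{path}:{lineno}: expected two node labels, got {line!r}"
                )
            if len(tokens) > 2 and not extra_warned:
                warnings.warn(
                    f"{path}:{lineno}: extra tokens beyond the first two are ignored",
                    stacklevel=2,
                )
                extra_warned = True
            edges.append((tokens[0], tokens[1]))
    if not edges:
        raise GraphInputError(f"{path}: no edges found")
    return Graph.from_edges(edges)


def write_edge_list(g: Graph, path: str | Path) -> None:
    """Write the graph back out in the two-column format (tab-separated)."""
    i0, i1 = g.edge_index_arrays()
    with open(path, "w") as fh:
        for a, b in zip(i0, i1):
            fh.write(f"{g.nodes[a]}\t{g.nodes[b]}\n")


def adjacency_submatrix(g: Graph, members: Sequence[str]) -> np.ndarray:
    """Principal submatrix of the adjacency matrix restricted to *members*,
    rows/columns in the order given."""
    try:
        idx = [g.index[m] for m in members]
    except KeyError as exc:
        raise GraphInputError(f"unknown node label {exc}") from None
    return g.adjacency[np.ix_(idx, idx)].copy()
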