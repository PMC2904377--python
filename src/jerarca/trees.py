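"""Dendrogram construction from the secondary-distance matrix.

Two classical distance-matrix methods are provided: size-weighted UPGMA
(producing an ultrametric rooted tree directly) and Saitou–Nei
neighbor-joining (producing an unrooted tree that is subsequently rooted at
the midpoint of its longest leaf-to-leaf path).  Minimum searches break ties
toward the lowest index pair in the current matrix order, so runs are
reproducible.  Branch lengths live on the secondary-distance scale (0–1) and
negative neighbor-joining estimates are clamped to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .iterative import SecondaryDistanceMatrix

__all__ = [
    "TreeNode",
    "UnrootedTree",
    "upgma",
    "neighbor_joining",
    "midpoint_root",
    "write_newick",
]


@dataclass(eq=False)
class TreeNode:
    """Node of a rooted dendrogram.

    ``children`` holds ``(child, branch_length)`` pairs; leaves carry the
    graph node label in ``name`` and have no children.
    """

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]


@dataclass
class UnrootedTree:
    """Unrooted tree with branch lengths, as produced by neighbor-joining.

    ``adj`` maps a node id to its ``(neighbour id, edge length)`` list;
    ``labels`` maps leaf ids to graph node labels.  Leaf ids 0..n-1 follow
    the input matrix order.
    """

    adj: dict[int, list[tuple[int, float]]]
    labels: dict[int, str]

    def leaf_ids(self) -> list[int]:
        return sorted(self.labels)


def _argmin_pair(m: np.ndarray) -> tuple[int, int]:
    """Row-major argmin of a symmetric matrix; ties resolve to the lowest
    (i, j) pair."""
    flat = int(np.argmin(m))
    i, j = divmod(flat, m.shape[0])
    return (i, j) if i < j else (j, i)


def upgma(d: SecondaryDistanceMatrix) -> TreeNode:
    """Average-linkage (size-weighted) agglomeration.

    Clusters at minimal average distance are joined at height = distance/2;
    distances to the merged cluster are size-weighted averages of the two
    constituents.  The result is ultrametric.
    """
    n = len(d.nodes)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 leaves")
    D = d.d.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    heights = np.zeros(n)
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in d.nodes]
    root = nodes[0]
    for _ in range(n - 1):
        mask = active[:, None] & active[None, :]
        Dm = np.where(mask, D, np.inf)
        i, j = _argmin_pair(Dm)
        h = Dm[i, j] / 2.0
        root = TreeNode(
            children=[(nodes[i], h - heights[i]), (nodes[j], h - heights[j])]
        )
        new_row = (sizes[i] * D[i] + sizes[j] * D[j]) / (sizes[i] + sizes[j])
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        active[j] = False
        sizes[i] += sizes[j]
        heights[i] = h
        nodes[i] = root
    return root


def neighbor_joining(d: SecondaryDistanceMatrix) -> UnrootedTree:
    """Canonical Saitou–Nei neighbor-joining.

    Repeatedly joins the pair minimizing the NJ criterion, computes branch
    lengths by the standard formulas (negative estimates clamped to 0) and
    reduces the matrix until two nodes remain, which are connected directly.
    """
    n = len(d.nodes)
    if n < 2:
        raise ValueError("neighbor-joining needs at least 2 leaves")
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    labels = {i: d.nodes[i] for i in range(n)}

    def connect(a: int, b: int, length: float) -> None:
        length = max(0.0, float(length))
        adj[a].append((b, length))
        adj[b].append((a, length))

    if n == 2:
        connect(0, 1, d.d[0, 1])
        return UnrootedTree(adj, labels)

    D = d.d.astype(float).copy()
    np.fill_diagonal(D, 0.0)
    active = np.ones(n, dtype=bool)
    slot_id = list(range(n))  # matrix slot -> tree node id
    next_id = n
    m = n
    while m > 2:
        mask = active[:, None] & active[None, :]
        Dm = np.where(mask, D, 0.0)
        r = Dm.sum(axis=1)
        Q = (m - 2) * Dm - r[:, None] - r[None, :]
        Q = np.where(mask, Q, np.inf)
        np.fill_diagonal(Q, np.inf)
        i, j = _argmin_pair(Q)
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        adj[u] = []
        connect(u, slot_id[i], li)
        connect(u, slot_id[j], lj)
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        active[j] = False
        slot_id[i] = u
        m -= 1
    i, j = [s for s in range(n) if active[s]]
    connect(slot_id[i], slot_id[j], D[i, j])
    return UnrootedTree(adj, labels)


def _distances_from(t: UnrootedTree, start: int) -> tuple[dict[int, float], dict[int, int]]:
    """Single-source path lengths and predecessors by iterative DFS."""
    dist = {start: 0.0}
    pred: dict[int, int] = {}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, L in t.adj[u]:
            if v not in dist:
                dist[v] = dist[u] + L
                pred[v] = u
                stack.append(v)
    return dist, pred


def midpoint_root(t: UnrootedTree) -> TreeNode:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    Leaf pairs are scanned in leaf-id order and the first strictly longest
    path wins, so rooting is deterministic.  A tree whose branch lengths are
    all zero gets its root placed on an arbitrary edge, with a warning.
    """
    leaf_ids = t.leaf_ids()
    if len(leaf_ids) == 1:
        return TreeNode(name=t.labels[leaf_ids[0]])
    best = (-1.0, leaf_ids[0], leaf_ids[0])
    dist_cache: dict[int, tuple[dict[int, float], dict[int, int]]] = {}
    for a in leaf_ids:
        dist, pred = _distances_from(t, a)
        dist_cache[a] = (dist, pred)
        for b in leaf_ids:
            if b <= a:
                continue
            if dist[b] > best[0]:
                best = (dist[b], a, b)
    total, a, b = best
    if total <= 0.0:
        warnings.warn("all branch lengths are zero; placing root on an arbitrary edge")
    dist, pred = dist_cache[a]
    # path from a to b
    path = [b]
    while path[-1] != a:
        path.append(pred[path[-1]])
    path.reverse()
    half = total / 2.0
    cum = 0.0
    for u, v in zip(path, path[1:]):
        length = next(L for (w, L) in t.adj[u] if w == v)
        if cum + length >= half or (u, v) == (path[-2], path[-1]):
            x = min(max(half - cum, 0.0), length)
            return _orient_with_root(t, u, v, x, length)
        cum += length
    raise AssertionError("midpoint not located")  # pragma: no cover


def _orient_with_root(
    t: UnrootedTree, u: int, v: int, x: float, length: float
) -> TreeNode:
    """Build the rooted tree with the root placed on edge (u, v) at distance
    ``x`` from ``u``."""

    def orient(node: int, parent: int) -> TreeNode:
        out = TreeNode(name=t.labels.get(node))
        for w, L in t.adj[node]:
            if w == parent:
                continue
            out.children.append((orient(w, node), L))
        return out

    root = TreeNode()
    root.children.append((orient(u, v), x))
    root.children.append((orient(v, u), length - x))
    return root


_NEWICK_UNSAFE = set("()[]{}:;,'\" \t\n")


def _quote_label(label: str) -> str:
    if label and not (_NEWICK_UNSAFE & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def _newick_node(node: TreeNode) -> str:
    label = _quote_label(node.name) if node.name is not None else ""
    if node.is_leaf:
        return label
    inner = ",".join(
        f"{_newick_node(c)}:{L:.10g}" for c, L in node.children
    )
    return f"({inner}){label}"


def write_newick(t: TreeNode) -> str:
    """Serialize a rooted dendrogram as a standard Newick string."""
    return _newick_node(t) + ";"
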