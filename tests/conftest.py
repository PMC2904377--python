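import itertools
from fractions import Fraction

import numpy as np
import pytest

from jerarca.graph_io import Graph


# ---------------------------------------------------------------------------
# small named graphs
# ---------------------------------------------------------------------------

@pytest.fixture
def path3():
    """a - b - c"""
    return Graph.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def two_triangles():
    return Graph.from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
    )


@pytest.fixture
def k5():
    labels = ["v1", "v2", "v3", "v4", "v5"]
    return Graph.from_edges(
        [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    )


@pytest.fixture
def bridged_triangles():
    """Two triangles joined by a single edge (m = 7)."""
    return Graph.from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("x", "y"), ("y", "z"), ("x", "z"), ("c", "x")]
    )


def random_graph(rng: np.random.Generator, n: int, p: float) -> Graph:
    """Erdos-Renyi-ish test graph; node labels n0..n{n-1}; may be edgeless."""
    labels = [f"n{i}" for i in range(n)]
    edges = [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return Graph.from_edges(edges, nodes=labels)


# ---------------------------------------------------------------------------
# enumeration oracles (independent of the production code paths)
# ---------------------------------------------------------------------------

def _uv_blocks_for_order(adj: np.ndarray, order: tuple[int, ...]) -> list[set[int]]:
    """Greedy clique partition for one fixed node ordering, transcribed
    directly from the verbal description: take the first available unit,
    scan the rest in list order, admit a unit iff adjacent to every member."""
    assigned: set[int] = set()
    blocks: list[set[int]] = []
    for pos, u in enumerate(order):
        if u in assigned:
            continue
        block = {u}
        for v in order[pos + 1 :]:
            if v in assigned or v in block:
                continue
            if all(adj[v, w] for w in block):
                block.add(v)
        assigned |= block
        blocks.append(block)
    return blocks


def uv_exact_separation(g: Graph) -> np.ndarray:
    """Exact pair-separation probabilities for UVCluster by brute-force
    enumeration of all node orderings."""
    n = g.num_nodes
    adj = g.adjacency
    sep = np.zeros((n, n), dtype=object)
    orders = list(itertools.permutations(range(n)))
    for order in orders:
        blocks = _uv_blocks_for_order(adj, order)
        label = {}
        for bi, b in enumerate(blocks):
            for v in b:
                label[v] = bi
        for i in range(n):
            for j in range(i + 1, n):
                if label[i] != label[j]:
                    sep[i, j] += 1
    out = np.zeros((n, n), dtype=float)
    total = Fraction(len(orders))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = float(Fraction(int(sep[i, j])) / total)
    return out


def s_exact_separation(g: Graph) -> np.ndarray:
    """Exact pair-separation probabilities for SCluster by recursive
    expectation over equally likely seed choices."""
    n = g.num_nodes
    adj = g.adjacency

    memo: dict[frozenset[int], dict[tuple[int, int], Fraction]] = {}

    def expect(remaining: frozenset[int]) -> dict[tuple[int, int], Fraction]:
        if len(remaining) <= 1:
            return {}
        if remaining in memo:
            return memo[remaining]
        acc: dict[tuple[int, int], Fraction] = {}
        w = Fraction(1, len(remaining))
        for seed in remaining:
            block = {seed} | {v for v in remaining if adj[seed, v]}
            rest = remaining - block
            # pairs split between block and rest separate now
            for i in block:
                for j in rest:
                    key = (min(i, j), max(i, j))
                    acc[key] = acc.get(key, Fraction(0)) + w
            for key, val in expect(frozenset(rest)).items():
                acc[key] = acc.get(key, Fraction(0)) + w * val
        memo[remaining] = acc
        return acc

    probs = expect(frozenset(range(n)))
    out = np.zeros((n, n), dtype=float)
    for (i, j), val in probs.items():
        out[i, j] = out[j, i] = float(val)
    return out


def exact_hypergeom_tail(F: int, n_obs: int, M: int, p_intra: int) -> Fraction:
    """Upper-tail cumulative hypergeometric probability with exact integer
    binomials."""
    from math import comb

    denom = comb(F, n_obs)
    total = 0
    for x in range(p_intra, min(n_obs, M) + 1):
        if n_obs - x > F - M:
            continue
        total += comb(M, x) * comb(F - M, n_obs - x)
    return Fraction(total, denom)
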