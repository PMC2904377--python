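"""Compiled inner loops for the randomized partitioners.

Each kernel takes the dense 0/1 adjacency matrix and a
``numpy.random.Generator`` and returns one iteration's cluster labels as an
int32 array (block ids are arbitrary but consistent within the array).
Everything here is an implementation detail of :mod:`jerarca.iterative`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["uv_labels", "r_labels", "s_labels", "accumulate_separation"]


@njit(cache=False)
def uv_labels(adj, rng):
    """One UVCluster iteration: shuffle the node list, then repeatedly grow a
    greedy clique from the first unassigned node, scanning candidates in
    shuffled-list order and admitting a node only if adjacent to every
    current member."""
    n = adj.shape[0]
    order = np.arange(n)
    rng.shuffle(order)
    labels = np.full(n, -1, dtype=np.int32)
    assigned = np.zeros(n, dtype=np.bool_)
    can = np.empty(n, dtype=np.bool_)
    block_id = 0
    for pos in range(n):
        u = order[pos]
        if assigned[u]:
            continue
        assigned[u] = True
        labels[u] = block_id
        for v in range(n):
            can[v] = (not assigned[v]) and adj[u, v] == 1
        for q in range(pos + 1, n):
            v = order[q]
            if can[v]:
                assigned[v] = True
                labels[v] = block_id
                can[v] = False
                for w in range(n):
                    if can[w] and adj[v, w] == 0:
                        can[w] = False
        block_id += 1
    return labels


@njit(cache=False)
def s_labels(adj, rng):
    """One SCluster iteration: pick an unassigned node uniformly at random,
    collapse it with all its unassigned neighbours into one cluster, remove
    them, repeat."""
    n = adj.shape[0]
    labels = np.full(n, -1, dtype=np.int32)
    alive = np.arange(n)
    pos_of = np.arange(n)
    alive_n = n
    block_id = 0
    while alive_n > 0:
        seed = alive[rng.integers(0, alive_n)]
        labels[seed] = block_id
        # swap-remove seed
        p = pos_of[seed]
        last = alive[alive_n - 1]
        alive[p] = last
        pos_of[last] = p
        alive_n -= 1
        for k in range(alive_n - 1, -1, -1):
            v = alive[k]
            if adj[seed, v] == 1:
                labels[v] = block_id
                last = alive[alive_n - 1]
                alive[k] = last
                pos_of[last] = k
                alive_n -= 1
                # the element swapped into position k is either already
                # scanned (it came from a higher index) or is `v` itself
        block_id += 1
    return labels


@njit(cache=False)
def _blocks_mergeable(mask, head, nxt, size, a, b):
    """Union of clique-blocks a and b is a clique iff every member of the
    smaller block is adjacent to all members of the other (mask[b][x] means
    node x is adjacent to every member of block b)."""
    small, big = (a, b) if size[a] <= size[b] else (b, a)
    x = head[small]
    while x != -1:
        if not mask[big, x]:
            return False
        x = nxt[x]
    return True


@njit(cache=False)
def _merge_blocks(mask, head, nxt, tail, size, a, b):
    """Merge block b into block a (member chain, size, candidate mask)."""
    nxt[tail[a]] = head[b]
    tail[a] = tail[b]
    size[a] += size[b]
    for w in range(mask.shape[1]):
        mask[a, w] = mask[a, w] and mask[b, w]


@njit(cache=False)
def r_labels(adj, rng, fail_budget):
    """One RCluster iteration: start from singletons; phase 1 repeatedly
    picks two distinct blocks uniformly at random and merges them when their
    union is a clique, until `fail_budget` consecutive picks fail; phase 2
    builds the block-level mergeability matrix, picks 1-entries uniformly at
    random and merges until none remain."""
    n = adj.shape[0]
    head = np.arange(n).astype(np.int64)
    tail = np.arange(n).astype(np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    size = np.ones(n, dtype=np.int64)
    mask = adj.astype(np.bool_)  # mask[b, x]: x adjacent to every member of b
    alive = np.arange(n)
    pos_of = np.arange(n)
    alive_n = n

    # phase 1: blind random picks
    fails = 0
    while fails < fail_budget and alive_n > 1:
        ia = rng.integers(0, alive_n)
        ib = rng.integers(0, alive_n)
        if ia == ib:
            continue
        a = alive[ia]
        b = alive[ib]
        if _blocks_mergeable(mask, head, nxt, size, a, b):
            _merge_blocks(mask, head, nxt, tail, size, a, b)
            p = pos_of[b]
            last = alive[alive_n - 1]
            alive[p] = last
            pos_of[last] = p
            alive_n -= 1
            fails = 0
        else:
            fails += 1

    # phase 2: exhaustive mergeability matrix
    B = alive_n
    if B > 1:
        mm = np.zeros((B, B), dtype=np.bool_)
        ones = 0  # unordered mergeable pairs
        for ii in range(B):
            for jj in range(ii + 1, B):
                if _blocks_mergeable(mask, head, nxt, size, alive[ii], alive[jj]):
                    mm[ii, jj] = True
                    mm[jj, ii] = True
                    ones += 1
        while ones > 0:
            r = rng.integers(0, ones)
            # locate the r-th 1-entry of the upper triangle
            ii = -1
            jj = -1
            c = 0
            for i2 in range(B):
                if jj != -1:
                    break
                for j2 in range(i2 + 1, B):
                    if mm[i2, j2]:
                        if c == r:
                            ii = i2
                            jj = j2
                            break
                        c += 1
            _merge_blocks(mask, head, nxt, tail, size, alive[ii], alive[jj])
            # drop row/col jj by swapping with the last block
            lastp = B - 1
            if jj != lastp:
                alive[jj] = alive[lastp]
                for k in range(B):
                    mm[jj, k] = mm[lastp, k]
                for k in range(B):
                    mm[k, jj] = mm[k, lastp]
                mm[jj, jj] = False
            B -= 1
            # refresh mergeability of the grown block against the rest
            for k in range(B):
                if k == ii:
                    continue
                ok = _blocks_mergeable(mask, head, nxt, size, alive[ii], alive[k])
                mm[ii, k] = ok
                mm[k, ii] = ok
            # recount unordered 1-pairs
            ones = 0
            for i2 in range(B):
                for j2 in range(i2 + 1, B):
                    if mm[i2, j2]:
                        ones += 1
        alive_n = B

    labels = np.full(n, -1, dtype=np.int32)
    for bi in range(alive_n):
        x = head[alive[bi]]
        while x != -1:
            labels[x] = bi
            x = nxt[x]
    return labels


@njit(cache=False)
def accumulate_separation(counts, labels):
    """Add 1 to counts[i, j] (upper triangle only) for every pair with
    different labels."""
    n = labels.size
    for i in range(n):
        li = labels[i]
        for j in range(i + 1, n):
            if labels[j] != li:
                counts[i, j] += 1
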