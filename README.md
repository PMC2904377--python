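# jerarca

Iterative hierarchical clustering of undirected networks.

A plain-text edge list is converted into dendrograms and statistically
optimal partitions in three stages:

1. **Secondary distances** — one of three randomized partitioners is run for
   many iterations; the fraction of iterations in which a pair of nodes
   lands in different clusters becomes its distance.
   * `uv` (UVCluster): greedy clique growth from a randomly ordered node
     list.
   * `r` (RCluster): random pairwise merging of clique blocks (blind phase,
     then an exhaustive block-mergeability matrix).
   * `s` (SCluster): collapse of a random seed node with all its remaining
     neighbours (star clusters).

   Only directly connected nodes may ever be co-clustered, so everything
   runs on the adjacency matrix alone.
2. **Dendrograms** — size-weighted UPGMA (`u`) and/or midpoint-rooted
   neighbor-joining (`nj`) on the secondary-distance matrix.
3. **Optimal partitions** — the tree is scanned from root to leaves (n
   nested partitions for n nodes); each cut is scored with Newman–Girvan
   modularity **Q** and with **H**, the negative decimal log of the
   upper-tail cumulative hypergeometric probability of the observed number
   of intracluster links. The best partition per index is reported.

A synthetic benchmark module generates planted-partition caveman graphs
(equal fully connected communities) with controlled degradation
(edge removal + random rewiring) and scores recovered partitions by optimal
matching against the planted communities.

## CLI

```sh
jerarca FILE {uv|r|s|all} {u|nj|all} ITERATIONS [--seed S] [--output-dir D]
```

`FILE` holds one undirected edge per line: two node labels separated by a
tab or space (`#` comments allowed). A rule of thumb for `ITERATIONS` is 10
times the number of nodes. With `all`/`all` the run produces 3 distance
matrices, 6 dendrograms and 12 partition analyses.

Outputs per combination (names encode algorithms and criterion, e.g.
`net_partitionH_SCluster_Upgma.txt`):

| extension | content |
|-----------|---------|
| `.nwk` | dendrogram in Newick format |
| `.meg` | MEGA 4 distance data + optimal clusters as comments |
| `.att` | Cytoscape 2.x node-attribute file (`node = cluster`) |
| `.txt` | partition report: cluster count, index value, members |
| `.log` | seed, iteration count, runtimes, chosen optima |

## Library

```python
import numpy as np
import jerarca as J

pg = J.make_caveman(16, 32)                      # planted benchmark graph
g  = J.degrade(pg, 20, np.random.default_rng(0)).graph
d  = J.secondary_distances(g, "uv", 5000, rng=1)
tree = J.upgma(d)                                 # or midpoint_root(neighbor_joining(d))
best_q, best_h = J.best_partitions(tree, g)
print(best_q.num_clusters, best_q.Q, best_h.H)
```

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` re-runs the published benchmark experiments
(512 nodes, 16 communities, 5000 iterations per algorithm at several
degradation levels); the full suite takes a few minutes on one CPU.

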