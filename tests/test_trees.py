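import numpy as np
import pytest
import dendropy
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from jerarca.iterative import SecondaryDistanceMatrix
from jerarca.trees import (
    TreeNode,
    midpoint_root,
    neighbor_joining,
    upgma,
    write_newick,
)


def sdm(labels, matrix):
    return SecondaryDistanceMatrix(tuple(labels), np.asarray(matrix, dtype=float))


def root_to_leaf_depths(t: TreeNode) -> dict[str, float]:
    out = {}

    def walk(node, depth):
        if node.is_leaf:
            out[node.name] = depth
        for c, L in node.children:
            walk(c, depth + L)

    walk(t, 0.0)
    return out


def cophenetic_map(t: TreeNode) -> dict[frozenset, float]:
    """Leaf-pair path distances through the rooted tree."""
    out = {}

    def walk(node):
        # returns {leaf: distance to this node}
        if node.is_leaf:
            return {node.name: 0.0}
        sub = []
        for c, L in node.children:
            m = walk(c)
            sub.append({k: v + L for k, v in m.items()})
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                for a, da in sub[i].items():
                    for b, db in sub[j].items():
                        out[frozenset((a, b))] = da + db
        merged = {}
        for m in sub:
            merged.update(m)
        return merged

    walk(t)
    return out


def unrooted_leaf_distances(t) -> dict[frozenset, float]:
    leaf_ids = t.leaf_ids()
    out = {}
    for a in leaf_ids:
        dist = {a: 0.0}
        stack = [a]
        while stack:
            u = stack.pop()
            for v, L in t.adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + L
                    stack.append(v)
        for b in leaf_ids:
            if b > a:
                out[frozenset((t.labels[a], t.labels[b]))] = dist[b]
    return out


class TestUpgma:
    def test_three_leaf_hand_example(self):
        d = sdm("ABC", [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        t = upgma(d)
        depths = root_to_leaf_depths(t)
        assert depths == pytest.approx({"A": 0.3, "B": 0.3, "C": 0.3})
        cm = cophenetic_map(t)
        assert cm[frozenset("AB")] == pytest.approx(0.2)
        assert cm[frozenset("AC")] == pytest.approx(0.6)

    def test_two_leaves(self):
        t = upgma(sdm("AB", [[0, 1], [1, 0]]))
        assert write_newick(t) in ("(A:0.5,B:0.5);", "(B:0.5,A:0.5);")

    def test_equal_distances_any_tie_order_same_heights(self):
        d = sdm("ABCD", (np.ones((4, 4)) - np.eye(4)) * 0.4)
        t = upgma(d)
        depths = root_to_leaf_depths(t)
        assert all(v == pytest.approx(0.2) for v in depths.values())

    def test_single_leaf_fatal(self):
        with pytest.raises(ValueError, match="at least 2"):
            upgma(sdm("A", [[0.0]]))

    def test_ultrametric_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            t = upgma(sdm([f"L{i}" for i in range(n)], m))
            depths = root_to_leaf_depths(t)
            vals = list(depths.values())
            assert max(vals) - min(vals) < 1e-9

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"L{i}" for i in range(n)]
            t = upgma(sdm(labels, m))
            cm = cophenetic_map(t)
            Z = linkage(squareform(m, checks=False), method="average")
            coph = squareform(cophenet(Z))
            for i in range(n):
                for j in range(i + 1, n):
                    assert cm[frozenset((labels[i], labels[j]))] == pytest.approx(
                        coph[i, j], abs=1e-9
                    )

    def test_leaf_permutation_invariance(self):
        rng = np.random.default_rng(3)
        n = 7
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"L{i}" for i in range(n)]
        cm1 = cophenetic_map(upgma(sdm(labels, m)))
        perm = rng.permutation(n)
        cm2 = cophenetic_map(
            upgma(sdm([labels[i] for i in perm], m[np.ix_(perm, perm)]))
        )
        for k, v in cm1.items():
            assert cm2[k] == pytest.approx(v, abs=1e-9)


ADDITIVE_4 = sdm(
    "ABCD",
    [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
)


class TestNeighborJoining:
    def test_additive_four_leaf_recovery(self):
        t = neighbor_joining(ADDITIVE_4)
        dm = unrooted_leaf_distances(t)
        assert dm[frozenset("AB")] == pytest.approx(2)
        assert dm[frozenset("CD")] == pytest.approx(2)
        assert dm[frozenset("AC")] == pytest.approx(4)
        # branch lengths: leaves at 1, internal edge 2
        lengths = sorted(
            L for u in t.adj for v, L in t.adj[u] if u < v
        )
        assert lengths == pytest.approx([1, 1, 1, 1, 2])

    def test_three_leaves_closed_form(self):
        d = sdm("ABC", [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        t = neighbor_joining(d)
        dm = unrooted_leaf_distances(t)
        assert dm[frozenset("AB")] == pytest.approx(0.3)
        assert dm[frozenset("AC")] == pytest.approx(0.5)
        assert dm[frozenset("BC")] == pytest.approx(0.6)

    def test_single_leaf_fatal(self):
        with pytest.raises(ValueError, match="at least 2"):
            neighbor_joining(sdm("A", [[0.0]]))

    def test_random_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            labels = [f"L{i}" for i in range(n)]
            m = _random_additive_matrix(rng, n)
            t = neighbor_joining(sdm(labels, m))
            dm = unrooted_leaf_distances(t)
            for i in range(n):
                for j in range(i + 1, n):
                    assert dm[frozenset((labels[i], labels[j]))] == pytest.approx(
                        m[i, j], abs=1e-9
                    )

    def test_topology_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 6
            m = rng.random((n, n)) + 0.5
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"L{i}" for i in range(n)]
            mine = neighbor_joining(sdm(labels, m))
            nwk_mine = write_newick(midpoint_root(mine))
            ref = skbio.tree.nj(skbio.DistanceMatrix(m, ids=labels))
            taxa = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(
                data=nwk_mine, schema="newick", taxon_namespace=taxa
            )
            t2 = dendropy.Tree.get(
                data=str(ref), schema="newick", taxon_namespace=taxa
            )
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
            # unrooted topologies agree (rooting may add one bipartition)
            assert rf <= 2

    def test_ultrametric_input_matches_upgma_topology(self):
        # enumerated small ultrametric matrix: ((A,B),(C,D)) heights 1 and 3
        m = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        labels = list("ABCD")
        nj_dm = unrooted_leaf_distances(neighbor_joining(sdm(labels, m)))
        # NJ splits AB|CD exactly as UPGMA does
        assert nj_dm[frozenset("AB")] < nj_dm[frozenset("AC")]
        assert nj_dm[frozenset("CD")] < nj_dm[frozenset("AC")]


def _random_additive_matrix(rng, n):
    """Distances induced by a random binary tree with positive lengths."""
    # build a random rooted binary tree over the leaves, then measure paths
    nodes = [TreeNode(name=f"L{i}") for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(
            TreeNode(children=[(a, rng.uniform(0.1, 2)), (b, rng.uniform(0.1, 2))])
        )
    cm = cophenetic_map(nodes[0])
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = cm[frozenset((f"L{i}", f"L{j}"))]
    return m


class TestMidpointRoot:
    def test_two_leaves(self):
        t = neighbor_joining(sdm("AB", [[0, 1], [1, 0]]))
        rooted = midpoint_root(t)
        depths = root_to_leaf_depths(rooted)
        assert depths == pytest.approx({"A": 0.5, "B": 0.5})

    def test_four_leaf_root_on_internal_edge(self):
        rooted = midpoint_root(neighbor_joining(ADDITIVE_4))
        # longest leaf-to-leaf path has length 4; root sits at its midpoint
        depths = root_to_leaf_depths(rooted)
        assert depths["A"] == pytest.approx(2)
        assert depths["C"] == pytest.approx(2)
        # the two root children subtend {A,B} and {C,D}
        sides = [frozenset(c.leaf_names()) for c, _ in rooted.children]
        assert set(sides) == {frozenset("AB"), frozenset("CD")}

    def test_balanced_ultrametric_root_matches_upgma(self):
        m = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        d = sdm("ABCD", m)
        nj_rooted = midpoint_root(neighbor_joining(d))
        up = upgma(d)
        assert root_to_leaf_depths(nj_rooted) == pytest.approx(
            root_to_leaf_depths(up)
        )

    def test_zero_length_tree_warns(self):
        d = sdm("ABC", np.zeros((3, 3)))
        t = neighbor_joining(d)
        with pytest.warns(UserWarning, match="zero"):
            rooted = midpoint_root(t)
        assert sorted(rooted.leaf_names()) == ["A", "B", "C"]


class TestWriteNewick:
    def test_two_leaf_string(self):
        t = TreeNode(children=[(TreeNode(name="A"), 0.5), (TreeNode(name="B"), 0.5)])
        assert write_newick(t) == "(A:0.5,B:0.5);"

    def test_three_leaf_upgma_example(self):
        d = sdm("ABC", [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        nwk = write_newick(upgma(d))
        taxa = dendropy.TaxonNamespace()
        ref = dendropy.Tree.get(
            data="((A:0.1,B:0.1):0.2,C:0.3);", schema="newick", taxon_namespace=taxa
        )
        got = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=taxa)
        ref.encode_bipartitions()
        got.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(ref, got) == 0

    def test_round_trip_topology_and_lengths(self):
        rng = np.random.default_rng(6)
        n = 8
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"L{i}" for i in range(n)]
        t = upgma(sdm(labels, m))
        nwk = write_newick(t)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        cm = cophenetic_map(t)
        taxa = {x.label: x for x in parsed.taxon_namespace}
        for i in range(n):
            for j in range(i + 1, n):
                got = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                assert got == pytest.approx(
                    cm[frozenset((labels[i], labels[j]))], abs=1e-6
                )

    def test_labels_with_metacharacters_are_quoted(self):
        t = TreeNode(
            children=[(TreeNode(name="a b"), 0.5), (TreeNode(name="c:d"), 0.5)]
        )
        nwk = write_newick(t)
        assert "'a b'" in nwk and "'c:d'" in nwk
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        names = sorted(leaf.taxon.label for leaf in parsed.leaf_node_iter())
        assert names == ["a b", "c:d"]
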