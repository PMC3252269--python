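import itertools
import math
import random

import dendropy
import numpy as np
import pytest

from hgtsieve.phylo import (
    SATURATION_CAP,
    DistanceMatrix,
    bionj,
    bootstrap_support,
    kimura_correction,
    midpoint_root,
    protein_distance_matrix,
    read_newick,
)


def bipartitions(gtree):
    """Leaf-set bipartitions of the internal edges, normalised."""
    leaves = frozenset(gtree.leaf_ids())
    ref = min(leaves)
    out = set()
    for node in gtree.tree.preorder_node_iter():
        if node.is_leaf() or node is gtree.tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(below) < len(leaves) - 1:
            out.add(below if ref not in below else leaves - below)
    return out


def random_additive_tree(n_taxa, rng):
    """Random unrooted topology with positive branch lengths; returns
    (taxa, patristic distance matrix, bipartition set)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    tree = dendropy.Tree()
    tree.seed_node.add_child(dendropy.Node(taxon=dendropy.Taxon(label=taxa[0])))
    tree.seed_node.add_child(dendropy.Node(taxon=dendropy.Taxon(label=taxa[1])))
    tree.seed_node.add_child(dendropy.Node(taxon=dendropy.Taxon(label=taxa[2])))
    for label in taxa[3:]:
        edges = [lf.edge for lf in tree.preorder_node_iter() if lf.parent_node is not None]
        edge = edges[rng.randrange(len(edges))]
        child = edge.head_node
        parent = edge.tail_node
        mid = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(mid)
        mid.add_child(child)
        new_leaf = dendropy.Node(taxon=dendropy.Taxon(label=label))
        mid.add_child(new_leaf)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = rng.uniform(0.1, 1.0)
    tree.update_taxon_namespace()

    # patristic distances by leaf-to-leaf path
    pdm = {}
    leaf_nodes = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    adj = {}
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            adj.setdefault(node, []).append((ch, ch.edge.length))
            adj.setdefault(ch, []).append((node, ch.edge.length))
    mat = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(taxa):
        dist = {leaf_nodes[a]: 0.0}
        stack = [leaf_nodes[a]]
        while stack:
            nd = stack.pop()
            for nb, w in adj[nd]:
                if nb not in dist:
                    dist[nb] = dist[nd] + w
                    stack.append(nb)
        for j, b in enumerate(taxa):
            mat[i, j] = dist[leaf_nodes[b]]
    mat = (mat + mat.T) / 2.0  # remove float asymmetry from per-source walks

    from hgtsieve.phylo import GeneTree

    return taxa, mat, bipartitions(GeneTree(tree))


class TestDistances:
    def test_identical_rows_distance_zero(self):
        dm = protein_distance_matrix([("a", "MKVL"), ("b", "MKVL")], model="p")
        assert dm["a", "b"] == 0.0

    def test_kimura_formula_at_half(self):
        assert kimura_correction(np.array([0.5]))[0] == pytest.approx(-math.log(0.45))

    def test_saturation_cap(self):
        assert kimura_correction(np.array([0.9]))[0] == SATURATION_CAP

    def test_kimura_dominates_p_and_is_monotone(self):
        p = np.linspace(0.01, 0.84, 100)
        d = kimura_correction(p)
        assert np.all(d >= p)
        assert np.all(np.diff(d) > 0)

    def test_pairwise_gap_deletion(self):
        dm = protein_distance_matrix([("a", "MK-L"), ("b", "MKVL")], model="p")
        assert dm["a", "b"] == 0.0

    def test_no_comparable_columns_names_pair(self):
        with pytest.raises(ValueError, match="'a'.*'b'"):
            protein_distance_matrix([("a", "--MK"), ("b", "VL--")], model="p")


class TestBionj:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = bionj(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_four_taxon_additive_recovery_vs_exhaustive_oracle(self):
        # additive matrix generated from ((A,B),(C,D)); the oracle picks the
        # minimal-sum pairing among the three unrooted quartets
        ids = ["A", "B", "C", "D"]
        mat = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        pairings = [(("A", "B"), ("C", "D")), (("A", "C"), ("B", "D")), (("A", "D"), ("B", "C"))]
        idx = {t: i for i, t in enumerate(ids)}

        def pair_sum(p):
            (a, b), (c, d) = p
            return mat[idx[a], idx[b]] + mat[idx[c], idx[d]]

        oracle = min(pairings, key=pair_sum)
        # bipartitions are normalised to the side not containing taxon A
        expected = frozenset(oracle[1]) if "A" in oracle[0] else frozenset(oracle[0])
        tree = bionj(DistanceMatrix(ids, mat))
        assert bipartitions(tree) == {expected}

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_recovers_random_additive_topologies(self, n_taxa):
        rng = random.Random(1234 + n_taxa)
        for _ in range(200):
            taxa, mat, true_bips = random_additive_tree(n_taxa, rng)
            tree = bionj(DistanceMatrix(taxa, mat))
            assert bipartitions(tree) == true_bips

    def test_matches_reference_nj_on_additive_matrix(self):
        """Independent cross-check against scikit-bio's neighbor joining."""
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix as SkbioDM

        rng = random.Random(99)
        for _ in range(20):
            taxa, mat, true_bips = random_additive_tree(5, rng)
            ours = bipartitions(bionj(DistanceMatrix(taxa, mat)))
            ref = skbio_tree.nj(SkbioDM(mat, ids=taxa))
            ref_bips = set()
            names = set(taxa)
            refname = min(names)
            for node in ref.non_tips():
                below = frozenset(t.name for t in node.tips())
                if 1 < len(below) < len(names) - 1:
                    ref_bips.add(below if refname not in below else frozenset(names - below))
            assert ours == ref_bips == true_bips

    def test_ultrametric_matches_single_linkage(self):
        from scipy.cluster.hierarchy import linkage, fcluster
        from scipy.spatial.distance import squareform

        # ultrametric: two clear clusters {A,B,C} and {D,E}
        ids = list("ABCDE")
        mat = np.array(
            [
                [0, 2, 4, 10, 10],
                [2, 0, 4, 10, 10],
                [4, 4, 0, 10, 10],
                [10, 10, 10, 0, 3],
                [10, 10, 10, 3, 0],
            ],
            float,
        )
        labels = fcluster(linkage(squareform(mat), method="single"), t=2, criterion="maxclust")
        clusters = {frozenset(np.array(ids)[labels == k]) for k in set(labels)}
        tree_bips = bipartitions(bionj(DistanceMatrix(ids, mat)))
        # normalised away from A: {A,B}|{C,D,E} -> CDE, {D,E}|{A,B,C} -> DE
        assert {frozenset("CDE"), frozenset("DE")} <= tree_bips
        assert frozenset("DE") in clusters or frozenset("ABC") in clusters

    def test_fewer_than_three_taxa_error(self):
        with pytest.raises(ValueError):
            bionj(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))

    def test_deterministic_under_ties(self):
        mat = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("ABCD"), mat)
        assert bionj(dm).newick() == bionj(dm).newick()


def chain_mutant(base, k, rng):
    out = list(base)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    for i in rng.sample(range(len(out)), k):
        out[i] = rng.choice(aa)
    return "".join(out)


class TestBootstrap:
    @pytest.fixture
    def alignment(self):
        rng = random.Random(0)
        base = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(200))
        c = chain_mutant(base, 50, rng)
        d = chain_mutant(c, 50, rng)
        return [("A", base), ("B", base), ("C", c), ("D", d)]

    def test_identical_pair_cherry_support_100(self, alignment):
        tree = bootstrap_support(alignment, n_replicates=100, seed=1)
        node = next(
            n for n in tree.tree.preorder_node_iter()
            if not n.is_leaf()
            and {lf.taxon.label for lf in n.leaf_iter()} == {"A", "B"}
        )
        assert tree.support_of(node) == 100.0

    def test_single_replicate_supports_binary(self, alignment):
        tree = bootstrap_support(alignment, n_replicates=1, seed=5)
        sups = [
            tree.support_of(n)
            for n in tree.tree.preorder_node_iter()
            if not n.is_leaf() and n.label is not None
        ]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_seed_reproducibility(self, alignment):
        t1 = bootstrap_support(alignment, n_replicates=50, seed=11)
        t2 = bootstrap_support(alignment, n_replicates=50, seed=11)
        assert t1.newick() == t2.newick()

    def test_supports_invariant_to_leaf_order(self, alignment):
        t1 = bootstrap_support(alignment, n_replicates=50, seed=11)
        t2 = bootstrap_support(list(reversed(alignment)), n_replicates=50, seed=11)

        def support_map(t):
            return {
                frozenset(lf.taxon.label for lf in n.leaf_iter()): t.support_of(n)
                for n in t.tree.preorder_node_iter()
                if not n.is_leaf() and n.label is not None
            }

        assert support_map(t1) == support_map(t2)

    def test_short_alignment_error(self):
        with pytest.raises(ValueError):
            bootstrap_support([("a", "M"), ("b", "K"), ("c", "V")], n_replicates=10, seed=0)


class TestMidpointRoot:
    def test_longest_path_on_c_edge(self):
        rooted = midpoint_root(read_newick("((A:1,B:1):1,C:4);"))
        children = {
            frozenset(lf.taxon.label for lf in ch.leaf_iter()): ch.edge.length
            for ch in rooted.tree.seed_node.child_nodes()
        }
        assert children[frozenset("C")] == pytest.approx(3.0)
        assert children[frozenset("AB")] == pytest.approx(2.0)

    def test_symmetric_quartet_tie_break_deterministic(self):
        text = "((A:1,B:1):1,(C:1,D:1):1);"
        r1 = midpoint_root(read_newick(text))
        r2 = midpoint_root(read_newick(text))
        assert r1.newick() == r2.newick()

    def test_all_zero_lengths_warn(self):
        with pytest.warns(UserWarning, match="zero"):
            midpoint_root(read_newick("((A:0,B:0):0,C:0);"))
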