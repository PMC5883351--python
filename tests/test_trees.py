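import math

import dendropy
import numpy as np
import pytest

from plastmark import trees
from plastmark.errors import DistanceError, RootingError, SaturationError
from plastmark.trees import DistanceMatrix

from conftest import make_alignment, random_rooted_tree


def path_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Independent additive-matrix oracle: sum of branch lengths on tip paths."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(tuple(t.label for t in taxa), m)


def unrooted_bipartitions(tree: dendropy.Tree) -> set:
    return set(trees._bipartitions(tree))


class TestPairwiseDistance:
    def test_identical_sequences_zero(self):
        aln = make_alignment({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert trees.pairwise_distance(aln).matrix[0, 1] == 0.0

    def test_p_distance_quarter(self):
        aln = make_alignment({"a": "AAAA", "b": "AAAT"})
        assert trees.pairwise_distance(aln, "p").matrix[0, 1] == pytest.approx(0.25)

    def test_jc69_closed_form(self):
        aln = make_alignment({"a": "AAAA", "b": "AAAT"})
        d = trees.pairwise_distance(aln, "jc69").matrix[0, 1]
        assert d == pytest.approx(-0.75 * math.log(2 / 3), abs=1e-10)

    def test_pairwise_deletion_of_gaps_and_ambiguity(self):
        # only the last 2 columns are comparable; 1 mismatch among them
        aln = make_alignment({"a": "-NRAT", "b": "ACGAA"})
        assert trees.pairwise_distance(aln, "p").matrix[0, 1] == pytest.approx(0.5)

    def test_no_comparable_sites(self):
        aln = make_alignment({"a": "--AA", "b": "CC--"})
        with pytest.raises(DistanceError):
            trees.pairwise_distance(aln)

    def test_jc69_saturation(self):
        aln = make_alignment({"a": "AAAA", "b": "CCCT"})
        with pytest.raises(SaturationError):
            trees.pairwise_distance(aln, "jc69")


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 0.3], [0.3, 0.0]]))
        t = trees.neighbor_joining(dm)
        total = sum(
            nd.edge.length for nd in t.preorder_node_iter() if nd.parent_node
        )
        assert total == pytest.approx(0.3)

    def test_exact_on_known_additive_quartet(self):
        # ((A:0.1,B:0.2):0.3,(C:0.4,D:0.5)); path sums give the matrix
        nw = "((A:0.1,B:0.2):0.3,C:0.4,D:0.5);"
        src = dendropy.Tree.get(data=nw, schema="newick")
        dm = path_distance_matrix(src)
        t = trees.neighbor_joining(dm)
        assert unrooted_bipartitions(t) == unrooted_bipartitions(src)
        back = path_distance_matrix(t)
        assert np.allclose(back.matrix, dm.matrix, atol=1e-12)

    def test_exact_on_random_additive_matrices(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 11))
            src = random_rooted_tree(rng, n, scale=0.1)
            src.is_rooted = False
            dm = path_distance_matrix(src)
            t = trees.neighbor_joining(dm)
            assert unrooted_bipartitions(t) == unrooted_bipartitions(src)
            assert np.allclose(
                path_distance_matrix(t).matrix, dm.matrix, atol=1e-9
            )

    def test_taxon_order_invariance(self, rng):
        src = random_rooted_tree(rng, 7, scale=0.2)
        dm = path_distance_matrix(src)
        perm = list(rng.permutation(len(dm.taxa)))
        dm2 = DistanceMatrix(
            tuple(dm.taxa[i] for i in perm), dm.matrix[np.ix_(perm, perm)]
        )
        t1 = trees.neighbor_joining(dm)
        t2 = trees.neighbor_joining(dm2)
        assert unrooted_bipartitions(t1) == unrooted_bipartitions(t2)


class TestBootstrap:
    def test_deterministic_under_seed(self, rng):
        from conftest import random_alignment

        aln = random_alignment(rng, 6, 120, alphabet="ACGT")
        t1 = trees.bootstrap_support(aln, reps=10, seed=5)
        t2 = trees.bootstrap_support(aln, reps=10, seed=5)
        assert trees.write_newick(t1) == trees.write_newick(t2)

    def test_constant_alignment_gives_unit_supports(self):
        aln = make_alignment(
            {"a": "AC" * 30, "b": "AC" * 30, "c": "AG" * 30, "d": "AG" * 30}
        )
        t = trees.bootstrap_support(aln, reps=20, seed=1)
        sups = [
            trees.get_support(nd)
            for nd in t.postorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        assert sups and all(s == 1.0 for s in sups)

    def test_species_split_strongly_supported(self):
        from plastmark.simulate import simulate_alignment, simulate_tree

        truth = simulate_tree(2, 4, 50, 2500, seed=4)
        aln, _ = simulate_alignment(truth, 3000, 1.0, seed=5)
        t = trees.bootstrap_support(aln, reps=50, seed=6)
        sp1 = frozenset(a for a, s in truth.species_map.items() if s == "sp01")
        all_tips = frozenset(truth.species_map)
        key = sp1 if min(all_tips) not in sp1 else all_tips - sp1
        node = trees._bipartitions(t)[key]
        assert trees.get_support(node) >= 0.9


class TestRooting:
    def test_root_write_read_round_trip(self, rng):
        src = random_rooted_tree(rng, 6, scale=0.3)
        src.is_rooted = False
        rooted = trees.root_with_outgroup(src, ["t0"])
        nwk = trees.write_newick(rooted)
        back = trees.read_newick(nwk, rooted=True)
        assert unrooted_bipartitions(back) == unrooted_bipartitions(rooted)
        d1 = path_distance_matrix(rooted)
        d2 = path_distance_matrix(back)
        assert np.allclose(d1.matrix, d2.matrix, rtol=1e-6)

    def test_single_tip_outgroup_always_roots(self, rng):
        src = random_rooted_tree(rng, 5)
        src.is_rooted = False
        rooted = trees.root_with_outgroup(src, ["t3"])
        kids = rooted.seed_node.child_nodes()
        sides = [frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids]
        assert frozenset({"t3"}) in sides

    def test_scattered_outgroup_rejected(self):
        nw = "((A:1,B:1):1,(C:1,D:1):1);"
        t = dendropy.Tree.get(data=nw, schema="newick")
        with pytest.raises(RootingError):
            trees.root_with_outgroup(t, ["A", "C"])

    def test_total_length_invariant_under_rerooting(self, rng):
        src = random_rooted_tree(rng, 8, scale=0.2)
        src.is_rooted = False

        def total(t):
            return sum(
                nd.edge.length or 0.0
                for nd in t.preorder_node_iter()
                if nd.parent_node
            )

        t_a = trees.root_with_outgroup(src, ["t1"])
        t_b = trees.root_with_outgroup(src, ["t5"])
        assert total(t_a) == pytest.approx(total(src), rel=1e-9)
        assert total(t_b) == pytest.approx(total(src), rel=1e-9)


def test_newick_support_labels_preserved(tmp_path):
    nw = "((A:0.1,B:0.2)0.93:0.3,(C:0.1,D:0.2)0.81:0.4);"
    t = trees.read_newick(nw)
    out = trees.write_newick(t)
    assert "0.93" in out and "0.81" in out
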