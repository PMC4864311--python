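"""Gap handling, identities, Poisson distances, NJ and bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from conftest import conflict_free_quartet
from oracles import best_ls_topology_fast, random_additive_matrix
from uvkit.errors import DomainError, InputError, SaturationError
from uvkit.molevol import (
    DistanceMatrix,
    ProteinAlignment,
    bootstrap_support,
    group_identity_stats,
    leaf_bipartitions,
    nj_tree,
    pairwise_identity,
    poisson_distance,
    poisson_distance_matrix,
    strip_gap_columns,
    tree_distance_matrix,
)


class TestAlignmentValidation:
    def test_duplicate_names_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            ProteinAlignment(("a", "a"), ("ACD", "ACD"))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InputError, match="unequal"):
            ProteinAlignment(("a", "b"), ("ACD", "ACDE"))

    def test_invalid_characters_rejected(self):
        with pytest.raises(InputError, match="invalid"):
            ProteinAlignment(("a",), ("AC*",))


class TestStripGapColumns:
    def test_complete_deletion(self):
        aln = ProteinAlignment(("a", "b"), ("ACD-E", "ACDFE"))
        out = strip_gap_columns(aln)
        assert out.rows == ("ACDE", "ACDE")
        assert out.column_mask == (3,)

    def test_x_treated_as_missing(self):
        aln = ProteinAlignment(("a", "b"), ("AXDEF", "ACDEF"))
        out = strip_gap_columns(aln)
        assert out.rows == ("ADEF", "ADEF")
        assert out.column_mask == (1,)

    def test_gap_free_identity(self):
        aln = ProteinAlignment(("a", "b"), ("ACDEF", "ACDEY"))
        out = strip_gap_columns(aln)
        assert out.rows == aln.rows
        assert out.column_mask == ()

    def test_fully_gapped_gives_empty(self):
        aln = ProteinAlignment(("a", "b"), ("A-", "-C"))
        assert strip_gap_columns(aln).n_columns == 0


class TestIdentity:
    def test_identical_rows(self):
        aln = ProteinAlignment(("a", "b"), ("ACDEF", "ACDEF"))
        assert pairwise_identity(aln, "a", "b") == 1.0

    def test_four_of_five(self):
        aln = ProteinAlignment(("a", "b"), ("ACDEF", "ACDEY"))
        assert pairwise_identity(aln, 0, 1) == pytest.approx(0.8)

    def test_global_vs_pair_exclusion(self):
        # a third gapped sequence shrinks the global comparison but not the
        # pairwise one
        aln = ProteinAlignment(("a", "b", "c"), ("ACDEF", "ACDEY", "AC--F"))
        assert pairwise_identity(aln, "a", "b", exclusion="global") == pytest.approx(
            2.0 / 3.0
        )
        assert pairwise_identity(aln, "a", "b", exclusion="pair") == pytest.approx(0.8)

    def test_no_comparable_columns(self):
        aln = ProteinAlignment(("a", "b"), ("A-", "-C"))
        with pytest.raises(InputError):
            pairwise_identity(aln, "a", "b")

    def test_group_stats_closed_form(self):
        # members at exact identities 0.4 / 0.5 / 0.6 to the target
        aln = ProteinAlignment(
            ("t", "g1", "g2", "g3"),
            (
                "AAAAAAAAAA",
                "AAAACCCCCC",
                "AAAAACCCCC",
                "AAAAAACCCC",
            ),
        )
        mean, sd, n = group_identity_stats(aln, "t", {"g1", "g2", "g3"})
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(0.1)
        assert n == 3

    def test_group_of_one(self):
        aln = ProteinAlignment(("t", "g"), ("ACDEF", "ACDEF"))
        mean, sd, n = group_identity_stats(aln, "t", {"g"})
        assert (mean, sd, n) == (1.0, 0.0, 1)

    def test_empty_group_rejected(self):
        aln = ProteinAlignment(("t", "g"), ("ACDEF", "ACDEF"))
        with pytest.raises(InputError):
            group_identity_stats(aln, "t", set())


class TestPoissonDistance:
    def test_exact_values(self):
        assert poisson_distance(0.0) == 0.0
        assert poisson_distance(0.5) == pytest.approx(-math.log(0.5), abs=1e-12)
        # the identity level of a 68.2%-identical pair
        assert poisson_distance(0.318) == pytest.approx(-math.log(0.682), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(SaturationError):
            poisson_distance(1.0)
        with pytest.raises(DomainError):
            poisson_distance(-0.1)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 0.999))
    def test_dominates_p_and_increases(self, p):
        d = poisson_distance(p)
        assert d >= p
        assert (d == 0) == (p == 0)
        assert poisson_distance(min(p + 1e-3, 0.9995)) > d

    def test_matrix_values_and_shape(self):
        aln = ProteinAlignment(("a", "b", "c"), ("ACDEF", "ACDEY", "ACDEF"))
        dm = poisson_distance_matrix(aln)
        assert dm.matrix[0, 2] == 0.0
        assert dm.matrix[0, 1] == pytest.approx(-math.log(0.8))
        np.testing.assert_array_equal(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)

    def test_saturated_pair_named(self):
        aln = ProteinAlignment(("a", "b"), ("AAAA", "CCCC"))
        with pytest.raises(SaturationError, match="'a'.*'b'"):
            poisson_distance_matrix(aln)


def _additive_example():
    # path distances of the tree ((A:1,B:2):1,(C:1,D:3))
    names = ("A", "B", "C", "D")
    D = np.array(
        [
            [0.0, 3.0, 3.0, 5.0],
            [3.0, 0.0, 4.0, 6.0],
            [3.0, 4.0, 0.0, 4.0],
            [5.0, 6.0, 4.0, 0.0],
        ]
    )
    return DistanceMatrix(names, D)


class TestNeighborJoining:
    def test_additive_quartet_recovered_exactly(self):
        dm = _additive_example()
        tree = nj_tree(dm)
        assert leaf_bipartitions(tree) == {frozenset({"C", "D"})}
        recon = tree_distance_matrix(tree, list(dm.names))
        np.testing.assert_allclose(recon.matrix, dm.matrix, atol=1e-12)
        # terminal branch lengths of the generating tree
        blen = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert blen == pytest.approx({"A": 1.0, "B": 2.0, "C": 1.0, "D": 3.0})

    def test_three_taxa_three_point_formulas(self):
        dm = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0.0, 2.0, 3.0], [2.0, 0.0, 4.0], [3.0, 4.0, 0.0]]),
        )
        tree = nj_tree(dm)
        blen = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert blen == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})
        recon = tree_distance_matrix(tree, list(dm.names))
        np.testing.assert_allclose(recon.matrix, dm.matrix, atol=1e-12)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(InputError):
            nj_tree(DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_ultrametric_matches_single_linkage(self):
        names = ("A", "B", "C", "D")
        D = np.array(
            [
                [0.0, 2.0, 6.0, 6.0],
                [2.0, 0.0, 6.0, 6.0],
                [6.0, 6.0, 0.0, 4.0],
                [6.0, 6.0, 4.0, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(names, D))
        Z = linkage(squareform(D), method="single")
        clusters = fcluster(Z, t=2, criterion="maxclust")
        groups = {
            frozenset(np.array(names)[clusters == c]) for c in set(clusters)
        }
        nontrivial = {g for g in groups if 2 <= len(g) <= 2}
        assert leaf_bipartitions(tree) <= {
            g if "A" not in g else frozenset(names) - g for g in nontrivial
        } | {frozenset({"C", "D"})}
        assert leaf_bipartitions(tree) == {frozenset({"C", "D"})}

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_exhaustive_least_squares(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(10):
            D, true_bips = random_additive_matrix(rng, n)
            names = tuple(str(i) for i in range(n))
            tree = nj_tree(DistanceMatrix(names, D))
            got = {
                frozenset(int(x) for x in bp) for bp in leaf_bipartitions(tree)
            }
            oracle_bips, sse = best_ls_topology_fast(D)
            assert got == oracle_bips == true_bips
            recon = tree_distance_matrix(tree, list(names))
            assert np.abs(recon.matrix - D).max() < 1e-9

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(17)
        D, _ = random_additive_matrix(rng, 6)
        names = [f"t{i}" for i in range(6)]
        mine = nj_tree(DistanceMatrix(tuple(names), D))
        sk = sknj(skbio.DistanceMatrix(D, names))
        allset = frozenset(names)
        anchor = min(allset)
        sk_bips = set()
        for node in sk.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = allset - side
            if 2 <= len(side) <= 4:
                sk_bips.add(side)
        assert sk_bips == leaf_bipartitions(mine)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        aln = conflict_free_quartet()
        t1 = bootstrap_support(aln, B=50, seed=7)
        t2 = bootstrap_support(aln, B=50, seed=7)
        assert t1.bipartition_support == t2.bipartition_support

    def test_conflict_free_signal_gives_full_support(self):
        aln = conflict_free_quartet(n_columns=200, seed=0)
        tree = bootstrap_support(aln, B=100, seed=1)
        assert tree.bipartition_support == {frozenset({"C", "D"}): 100.0}
        labels = [
            node.label
            for node in tree.preorder_node_iter()
            if not node.is_leaf() and node.parent_node is not None
        ]
        assert "100" in labels

    def test_invalid_inputs(self):
        aln = conflict_free_quartet()
        with pytest.raises(InputError):
            bootstrap_support(aln, B=0)
        tiny = ProteinAlignment(("a", "b", "c"), ("A", "A", "C"))
        with pytest.raises(InputError):
            bootstrap_support(tiny, B=10)
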