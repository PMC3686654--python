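"""Distances, Neighbor-Joining, bootstrap, Newick round-trips."""

import math

import dendropy
import numpy as np
import pytest

from oracles import random_additive_tree
from repatlas.phylo import (
    Alignment,
    DistanceMatrix,
    bootstrap,
    concatenate,
    distance,
    distance_matrix,
    internal_splits,
    nj_tree,
    read_newick,
    write_newick,
)


class TestDistance:
    def test_p_distance(self):
        assert distance("AAAA", "AAAT", model="p") == 0.25

    def test_identical_rows_zero(self):
        assert distance("ACGT", "ACGT", model="p") == 0.0
        assert distance("ACGT", "ACGT", model="JC") == 0.0

    def test_jc_closed_form(self):
        # p = 0.25 -> -(3/4) ln(1 - 1/3)
        expected = -0.75 * math.log(2 / 3)
        assert distance("AAAA", "AAAT", model="JC") == pytest.approx(expected)
        assert expected == pytest.approx(0.304099, abs=1e-6)

    def test_gap_and_n_sites_excluded_pairwise(self):
        assert distance("AA-N", "AATT", model="p") == 0.0

    def test_zero_comparable_sites(self):
        with pytest.raises(ValueError, match="comparable"):
            distance("----", "AAAA")

    def test_saturation(self):
        with pytest.raises(ValueError, match="saturation"):
            distance("AAAA", "TTTT", model="JC")

    def test_jc_exceeds_p(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=100))
            b = "".join(rng.choice(list("ACGT"), size=100))
            p = distance(a, b, model="p")
            if 0 < p < 0.75:
                assert distance(a, b, model="JC") > p


class TestConcatenate:
    def test_lengths_add(self):
        g1 = Alignment(["a", "b"], ["ACGTACGTAC", "ACGTACGTAC"])
        g2 = Alignment(["b", "a"], ["A" * 20, "C" * 20])
        cat = concatenate([g1, g2], ["a", "b"])
        assert cat.length == 30
        assert cat.row("a") == "ACGTACGTAC" + "C" * 20

    def test_single_gene_identity(self):
        g = Alignment(["a", "b"], ["ACGT", "ACGA"])
        assert concatenate([g], ["a", "b"]).rows == g.rows

    def test_missing_taxon(self):
        g1 = Alignment(["a", "b"], ["ACGT", "ACGA"])
        g2 = Alignment(["a"], ["ACGT"])
        with pytest.raises(ValueError, match="b"):
            concatenate([g1, g2], ["a", "b"])


WORKED_TAXA = ["A", "B", "C", "D"]
WORKED_D = np.array(
    [
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ],
    dtype=float,
)


def _leaf_edge_lengths(tree):
    return {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        """Additive matrix from ((A:1,B:2):1,(C:3,D:4)): NJ must return the
        AB|CD split with internal edge 1 and leaf edges 1,2,3,4."""
        tree = nj_tree(DistanceMatrix(WORKED_TAXA, WORKED_D))
        splits = internal_splits(tree)
        assert len(splits) == 1
        (side, node), = splits.items()
        assert side in (frozenset({"C", "D"}), frozenset({"A", "B"}))
        assert node.edge.length == pytest.approx(1.0)
        assert _leaf_edge_lengths(tree) == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        )

    def test_three_taxon_exact(self):
        d = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(d)
        assert _leaf_edge_lengths(tree) == pytest.approx({"a": 1.0, "b": 1.0, "c": 3.0})

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_recovers_random_additive_trees(self, rng):
        """NJ is consistent on additive matrices: the generating topology is
        recovered exactly for >=100 random trees with 4-6 leaves."""
        for trial in range(100):
            n = int(rng.integers(4, 7))
            labels, dmat, true_splits = random_additive_tree(rng, n)
            values = np.array([[dmat[a][b] for b in labels] for a in labels])
            tree = nj_tree(DistanceMatrix(labels, values))
            assert set(internal_splits(tree)) == true_splits, trial

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        for trial in range(10):
            labels, dmat, _ = random_additive_tree(rng, 6)
            values = np.array([[dmat[a][b] for b in labels] for a in labels])
            values = (values + values.T) / 2  # exact symmetry for skbio
            ours = set(internal_splits(nj_tree(DistanceMatrix(labels, values))))
            sk_tree = skbio_nj(skbio.DistanceMatrix(values, labels))
            newick = sk_tree.__str__()
            theirs = set(internal_splits(read_newick(newick)))
            assert ours == theirs


def _two_clade_alignment(n_diag=100):
    """Two clearly separated 3-taxon groups with diagnostic columns."""
    base = "ACGT" * 30
    group1 = base + "A" * n_diag
    group2 = base + "T" * n_diag
    taxa = ["a1", "a2", "a3", "b1", "b2", "b3"]
    rows = [group1, group1, group1, group2, group2, group2]
    # small private differences so the within-clade splits resolve
    rows = [
        r[:i] + c + r[i + 1:]
        for (r, (i, c)) in zip(rows, [(0, "C"), (1, "G"), (2, "T"),
                                      (3, "A"), (4, "C"), (5, "G")])
    ]
    return Alignment(taxa, rows)


class TestBootstrap:
    def test_identical_rows_star(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGT" * 5] * 4)
        tree = bootstrap(aln, b=10, seed=1)
        assert internal_splits(tree) == {}

    def test_separated_clades_full_support(self):
        tree = bootstrap(_two_clade_alignment(), b=50, seed=3)
        supports = [int(n.label) for n in internal_splits(tree).values()]
        assert supports  # at least the clade split
        clade_split = internal_splits(tree)[frozenset({"b1", "b2", "b3"})]
        assert int(clade_split.label) == 100

    def test_seed_determinism(self):
        aln = _two_clade_alignment()
        t1 = write_newick(bootstrap(aln, b=20, seed=5))
        t2 = write_newick(bootstrap(aln, b=20, seed=5))
        assert t1 == t2

    def test_taxon_order_invariance(self):
        aln = _two_clade_alignment()
        order = [3, 0, 4, 1, 5, 2]
        shuffled = Alignment([aln.taxa[i] for i in order], [aln.rows[i] for i in order])
        s1 = {k: n.label for k, n in internal_splits(bootstrap(aln, b=20, seed=7)).items()}
        s2 = {k: n.label for k, n in internal_splits(bootstrap(shuffled, b=20, seed=7)).items()}
        assert set(s1) == set(s2)
        assert s1[frozenset({"b1", "b2", "b3"})] == s2[frozenset({"b1", "b2", "b3"})]


class TestNewick:
    def test_three_leaf_star_shape(self):
        d = DistanceMatrix(["A", "B", "C"], np.array(
            [[0, 2, 2], [2, 0, 2], [2, 2, 0]], float))
        text = write_newick(nj_tree(d))
        assert text.count("(") == 1 and text.strip().endswith(";")

    def test_round_trip(self, rng):
        for _ in range(5):
            labels, dmat, _ = random_additive_tree(rng, 5)
            values = np.array([[dmat[a][b] for b in labels] for a in labels])
            tree = nj_tree(DistanceMatrix(labels, values))
            back = read_newick(write_newick(tree))
            assert set(internal_splits(back)) == set(internal_splits(tree))

    def test_supports_on_internal_nodes_only(self):
        tree = bootstrap(_two_clade_alignment(), b=10, seed=2)
        text = write_newick(tree)
        back = read_newick(text)
        for leaf in back.leaf_node_iter():
            assert leaf.taxon.label in {"a1", "a2", "a3", "b1", "b2", "b3"}
        labels = [n.label for n in internal_splits(back).values()]
        assert all(l is None or l.isdigit() for l in labels)
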