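"""Neighbor joining, bootstrap supports, and newick export."""

import itertools

import dendropy
import numpy as np
import pytest

from amplihap.phylo import (
    DistanceMatrix,
    attach_supports,
    bootstrap_supports,
    nj_tree,
    pdistance_matrix,
    to_newick,
    write_newick,
)


def additive_matrix_4taxa():
    """Distances of the tree ((A:1,B:2):1,(C:3,D:4))."""
    labels = ("A", "B", "C", "D")
    d = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
         ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
    vals = np.zeros((4, 4))
    for (x, y), v in d.items():
        i, j = labels.index(x), labels.index(y)
        vals[i, j] = vals[j, i] = v
    return DistanceMatrix(labels, vals), d


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        vals = np.array([[0, 1.0, 2], [1.1, 0, 3], [2, 3, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b", "c"), vals)

    def test_negative_values_rejected(self):
        vals = np.array([[0, -1.0], [-1.0, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), vals)

    def test_nonzero_diagonal_rejected(self):
        vals = np.array([[0.1, 1.0], [1.0, 0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(("a", "b"), vals)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        vals = np.array([[0, 3.0, 4], [3, 0, 5], [4, 5, 0]])
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), vals))
        dists = tree.leaf_distances()
        assert dists[("A", "B")] == pytest.approx(3)
        assert dists[("A", "C")] == pytest.approx(4)
        assert dists[("B", "C")] == pytest.approx(5)
        lengths = {leaf.label: leaf.length for leaf in tree.root.leaves()}
        assert lengths == {"A": pytest.approx(1), "B": pytest.approx(2), "C": pytest.approx(3)}

    def test_additive_four_taxon_round_trip(self):
        matrix, d = additive_matrix_4taxa()
        tree = nj_tree(matrix)
        assert frozenset({"C", "D"}) in tree.splits()
        dists = tree.leaf_distances()
        for (x, y), v in d.items():
            assert dists[(x, y)] == pytest.approx(v)

    def test_ultrametric_matrix_matches_single_linkage(self):
        # heights: (A,B) join at 1, +C at 2, +D at 3
        labels = ("A", "B", "C", "D")
        vals = np.array(
            [[0, 2.0, 4, 6], [2, 0, 4, 6], [4, 4, 0, 6], [6, 6, 6, 0]]
        )
        tree = nj_tree(DistanceMatrix(labels, vals))
        assert frozenset({"C", "D"}) in tree.splits() or frozenset({"A", "B"}) in tree.splits()
        dists = tree.leaf_distances()
        assert dists[("A", "B")] == pytest.approx(2)

    def test_agrees_with_skbio_on_random_additive_matrices(self, rng):
        """Independent oracle: scikit-bio's NJ on the same matrices."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        labels = tuple("ABCDEF")
        for trial in range(5):
            # additive matrix from the binary tree
            # (((A:a,B:b):e1,C:c):g,((E:e,F:f):e2,D:d)) with random lengths
            a, b, c, d, e, f, e1, e2, g = rng.uniform(0.5, 3.0, size=9)
            paths = {
                ("A", "B"): a + b,
                ("A", "C"): a + e1 + c,
                ("B", "C"): b + e1 + c,
                ("A", "D"): a + e1 + g + d,
                ("B", "D"): b + e1 + g + d,
                ("C", "D"): c + g + d,
                ("A", "E"): a + e1 + g + e2 + e,
                ("B", "E"): b + e1 + g + e2 + e,
                ("C", "E"): c + g + e2 + e,
                ("D", "E"): d + e2 + e,
                ("A", "F"): a + e1 + g + e2 + f,
                ("B", "F"): b + e1 + g + e2 + f,
                ("C", "F"): c + g + e2 + f,
                ("D", "F"): d + e2 + f,
                ("E", "F"): e + f,
            }
            vals = np.zeros((6, 6))
            for (x, y), v in paths.items():
                i, j = labels.index(x), labels.index(y)
                vals[i, j] = vals[j, i] = v
            mine = nj_tree(DistanceMatrix(labels, vals))
            theirs = skbio_nj(SkbioDM(vals, ids=list(labels)))
            their_splits = set()
            for node in theirs.non_tips():
                below = frozenset(t.name for t in node.tips())
                if 1 < len(below) < 5:
                    side = below if "A" not in below else frozenset(labels) - below
                    their_splits.add(side)
            assert set(mine.splits()) == their_splits

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0, 1.0], [1.0, 0]])))


def two_clade_alignment(rng, n_fixed=20, length=120):
    """Two 2-taxon clades separated by n_fixed fixed differences."""
    base = rng.choice(list("ACGT"), size=length)
    clade2 = base.copy()
    sites = rng.choice(length, size=n_fixed, replace=False)
    for s in sites:
        clade2[s] = "A" if clade2[s] != "A" else "G"
    seqs = {}
    for name, template in (("A1", base), ("A2", base), ("B1", clade2), ("B2", clade2)):
        variant = template.copy()
        # one private difference each so the matrix is non-degenerate
        site = rng.integers(length)
        variant[site] = "C" if variant[site] != "C" else "T"
        seqs[name] = "".join(variant)
    return seqs


class TestBootstrap:
    def test_strong_split_has_high_support(self, rng):
        seqs = two_clade_alignment(rng)
        supports = bootstrap_supports(seqs, n_replicates=200, seed=5)
        split = frozenset({"B1", "B2"})
        assert split in supports
        assert supports[split] >= 95

    def test_identical_sequences_yield_no_supported_edges(self):
        seqs = {k: "ACGT" * 30 for k in ("a", "b", "c", "d")}
        assert bootstrap_supports(seqs, n_replicates=20, seed=1) == {}

    def test_same_seed_reproducible(self, rng):
        seqs = two_clade_alignment(rng, n_fixed=6)
        s1 = bootstrap_supports(seqs, n_replicates=100, seed=9)
        s2 = bootstrap_supports(seqs, n_replicates=100, seed=9)
        assert s1 == s2

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            bootstrap_supports({"a": "ACGT", "b": "ACG"}, n_replicates=5, seed=0)


class TestNewick:
    def test_three_taxon_single_line(self):
        vals = np.array([[0, 3.0, 4], [3, 0, 5], [4, 5, 0]])
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), vals))
        text = to_newick(tree)
        assert text.endswith(";")
        assert "\n" not in text

    def test_round_trip_is_isomorphic(self, tmp_path, rng):
        matrix, d = additive_matrix_4taxa()
        tree = nj_tree(matrix)
        path = write_newick(tree, tmp_path / "t.nwk")
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for (x, y), v in d.items():
            assert pdm.patristic_distance(taxa[x], taxa[y]) == pytest.approx(v, abs=1e-9)

    def test_support_appears_as_internal_label(self, rng):
        seqs = two_clade_alignment(rng)
        tree = nj_tree(pdistance_matrix(seqs, aligned=True))
        attach_supports(tree, {frozenset({"B1", "B2"}): 87.0})
        assert ")87:" in to_newick(tree)

    def test_reserved_characters_quoted(self):
        labels = ("iso A", "iso(B)", "isoC")
        vals = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        tree = nj_tree(DistanceMatrix(labels, vals))
        text = to_newick(tree)
        assert "'iso A'" in text and "'iso(B)'" in text
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == {"iso A", "iso(B)", "isoC"}
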