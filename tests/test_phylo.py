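"""Neighbor joining, bipartitions, monophyly, tree and matrix I/O."""

import numpy as np
import pytest

from capsidphylo.phylo import (DistanceMatrix, build_distance_matrix,
                               is_monophyletic, neighbor_joining, read_newick,
                               read_phylip, robinson_foulds, write_newick,
                               write_phylip)
from capsidphylo.simulate import make_additive_matrix, random_tree

from oracles import newick_splits


def _split_lengths(tree):
    """(bipartition -> branch length) for every edge, pendant edges keyed by
    their singleton leaf set."""
    leaves = tree.leaf_labels
    ref = min(leaves)
    out = {}
    below = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(
                *(below[c] for c in node.child_nodes()))
        if node is tree.tree.seed_node:
            continue
        side = below[node]
        if node.is_leaf():
            canon = side  # pendant edges keyed by their leaf
        else:
            canon = side if ref not in side else leaves - side
        out[canon] = node.edge.length
    return out


THREE_TAXON = DistanceMatrix(
    ["A", "B", "C"], np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0.0]]))
FOUR_TAXON = DistanceMatrix(
    ["A", "B", "C", "D"],
    np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0.0]]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        tree = neighbor_joining(THREE_TAXON)
        lengths = _split_lengths(tree)
        assert lengths[frozenset({"A"})] == pytest.approx(1.0, abs=1e-12)
        assert lengths[frozenset({"B"})] == pytest.approx(2.0, abs=1e-12)
        assert lengths[frozenset({"C"})] == pytest.approx(4.0, abs=1e-12)

    def test_four_taxon_additive_matrix(self):
        tree = neighbor_joining(FOUR_TAXON)
        splits = tree.splits()
        # split AB|CD, canonicalized as the side excluding leaf A
        assert splits == {frozenset({"C", "D"})}
        lengths = _split_lengths(tree)
        assert lengths[frozenset({"C", "D"})] == pytest.approx(1.0, abs=1e-12)
        assert lengths[frozenset({"A"})] == pytest.approx(1.0, abs=1e-12)
        assert lengths[frozenset({"B"})] == pytest.approx(2.0, abs=1e-12)
        assert lengths[frozenset({"C"})] == pytest.approx(3.0, abs=1e-12)
        assert lengths[frozenset({"D"})] == pytest.approx(4.0, abs=1e-12)

    def test_equidistant_taxa_tie_break_is_deterministic(self):
        d = DistanceMatrix(list("ABCD"), 2.0 * (1 - np.eye(4)))
        t1 = neighbor_joining(d)
        t2 = neighbor_joining(d)
        assert write_newick(t1) == write_newick(t2)
        lengths = _split_lengths(t1)
        internal = [v for k, v in lengths.items() if len(k) > 1]
        assert internal == [pytest.approx(0.0, abs=1e-12)]

    def test_exact_recovery_on_random_additive_matrices(self, rng):
        for _ in range(60):
            true = random_tree(int(rng.integers(4, 13)), rng,
                               blen_range=(0.1, 5.0))
            rec = neighbor_joining(make_additive_matrix(true))
            assert robinson_foulds(true, rec) == 0
            lt, lr = _split_lengths(true), _split_lengths(rec)
            for split, length in lt.items():
                assert lr[split] == pytest.approx(length, abs=1e-9)

    def test_permutation_invariance(self, rng):
        true = random_tree(8, rng)
        d = make_additive_matrix(true)
        perm = list(d.labels)
        rng.shuffle(perm)
        t1 = neighbor_joining(d)
        t2 = neighbor_joining(d.permuted(perm))
        assert robinson_foulds(t1, t2) == 0

    def test_no_negative_branch_lengths(self, rng):
        # noisy non-additive matrices are where NJ goes negative
        for _ in range(20):
            true = random_tree(7, rng, blen_range=(0.1, 1.0))
            d = make_additive_matrix(true)
            noisy = d.values + rng.normal(0, 0.2, d.values.shape)
            noisy = np.abs(0.5 * (noisy + noisy.T))
            np.fill_diagonal(noisy, 0.0)
            tree = neighbor_joining(DistanceMatrix(d.labels, noisy))
            for edge in tree.tree.edges():
                if edge.length is not None:
                    assert edge.length >= 0.0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            neighbor_joining(DistanceMatrix(["A", "B"],
                                            np.array([[0, 1], [1, 0.0]])))


class TestDistanceMatrix:
    def test_asymmetric_input_rejected(self):
        vals = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B", "C"], vals)

    def test_nan_rejected_with_pair_named(self):
        vals = np.zeros((3, 3))
        vals[0, 2] = vals[2, 0] = np.nan
        with pytest.raises(ValueError, match="'A'"):
            DistanceMatrix(["A", "B", "C"], vals)

    def test_zero_matrix_from_identical_traces(self):
        from capsidphylo.align import multiple_superpose
        from capsidphylo.simulate import simulate_backbone
        from capsidphylo.structure_io import CoreTrace
        base = simulate_backbone(50, 11)
        traces = [CoreTrace(lab, base.positions, base.residue_tags)
                  for lab in ("x", "y", "z")]
        d = build_distance_matrix(multiple_superpose(traces))
        assert np.abs(d.values).max() < 1e-9


class TestMonophyly:
    TREE = read_newick("((A:1,B:1):1,(C:1,D:1):1);")

    def test_cherry_is_monophyletic(self):
        assert is_monophyletic(self.TREE, {"A", "B"})

    def test_non_clade_pair_is_not(self):
        assert not is_monophyletic(self.TREE, {"A", "C"})

    def test_whole_leaf_set_is_trivially_monophyletic(self):
        assert is_monophyletic(self.TREE, {"A", "B", "C", "D"})

    def test_unknown_label_is_an_error(self):
        with pytest.raises(ValueError, match="unknown"):
            is_monophyletic(self.TREE, {"A", "Q"})

    def test_nested_clades_in_caterpillar(self):
        tree = read_newick("(((A:1,B:1):1,C:1):1,D:1,E:1);")
        assert is_monophyletic(tree, {"A", "B"})
        assert is_monophyletic(tree, {"A", "B", "C"})


class TestRobinsonFoulds:
    def test_identical_trees_distance_zero(self, rng):
        t = random_tree(9, rng)
        assert robinson_foulds(t, t) == 0

    def test_conflicting_quartets_distance_two(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(t1, t2) == 2

    def test_against_split_enumeration_oracle(self, rng):
        for _ in range(10):
            t1 = random_tree(10, rng)
            t2 = random_tree(10, rng)
            expected = len(newick_splits(write_newick(t1))
                           ^ newick_splits(write_newick(t2)))
            assert robinson_foulds(t1, t2) == expected

    def test_leaf_set_mismatch_rejected(self, rng):
        t1 = random_tree(5, rng)
        t2 = random_tree(6, rng)
        with pytest.raises(ValueError, match="differ"):
            robinson_foulds(t1, t2)


class TestSerialization:
    def test_newick_round_trip(self):
        tree = neighbor_joining(FOUR_TAXON)
        back = read_newick(write_newick(tree))
        assert robinson_foulds(tree, back) == 0
        lt, lb = _split_lengths(tree), _split_lengths(back)
        for split, length in lt.items():
            assert lb[split] == pytest.approx(length, rel=1e-6)

    def test_newick_split_reading(self):
        tree = read_newick("(A:1,B:2,(C:3,D:4):1);")
        assert tree.splits() == {frozenset({"C", "D"})}

    def test_malformed_newick_raises_parse_error(self):
        with pytest.raises(ValueError, match="malformed"):
            read_newick("(A:1,B:2")

    def test_phylip_round_trip(self):
        text = write_phylip(FOUR_TAXON)
        back = read_phylip(text)
        assert back.labels == FOUR_TAXON.labels
        np.testing.assert_allclose(back.values, FOUR_TAXON.values, atol=1e-9)

    def test_phylip_rejects_truncated_body(self):
        with pytest.raises(ValueError, match="tokens"):
            read_phylip("3\nA 0 1 2\nB 1 0 3\n")

    def test_csv_round_trip(self):
        back = DistanceMatrix.from_csv(FOUR_TAXON.to_csv())
        assert back.labels == FOUR_TAXON.labels
        np.testing.assert_allclose(back.values, FOUR_TAXON.values)
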