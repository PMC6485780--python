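import numpy as np
import pytest

import dendropy

from taxogen.msa import DistanceMatrix
from taxogen.phylo import (bootstrap_supports, neighbor_joining, to_newick,
                           tree_distance_matrix)
from taxogen.synthetic import two_clade_alignment

from .oracles import (edges_bipartitions, edges_to_matrix,
                      nj_tree_leaf_distances, random_tree_edges)


def test_three_taxon_closed_form():
    # three-point equations: l_A = (dAB + dAC - dBC)/2, etc.
    d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
    tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
    lengths = {c.name: c.branch_length for c in tree.root.children}
    assert lengths == pytest.approx({"A": 1.0, "B": 3.0, "C": 5.0})


def test_four_taxon_additive_example():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths
    taxa = ["A", "B", "C", "D"]
    d = np.array([[0, 3, 5, 6],
                  [3, 0, 6, 7],
                  [5, 6, 0, 7],
                  [6, 7, 7, 0]], float)
    tree = neighbor_joining(DistanceMatrix(taxa, d))
    assert tree.bipartitions() == {frozenset({"C", "D"})}
    leaf_bl = {leaf.name: leaf.branch_length for leaf in tree.root.leaves()}
    assert leaf_bl == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
    recovered = tree_distance_matrix(tree)
    assert np.allclose(recovered.values, d)


def test_nj_consistent_on_random_additive_matrices():
    rng = np.random.default_rng(13)
    for rep in range(20):
        n = int(rng.integers(4, 9))
        taxa = [f"t{i:02d}" for i in range(n)]
        edges = random_tree_edges(taxa, rng)
        matrix = edges_to_matrix(taxa, edges)
        tree = neighbor_joining(DistanceMatrix(taxa, matrix))
        assert tree.bipartitions() == edges_bipartitions(taxa, edges)
        recovered = nj_tree_leaf_distances(tree, taxa)
        assert np.allclose(recovered, matrix, atol=1e-8)


def test_permuting_taxa_preserves_bipartitions():
    rng = np.random.default_rng(14)
    taxa = [f"t{i}" for i in range(6)]
    edges = random_tree_edges(taxa, rng)
    matrix = edges_to_matrix(taxa, edges)
    tree1 = neighbor_joining(DistanceMatrix(taxa, matrix))
    perm = list(rng.permutation(6))
    tree2 = neighbor_joining(DistanceMatrix(
        [taxa[i] for i in perm], matrix[np.ix_(perm, perm)]))
    assert tree1.bipartitions() == tree2.bipartitions()


def test_infinite_entry_is_error():
    d = np.zeros((3, 3))
    d[0, 1] = d[1, 0] = np.inf
    with pytest.raises(ValueError, match="non-finite"):
        neighbor_joining(DistanceMatrix(["A", "B", "C"], d))


def test_too_few_taxa_is_error():
    with pytest.raises(ValueError, match="3 taxa"):
        neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


def test_negative_branches_clamped():
    # near-degenerate matrix that yields a negative NJ branch
    taxa = ["A", "B", "C", "D"]
    d = np.array([[0.0, 0.1, 0.4, 0.5],
                  [0.1, 0.0, 0.45, 0.55],
                  [0.4, 0.45, 0.0, 0.05],
                  [0.5, 0.55, 0.05, 0.0]])
    tree = neighbor_joining(DistanceMatrix(taxa, d))

    def all_lengths(node):
        yield node.branch_length
        for c in node.children:
            yield from all_lengths(c)

    assert all(bl >= 0 for c in tree.root.children for bl in all_lengths(c))


class TestNewick:
    def test_three_taxon_shape(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        newick = to_newick(neighbor_joining(DistanceMatrix(["A", "B", "C"], d)))
        assert newick.startswith("(") and newick.endswith(";")
        assert newick.count(",") == 2

    def test_roundtrip_through_independent_parser(self):
        rng = np.random.default_rng(15)
        taxa = [f"t{i}" for i in range(7)]
        edges = random_tree_edges(taxa, rng)
        matrix = edges_to_matrix(taxa, edges)
        tree = neighbor_joining(DistanceMatrix(taxa, matrix))
        newick = to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        dd = {t.label: t for t in parsed.taxon_namespace}
        mine = nj_tree_leaf_distances(tree, taxa)
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    assert pdm.distance(dd[a], dd[b]) == pytest.approx(
                        mine[i, j], abs=1e-9)
        # bipartition sets agree
        parsed.encode_bipartitions()
        labels = {frozenset(bp.leafset_taxa(parsed.taxon_namespace))
                  for bp in parsed.bipartition_encoding}
        parsed_splits = {frozenset(t.label for t in s) for s in labels}
        for bp in tree.bipartitions():
            assert bp in parsed_splits or frozenset(set(taxa) - bp) in parsed_splits

    def test_labels_with_spaces_are_quoted(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["tax a", "B", "C"], d))
        assert "'tax a'" in to_newick(tree)


class TestBootstrap:
    def test_strong_clade_split_has_high_support(self):
        msa = two_clade_alignment(n_per_clade=4, length=500, n_diagnostic=50,
                                  seed=16)
        tree = bootstrap_supports(msa, replicates=100, seed=17)
        clade_a = frozenset(t for t in msa.taxa if t.startswith("B"))
        supports = {}
        all_taxa = set(msa.taxa)
        for node in tree.internal_nodes():
            below = {leaf.name for leaf in node.leaves()}
            side = below if "A1" not in below else all_taxa - below
            supports[frozenset(side)] = node.support
        assert supports[clade_a] >= 95

    def test_zero_replicates_returns_plain_tree(self):
        msa = two_clade_alignment(seed=18)
        tree = bootstrap_supports(msa, replicates=0, seed=0)
        assert all(n.support is None for n in tree.internal_nodes())

    def test_same_seed_byte_identical_newick(self):
        msa = two_clade_alignment(seed=19)
        n1 = to_newick(bootstrap_supports(msa, replicates=25, seed=42))
        n2 = to_newick(bootstrap_supports(msa, replicates=25, seed=42))
        assert n1 == n2

    def test_supports_lie_in_range(self):
        msa = two_clade_alignment(seed=20)
        tree = bootstrap_supports(msa, replicates=30, seed=1)
        for node in tree.internal_nodes():
            assert node.support is None or 0 <= node.support <= 100
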