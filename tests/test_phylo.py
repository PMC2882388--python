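import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from brcarray.phylo import (
    DistanceMatrix,
    neighbor_joining,
    p_distance_matrix,
    read_newick,
    root_with_outgroup,
    write_newick,
)
from brcarray.seq_io import BioSequence, Msa, NUCLEOTIDE, PROTEIN

from oracles import random_additive_tree


def _msa(pairs, alphabet=NUCLEOTIDE):
    return Msa(
        tuple(BioSequence(i, s, alphabet, aligned=True) for i, s in pairs)
    )


def _leaf_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    ns = tree.taxon_namespace
    labels = sorted(t.label for t in ns)
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            out[(a, b)] = pdm.distance(ns.get_taxon(a), ns.get_taxon(b))
    return out


# ---------------------------------------------------------------------------
# p-distances


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("AAAA", "AAAA", 0.0),
        ("AAAA", "AAAT", 0.25),
        ("AA--", "AATT", 0.0),  # pairwise deletion: only 2 comparable sites
    ],
)
def test_p_distance_examples(a, b, expected):
    dm = p_distance_matrix(_msa([("x", a), ("y", b)]))
    assert dm.d[0, 1] == pytest.approx(expected)


def test_pair_without_comparable_sites_is_an_error():
    with pytest.raises(ValueError, match="x.*y"):
        p_distance_matrix(_msa([("x", "AA--"), ("y", "--TT")]))


def test_protein_distance_skips_x_columns():
    dm = p_distance_matrix(_msa([("x", "MKXV"), ("y", "MRLV")], PROTEIN))
    assert dm.d[0, 1] == pytest.approx(1 / 3)


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))


# ---------------------------------------------------------------------------
# neighbor joining


def test_three_taxon_lengths_solve_the_closed_form():
    # pendant lengths: la = (dab + dac - dbc)/2, etc.
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), d))
    lens = {
        lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
    }
    assert lens["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lens["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lens["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_nj_needs_three_labels():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


def test_nj_recovers_a_known_additive_tree_exactly():
    rng = np.random.default_rng(8)
    newick, labels, mat = random_additive_tree(rng, 6)
    nj = neighbor_joining(DistanceMatrix(tuple(labels), mat))
    ns = dendropy.TaxonNamespace()
    truth = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=ns)
    got = dendropy.Tree.get(data=write_newick(nj), schema="newick", taxon_namespace=ns)
    truth.encode_bipartitions()
    got.encode_bipartitions()
    assert treecompare.symmetric_difference(truth, got, is_bipartitions_updated=True) == 0
    # additive consistency: every leaf-to-leaf path equals the input distance
    dists = _leaf_distances(nj)
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            assert dists[(a, labels[j])] == pytest.approx(mat[i, j], abs=1e-9)


def test_nj_output_invariant_under_label_permutation():
    rng = np.random.default_rng(9)
    _, labels, mat = random_additive_tree(rng, 7)
    perm = rng.permutation(len(labels))
    permuted = DistanceMatrix(
        tuple(labels[i] for i in perm), mat[np.ix_(perm, perm)]
    )
    d1 = _leaf_distances(neighbor_joining(DistanceMatrix(tuple(labels), mat)))
    d2 = _leaf_distances(neighbor_joining(permuted))
    for key, val in d1.items():
        assert d2[key] == pytest.approx(val, abs=1e-9)


def test_negative_branch_lengths_are_clamped():
    # a strongly non-additive matrix provokes a negative estimate
    d = np.array(
        [
            [0.0, 0.1, 0.4, 0.4],
            [0.1, 0.0, 0.4, 0.4],
            [0.4, 0.4, 0.0, 0.02],
            [0.4, 0.4, 0.02, 0.0],
        ]
    )
    tree = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), d))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            assert edge.length >= 0


# ---------------------------------------------------------------------------
# rooting and Newick IO


@pytest.fixture()
def small_tree():
    rng = np.random.default_rng(10)
    _, labels, mat = random_additive_tree(rng, 5)
    return neighbor_joining(DistanceMatrix(tuple(labels), mat))


def test_outgroup_rooting_preserves_leaf_paths(small_tree):
    before = _leaf_distances(small_tree)
    rooted = root_with_outgroup(small_tree, "t1")
    after = _leaf_distances(rooted)
    for key, val in before.items():
        assert after[key] == pytest.approx(val, abs=1e-9)


def test_rooted_tree_has_two_children_and_outgroup_pendant(small_tree):
    rooted = root_with_outgroup(small_tree, "t1")
    children = rooted.seed_node.child_nodes()
    assert len(children) == 2
    assert any(
        c.is_leaf() and c.taxon.label == "t1" for c in children
    )


def test_unknown_outgroup_is_an_error(small_tree):
    with pytest.raises(ValueError, match="nope"):
        root_with_outgroup(small_tree, "nope")


def test_newick_round_trip(small_tree):
    text = write_newick(small_tree)
    back = read_newick(text)
    d1 = _leaf_distances(small_tree)
    d2 = _leaf_distances(back)
    for key, val in d1.items():
        assert d2[key] == pytest.approx(val, abs=1e-12)


def test_labels_with_spaces_are_quoted():
    d = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.4], [0.4, 0.4, 0.0]])
    tree = neighbor_joining(DistanceMatrix(("taxon one", "b", "c"), d))
    text = write_newick(tree)
    assert "'taxon one'" in text or "taxon_one" in text
    assert {t.label for t in read_newick(text).taxon_namespace} >= {"b", "c"}


def test_nj_agrees_with_independent_implementation():
    # scikit-bio's neighbor joining as a cross-check on a noisy matrix
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(11)
    _, labels, mat = random_additive_tree(rng, 6)
    noisy = mat + rng.uniform(0, 0.01, size=mat.shape)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0.0)
    ours = neighbor_joining(DistanceMatrix(tuple(labels), noisy))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=list(labels)))
    ns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=write_newick(ours), schema="newick", taxon_namespace=ns)
    t2 = dendropy.Tree.get(data=str(theirs), schema="newick", taxon_namespace=ns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    assert treecompare.symmetric_difference(t1, t2, is_bipartitions_updated=True) == 0
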