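"""NJ and minimum-evolution trees against brute-force oracles."""

import itertools

import dendropy
import numpy as np
import pytest

from degenphy import bipartitions, me_refine, nj_tree, tree_length
from degenphy.composition import DistanceMatrix

from conftest import enumerate_unrooted_topologies, trees_from_newicks


def additive_matrix_from_tree(tree):
    """Patristic distances of a tree with branch lengths: an additive matrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(tuple(t.label for t in taxa), d)


def random_tree(labels, rng):
    """Random unrooted binary topology by stepwise addition, random lengths."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    for lab in labels[:3]:
        tree.seed_node.add_child(dendropy.Node(taxon=tns.require_taxon(label=lab)))
    for lab in labels[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
        edge = edges[rng.integers(len(edges))]
        old_head, parent = edge.head_node, edge.tail_node
        mid = dendropy.Node()
        parent.remove_child(old_head)
        parent.add_child(mid)
        mid.add_child(old_head)
        mid.add_child(dendropy.Node(taxon=tns.require_taxon(label=lab)))
    for e in tree.preorder_edge_iter():
        if e.tail_node is not None:
            e.length = float(rng.uniform(0.5, 3.0))
    tree.is_rooted = False
    return tree


def test_four_taxon_additive_exact():
    (tree,) = trees_from_newicks(["((A:1,B:2):1,(C:3,D:4));"])
    D = additive_matrix_from_tree(tree)
    # hand-checked path distances
    assert D["A", "B"] == 3 and D["A", "C"] == 5 and D["B", "D"] == 7
    out = nj_tree(D)
    assert bipartitions(out) == {frozenset({"C", "D"})}
    lengths = {}
    for node in out.preorder_node_iter():
        if node.is_leaf():
            lengths[node.taxon.label] = node.edge.length
    assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})


def test_three_taxon_star():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    out = nj_tree(DistanceMatrix(("A", "B", "C"), d))
    lengths = {
        n.taxon.label: n.edge.length for n in out.preorder_node_iter() if n.is_leaf()
    }
    # three-point formulas
    assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3})


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
def test_nj_recovers_additive_topologies(n_taxa):
    """On additive matrices NJ must return the generating topology exactly."""
    rng = np.random.default_rng(n_taxa)
    labels = [f"x{i}" for i in range(n_taxa)]
    for _ in range(5):
        tree = random_tree(labels, rng)
        D = additive_matrix_from_tree(tree)
        assert bipartitions(nj_tree(D)) == bipartitions(tree)


def test_nj_agrees_with_dendropy_on_random_matrix():
    """Independent cross-check against dendropy's NJ on a perturbed matrix."""
    rng = np.random.default_rng(42)
    labels = [f"x{i}" for i in range(7)]
    tree = random_tree(labels, rng)
    d = additive_matrix_from_tree(tree).values + rng.uniform(0, 0.05, (7, 7))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    D = DistanceMatrix(tuple(labels), d)
    import io as _io

    csv = "," + ",".join(labels) + "\n" + "\n".join(
        labels[i] + "," + ",".join(str(v) for v in d[i]) for i in range(7)
    )
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=_io.StringIO(csv))
    ref = pdm.nj_tree()
    assert bipartitions(nj_tree(D)) == bipartitions(ref)


def test_nj_input_validation():
    bad = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
    with pytest.raises(ValueError):
        DistanceMatrix(("a", "b", "c"), bad)
    with pytest.raises(ValueError):
        DistanceMatrix(("a", "b", "c"), -np.ones((3, 3)))


class TestMeRefine:
    def test_additive_matrix_topology_unchanged(self):
        rng = np.random.default_rng(3)
        tree = random_tree([f"x{i}" for i in range(6)], rng)
        D = additive_matrix_from_tree(tree)
        nj = nj_tree(D)
        refined = me_refine(nj, D, nni_rounds=5)
        assert bipartitions(refined) == bipartitions(tree)
        assert tree_length(refined) == pytest.approx(tree_length(tree))

    def test_length_never_increases(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            n = 8
            d = rng.uniform(0.2, 2.0, (n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            D = DistanceMatrix(tuple(f"x{i}" for i in range(n)), d)
            nj = nj_tree(D)
            from degenphy.distance_trees import _from_dendropy, _ols_lengths

            nj_len = _ols_lengths(_from_dendropy(nj), D)[1]
            refined_len = _ols_lengths(_from_dendropy(me_refine(nj, D, 10)), D)[1]
            assert refined_len <= nj_len + 1e-9

    def test_six_taxon_exhaustive_minimum(self):
        """NNI refinement reaches the global ME optimum over all 105 topologies."""
        from degenphy.distance_trees import _from_dendropy, _ols_lengths

        rng = np.random.default_rng(7)
        labels = [f"x{i}" for i in range(6)]
        tops = enumerate_unrooted_topologies(labels)
        assert len(tops) == 105
        for trial in range(3):
            base = random_tree(labels, rng)
            d = additive_matrix_from_tree(base).values + rng.uniform(0, 0.4, (6, 6))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            D = DistanceMatrix(tuple(labels), d)
            best = min(_ols_lengths(_from_dendropy(t), D)[1] for t in tops)
            refined = me_refine(nj_tree(D), D, nni_rounds=20)
            got = _ols_lengths(_from_dendropy(refined), D)[1]
            assert got == pytest.approx(best, abs=1e-9)

    def test_leafset_mismatch(self):
        rng = np.random.default_rng(9)
        tree = random_tree(["a", "b", "c", "d"], rng)
        D = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            me_refine(tree, D)


class TestTreeLength:
    def test_hand_built(self):
        (tree,) = trees_from_newicks(["((A:1,B:2):1,C:3,D:4);"])
        assert tree_length(tree) == 11

    def test_missing_lengths_rejected(self):
        (tree,) = trees_from_newicks(["((A,B),(C,D));"])
        with pytest.raises(ValueError):
            tree_length(tree)

    def test_scaling_linearity(self):
        rng = np.random.default_rng(11)
        tree = random_tree([f"x{i}" for i in range(6)], rng)
        D = additive_matrix_from_tree(tree)
        D5 = DistanceMatrix(D.taxa, D.values * 5.0)
        t1 = me_refine(nj_tree(D), D)
        t5 = me_refine(nj_tree(D5), D5)
        assert tree_length(t5) == pytest.approx(5 * tree_length(t1))
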