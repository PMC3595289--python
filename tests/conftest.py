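import dendropy
import pytest

from degenphy import CodonAlignment


def trees_from_newicks(newicks, rooted=False):
    """Parse newick strings onto one shared taxon namespace."""
    tns = dendropy.TaxonNamespace()
    out = []
    for nwk in newicks:
        prefix = "[&R] " if rooted else "[&U] "
        out.append(
            dendropy.Tree.get(data=prefix + nwk, schema="newick", taxon_namespace=tns)
        )
    return out


def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies on the given leaves, by stepwise addition."""
    labels = list(labels)
    assert len(labels) >= 3

    # build newick strings recursively: start from 3-leaf star, insert each
    # next leaf into every edge of every partial tree
    def insert_all(nwk_tree, leaf):
        tns = dendropy.TaxonNamespace()
        base = dendropy.Tree.get(data=nwk_tree, schema="newick", taxon_namespace=tns)
        out = []
        edges = [
            e for e in base.preorder_edge_iter() if e.tail_node is not None
        ]
        for k in range(len(edges)):
            tns2 = dendropy.TaxonNamespace()
            t = dendropy.Tree.get(data=nwk_tree, schema="newick", taxon_namespace=tns2)
            es = [e for e in t.preorder_edge_iter() if e.tail_node is not None]
            edge = es[k]
            old_head = edge.head_node
            parent = edge.tail_node
            mid = dendropy.Node()
            parent.remove_child(old_head)
            parent.add_child(mid)
            mid.add_child(old_head)
            new_leaf = dendropy.Node(taxon=tns2.require_taxon(label=leaf))
            mid.add_child(new_leaf)
            out.append(t.as_string(schema="newick", suppress_rooting=True).strip())
        return out

    partial = [f"({labels[0]},{labels[1]},{labels[2]});"]
    for leaf in labels[3:]:
        partial = [nwk for p in partial for nwk in insert_all(p, leaf)]
    # deduplicate by split sets
    from degenphy import bipartitions

    seen = {}
    for nwk in partial:
        t = dendropy.Tree.get(data=nwk, schema="newick")
        key = frozenset(bipartitions(t))
        seen.setdefault(key, t)
    return list(seen.values())


@pytest.fixture(scope="session")
def five_taxon_topologies():
    tops = enumerate_unrooted_topologies(list("ABCDE"))
    assert len(tops) == 15
    return tops


@pytest.fixture
def tiny_alignment():
    # 2 taxa, codons CTT|GAA (Leu, Glu) in both
    return CodonAlignment(("ta", "tb"), ("CTTGAA", "CTTGAA"))
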