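"""Bipartition utilities, consensus trees and taxon subsetting.

A bipartition (split) of an unrooted leaf-labelled tree is represented
canonically as the frozenset of leaf labels on the side *not* containing the
lexicographically smallest label; trivial splits (single leaves) are excluded.
All consensus operations work on these canonical splits, so they are invariant
to taxon input order and to tree rotation.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import dendropy

logger = logging.getLogger(__name__)

Split = frozenset


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial canonical splits of an (un)rooted tree."""
    labels = _leaf_labels(tree)
    all_set = frozenset(labels)
    ref = min(labels)
    splits: set[frozenset] = set()
    # postorder accumulation of leaf sets
    below: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        side = below[node]
        if ref in side:
            side = all_set - side
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(side)
    return splits


def _check_shared_leafset(trees: Sequence[dendropy.Tree]) -> list[str]:
    if not trees:
        raise ValueError("need at least one tree")
    labels = _leaf_labels(trees[0])
    for t in trees[1:]:
        if _leaf_labels(t) != labels:
            raise ValueError("trees do not share one leaf set")
    return labels


def tree_from_splits(
    labels: Iterable[str],
    splits: Iterable[frozenset],
    supports: dict[frozenset, float] | None = None,
) -> dendropy.Tree:
    """Build a tree from pairwise-compatible canonical splits.

    Splits are clusters on the side away from the reference (smallest) label;
    they form a laminar family and nest into a rooted tree with the reference
    leaf attached at the root.  Support values (percent) are written to the
    internal-node labels.
    """
    labels = sorted(labels)
    ref = labels[0]
    clusters = sorted(set(splits), key=lambda s: (-len(s), sorted(s)))
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node

    # clusters are laminar: each nests under the smallest proper superset
    node_of: dict[frozenset, dendropy.Node] = {}
    for cl in clusters:  # decreasing size, so supersets are already built
        supersets = [o for o in clusters if len(o) > len(cl) and cl < o]
        parent = node_of[min(supersets, key=len)] if supersets else root
        node = dendropy.Node()
        if supports is not None and cl in supports:
            node.label = str(int(round(supports[cl])))
            node.support = supports[cl]
        node_of[cl] = node
        parent.add_child(node)
    # attach each leaf under the smallest cluster containing it
    for lab in labels:
        if lab == ref:
            parent = root
        else:
            containing = [cl for cl in clusters if lab in cl]
            parent = node_of[min(containing, key=len)] if containing else root
        leaf = dendropy.Node(taxon=tns.require_taxon(label=lab))
        parent.add_child(leaf)
    tree.is_rooted = False
    return tree


def strict_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Tree retaining exactly the splits present in every input tree."""
    labels = _check_shared_leafset(trees)
    common = set.intersection(*(bipartitions(t) for t in trees))
    return tree_from_splits(labels, common)


def majority_consensus(trees: Sequence[dendropy.Tree], cutoff: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus: splits with frequency > cutoff, support as percent."""
    if not 0.5 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0.5, 1]")
    labels = _check_shared_leafset(trees)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in bipartitions(t):
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    kept = {s: 100.0 * c / n for s, c in counts.items() if c / n > cutoff}
    return tree_from_splits(labels, kept, supports=kept)


def _rooted_paths(tree: dendropy.Tree, root_at: str | None) -> dict[str, tuple]:
    """Per-leaf node path from the root, after optional rerooting at a leaf."""
    work = tree
    if root_at is not None:
        work = tree.clone(depth=1)
        leaf = next(
            lf for lf in work.leaf_node_iter() if lf.taxon.label == root_at
        )
        if leaf.edge.length is None:
            leaf.edge.length = 1.0
        work.reroot_at_edge(leaf.edge, update_bipartitions=False)
    paths: dict[str, tuple] = {}

    def walk(node, prefix):
        prefix = prefix + (id(node),)
        if node.is_leaf():
            paths[node.taxon.label] = prefix
        for c in node.child_nodes():
            walk(c, prefix)

    walk(work.seed_node, ())
    return paths


def _root_partition(paths: dict[str, tuple], group: frozenset) -> list[frozenset]:
    """Partition of ``group`` at the root of the tree restricted to it."""
    sub = {lab: paths[lab] for lab in group}
    depth = 0
    while True:
        heads = {p[depth] for p in sub.values() if len(p) > depth}
        if len(heads) != 1 or any(len(p) == depth + 1 for p in sub.values()):
            break
        depth += 1
    blocks: dict[object, set] = {}
    for lab, p in sub.items():
        blocks.setdefault(p[depth], set()).add(lab)
    return [frozenset(b) for b in blocks.values()]


def adams_consensus(
    trees: Sequence[dendropy.Tree], root_at: str | None = None
) -> dendropy.Tree:
    """Classical Adams consensus of rooted trees.

    Recursively intersects the root partitions of the input trees (their
    common refinement becomes the children of the consensus root) and recurses
    into each block.  Unrooted inputs are rooted at ``root_at`` (default: the
    first taxon label in sorted order), the convention being that Adams
    consensus is only defined for rooted trees.
    """
    labels = _check_shared_leafset(trees)
    reroot: str | None = None
    needs_rooting = any(
        not t.is_rooted or len(t.seed_node.child_nodes()) > 2 for t in trees
    )
    if needs_rooting or root_at is not None:
        reroot = root_at if root_at is not None else labels[0]
    all_paths = [_rooted_paths(t, reroot) for t in trees]

    tns = dendropy.TaxonNamespace()
    out = dendropy.Tree(taxon_namespace=tns)

    def build(group: frozenset, parent: dendropy.Node) -> None:
        if len(group) == 1:
            (lab,) = group
            parent.add_child(dendropy.Node(taxon=tns.require_taxon(label=lab)))
            return
        partitions = [_root_partition(p, group) for p in all_paths]
        # common refinement (product) of all partitions
        block_of: dict[str, tuple] = {}
        for lab in group:
            key = tuple(
                next(i for i, b in enumerate(part) if lab in b) for part in partitions
            )
            block_of[lab] = key
        blocks: dict[tuple, set] = {}
        for lab, key in block_of.items():
            blocks.setdefault(key, set()).add(lab)
        if len(blocks) == 1:
            # cannot refine further: polytomy of leaves
            for lab in sorted(group):
                parent.add_child(dendropy.Node(taxon=tns.require_taxon(label=lab)))
            return
        for key in sorted(blocks, key=lambda k: sorted(blocks[k])):
            blk = frozenset(blocks[key])
            if len(blk) == 1:
                build(blk, parent)
            else:
                node = dendropy.Node()
                parent.add_child(node)
                build(blk, node)

    build(frozenset(labels), out.seed_node)
    out.is_rooted = True
    return out


def bootstrap_support(
    reference: dendropy.Tree, trees: Sequence[dendropy.Tree]
) -> dict[frozenset, float]:
    """Percent of trees containing each internal split of the reference."""
    _check_shared_leafset([reference, *trees])
    ref_splits = bipartitions(reference)
    counts = {s: 0 for s in ref_splits}
    for t in trees:
        for s in bipartitions(t):
            if s in counts:
                counts[s] += 1
    n = len(trees)
    return {s: 100.0 * c / n for s, c in counts.items()}


def map_supports(tree: dendropy.Tree, supports: dict[frozenset, float]) -> dendropy.Tree:
    """Annotate a tree's internal nodes with support values (percent)."""
    labels = _leaf_labels(tree)
    all_set = frozenset(labels)
    ref = min(labels)
    below: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            continue
        below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        side = below[node]
        if ref in side:
            side = all_set - side
        if side in supports:
            node.support = supports[side]
            node.label = str(int(round(supports[side])))
    return tree


def edge_supports(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Read support annotations back off a tree (split -> percent)."""
    labels = _leaf_labels(tree)
    all_set = frozenset(labels)
    ref = min(labels)
    below: dict[dendropy.Node, frozenset] = {}
    out: dict[frozenset, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            continue
        below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        side = below[node]
        if ref in side:
            side = all_set - side
        support = getattr(node, "support", None)
        if support is None and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        if support is not None and 2 <= len(side) <= len(labels) - 2:
            out[side] = float(support)
    return out


def subset_taxa(obj, keep: Sequence[str] | None = None, drop: Sequence[str] | None = None,
                on_unknown: str = "error"):
    """Restrict an alignment, tree, tree list or annotation to a taxon subset.

    Exactly one of ``keep``/``drop`` must be given.  Pruned trees suppress
    degree-2 nodes, merging branch lengths.  ``on_unknown`` is ``error`` or
    ``warn``.
    """
    if (keep is None) == (drop is None):
        raise ValueError("give exactly one of keep or drop")
    from degenphy.alignment import CodonAlignment

    def resolve(names: Sequence[str], universe: list[str]) -> list[str]:
        unknown = [n for n in names if n not in universe]
        if unknown:
            if on_unknown == "error":
                raise KeyError(f"unknown taxa: {unknown}")
            logger.warning("ignoring unknown taxa: %s", unknown)
        return [n for n in names if n in universe]

    if isinstance(obj, CodonAlignment):
        universe = list(obj.taxa)
    elif isinstance(obj, dendropy.Tree):
        universe = _leaf_labels(obj)
    elif isinstance(obj, dict):
        universe = list(obj)
    elif isinstance(obj, (list, tuple)):
        return type(obj)(subset_taxa(t, keep=keep, drop=drop, on_unknown=on_unknown) for t in obj)
    else:
        raise TypeError(f"cannot subset object of type {type(obj).__name__}")

    if keep is not None:
        kept = resolve(list(keep), universe)
    else:
        dropped = set(resolve(list(drop), universe))
        kept = [t for t in universe if t not in dropped]

    if isinstance(obj, CodonAlignment):
        return obj.subset([t for t in obj.taxa if t in set(kept)])
    if isinstance(obj, dict):
        return {t: obj[t] for t in kept}
    pruned = obj.clone(depth=1)
    pruned.retain_taxa_with_labels(kept)
    pruned.purge_taxon_namespace()
    return pruned
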