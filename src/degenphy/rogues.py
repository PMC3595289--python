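"""Rogue-taxon screening.

Two complementary screens for unstably placed taxa: an annotation-based scan
of a (rooted) consensus tree against known group membership, and a greedy
pruning search maximizing the relative bipartition information criterion
(RBIC) over a profile of bootstrap trees.  The RBIC implementation is a
deliberately simple single-taxon greedy variant: at each step the one leaf
whose removal most increases

    RBIC(S) = sum of majority-rule consensus split supports / ((|S| - 3) * 100)

is dropped, until no removal increases it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import dendropy

from degenphy.consensus import _leaf_labels, bipartitions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaxonAnnotation:
    """Taxon -> group label map (e.g., superfamily membership)."""

    groups: dict[str, str]

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.groups.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes


@dataclass(frozen=True)
class RogueFlag:
    taxon: str
    rule: str
    detail: str = ""


def annotation_rogues(
    consensus: dendropy.Tree,
    annotation: TaxonAnnotation,
    degree_limit: int = 3,
) -> list[RogueFlag]:
    """Flag taxa that contradict their group annotation on a rooted consensus.

    Rule (a): a taxon of a multi-exemplar group is flagged when no clade of
    the tree consists purely of >= 2 members of its own group and contains it.
    Rule (b): a taxon that is its group's single exemplar is flagged when it
    attaches at an unresolved node with more than ``degree_limit`` children.
    Taxa present in the tree but missing from the annotation are skipped with
    a warning.
    """
    leaves = set(_leaf_labels(consensus))
    sizes = annotation.group_sizes()
    below: dict[dendropy.Node, frozenset] = {}
    pure_clades: list[frozenset] = []
    parent_children: dict[str, int] = {}
    for node in consensus.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            if node.parent_node is not None:
                parent_children[node.taxon.label] = len(node.parent_node.child_nodes())
            continue
        below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        grp = {annotation.groups.get(t) for t in below[node]}
        if len(grp) == 1 and None not in grp and len(below[node]) >= 2:
            pure_clades.append(below[node])

    flags: list[RogueFlag] = []
    for taxon in sorted(leaves):
        if taxon not in annotation.groups:
            logger.warning("taxon %r has no group annotation; skipped", taxon)
            continue
        group = annotation.groups[taxon]
        if sizes[group] >= 2:
            if not any(taxon in clade for clade in pure_clades):
                flags.append(
                    RogueFlag(taxon, "a", f"does not cluster with other members of {group!r}")
                )
        else:
            if parent_children.get(taxon, 0) > degree_limit:
                flags.append(
                    RogueFlag(
                        taxon,
                        "b",
                        f"single exemplar of {group!r} at an unresolved node "
                        f"({parent_children[taxon]} children)",
                    )
                )
    return flags


def _restricted_splits(full_splits: set, keep: frozenset) -> set:
    """Restrict a tree's canonical splits to a leaf subset, re-canonicalized."""
    ref = min(keep)
    out = set()
    n = len(keep)
    for s in full_splits:
        side = s & keep
        if ref in side:
            side = keep - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def rbic(trees_splits: Sequence[set], keep: frozenset) -> float:
    """Relative bipartition information criterion of a leaf subset.

    Sum of majority-rule (>50%) consensus split frequencies over the pruned
    profile, normalized by the maximum possible (|keep| - 3 fully supported
    splits); lies in (0, 1] for any profile with >= 4 leaves.
    """
    n_trees = len(trees_splits)
    counts: dict[frozenset, int] = {}
    for splits in trees_splits:
        for s in _restricted_splits(splits, keep):
            counts[s] = counts.get(s, 0) + 1
    kept = [c / n_trees for c in counts.values() if c / n_trees > 0.5]
    denom = len(keep) - 3
    if denom <= 0:
        raise ValueError("need at least 4 retained taxa")
    return sum(kept) / denom


def greedy_rbic_prune(
    trees: Sequence[dendropy.Tree], max_drop: int | None = None
) -> tuple[list[str], list[float]]:
    """Greedily drop the taxa whose removal most increases RBIC.

    Returns the dropped taxa in drop order and the strictly increasing RBIC
    trace (initial value first).  Stops when no single-taxon removal
    increases RBIC, or after ``max_drop`` removals.
    """
    labels = _leaf_labels(trees[0])
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 shared taxa")
    if max_drop is None:
        max_drop = n - 4
    if max_drop >= n - 3:
        raise ValueError("max_drop must leave at least 4 taxa")
    trees_splits = [bipartitions(t) for t in trees]
    keep = frozenset(labels)
    trace = [rbic(trees_splits, keep)]
    dropped: list[str] = []
    while len(dropped) < max_drop and len(keep) > 4:
        best: tuple[float, str] | None = None
        for taxon in sorted(keep):
            value = rbic(trees_splits, keep - {taxon})
            if best is None or value > best[0]:
                best = (value, taxon)
        if best is None or best[0] <= trace[-1] + 1e-12:
            break
        keep = keep - {best[1]}
        dropped.append(best[1])
        trace.append(best[0])
    return dropped, trace
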