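"""Neighbor-joining and minimum-evolution distance trees.

``nj_tree`` is the standard saitou-nei agglomeration made fully deterministic:
taxa are canonicalized to sorted-label order and ties in the Q criterion are
broken by the lowest (row, column) index pair.  ``me_refine`` fits
ordinary-least-squares branch lengths to a fixed topology and hill-climbs with
nearest-neighbour interchanges under the minimum-evolution criterion (total
clamped branch length).  Negative OLS lengths are retained internally but
clamped to zero for length reporting, and NJ's negative branch lengths are
clamped at construction with the deficit logged.

Trees are returned as :class:`dendropy.Tree` (unrooted).
"""

from __future__ import annotations

import itertools
import logging

import dendropy
import numpy as np

logger = logging.getLogger(__name__)


class _Unrooted:
    """Minimal mutable unrooted binary tree: adjacency + edge lengths."""

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.leaf_label: dict[int, str] = {}
        self.lengths: dict[frozenset[int], float] = {}
        self._next = 0

    def new_node(self, label: str | None = None) -> int:
        n = self._next
        self._next += 1
        self.adj[n] = set()
        if label is not None:
            self.leaf_label[n] = label
        return n

    def connect(self, a: int, b: int, length: float = 0.0) -> None:
        self.adj[a].add(b)
        self.adj[b].add(a)
        self.lengths[frozenset((a, b))] = length

    def disconnect(self, a: int, b: int) -> None:
        self.adj[a].discard(b)
        self.adj[b].discard(a)
        self.lengths.pop(frozenset((a, b)), None)

    def edges(self) -> list[frozenset[int]]:
        return sorted(self.lengths, key=sorted)

    def internal_edges(self) -> list[frozenset[int]]:
        return [e for e in self.edges() if all(n not in self.leaf_label for n in e)]

    def leaves(self) -> list[int]:
        return sorted(self.leaf_label)

    def leaf_paths(self) -> dict[tuple[int, int], list[frozenset[int]]]:
        """Edge path between every leaf pair (BFS per leaf; trees are small)."""
        paths = {}
        leaves = self.leaves()
        for src in leaves:
            prev: dict[int, int] = {src: src}
            queue = [src]
            while queue:
                node = queue.pop()
                for nb in self.adj[node]:
                    if nb not in prev:
                        prev[nb] = node
                        queue.append(nb)
            for dst in leaves:
                if dst <= src:
                    continue
                path = []
                node = dst
                while node != src:
                    path.append(frozenset((node, prev[node])))
                    node = prev[node]
                paths[(src, dst)] = path
        return paths

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        root_id = next(n for n in sorted(self.adj) if n not in self.leaf_label)
        nodes: dict[int, dendropy.Node] = {root_id: tree.seed_node}

        def build(parent_id: int) -> None:
            for child_id in sorted(self.adj[parent_id]):
                if child_id in nodes:
                    continue
                child = dendropy.Node()
                child.edge.length = self.lengths[frozenset((parent_id, child_id))]
                if child_id in self.leaf_label:
                    child.taxon = tns.require_taxon(label=self.leaf_label[child_id])
                nodes[parent_id].add_child(child)
                nodes[child_id] = child
                build(child_id)

        build(root_id)
        tree.is_rooted = False
        return tree


def _from_dendropy(tree: dendropy.Tree) -> _Unrooted:
    ut = _Unrooted()
    # deterministic node ids: leaves first in sorted label order
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ids = {lab: ut.new_node(lab) for lab in labels}
    mapping: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        if node.taxon is not None and node.is_leaf():
            mapping[node] = ids[node.taxon.label]
        else:
            mapping[node] = ut.new_node()
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            ut.connect(mapping[node.parent_node], mapping[node], node.edge.length or 0.0)
    # suppress a degree-2 root left over from rooted input
    for nid in list(ut.adj):
        if nid not in ut.leaf_label and len(ut.adj[nid]) == 2:
            a, b = sorted(ut.adj[nid])
            length = ut.lengths[frozenset((nid, a))] + ut.lengths[frozenset((nid, b))]
            ut.disconnect(nid, a)
            ut.disconnect(nid, b)
            del ut.adj[nid]
            ut.connect(a, b, length)
    return ut


def _clamp(value: float, context: str) -> float:
    if value < 0:
        logger.debug("negative branch length %.6g clamped to 0 (%s)", value, context)
        return 0.0
    return value


def nj_tree(D) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Deterministic: taxa are sorted, Q ties break at the lowest index pair.
    Negative branch lengths are clamped to zero (deficit logged).
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    order = sorted(range(n), key=lambda i: D.taxa[i])
    labels = [D.taxa[i] for i in order]
    d = D.values[np.ix_(order, order)].astype(float).copy()

    ut = _Unrooted()
    node_ids = [ut.new_node(lab) for lab in labels]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (r - 2) * sub - totals[:, None] - totals[None, :]
        # evaluate the upper triangle only: broadcasting makes q asymmetric in
        # the last ulp, and ties must break at the lowest (row, column) pair
        iu = np.triu_indices(r, 1)
        flat = q[iu]
        pos = int(np.flatnonzero(flat == flat.min())[0])
        i_loc, j_loc = int(iu[0][pos]), int(iu[1][pos])
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = dij / 2.0 + (totals[i_loc] - totals[j_loc]) / (2.0 * (r - 2))
        lj = dij - li
        new_id = ut.new_node()
        ut.connect(node_ids[i], new_id, _clamp(li, f"join {labels[i] if i < n else i}"))
        ut.connect(node_ids[j], new_id, _clamp(lj, f"join {labels[j] if j < n else j}"))
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = (d[i, k] + d[j, k] - dij) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row)] = new_row
        d[: len(new_row), -1] = new_row
        node_ids.append(new_id)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    a, b, c = active
    center = ut.new_node()
    ut.connect(node_ids[a], center, _clamp((d[a, b] + d[a, c] - d[b, c]) / 2.0, "final"))
    ut.connect(node_ids[b], center, _clamp((d[a, b] + d[b, c] - d[a, c]) / 2.0, "final"))
    ut.connect(node_ids[c], center, _clamp((d[a, c] + d[b, c] - d[a, b]) / 2.0, "final"))
    return ut.to_dendropy()


def _ols_lengths(ut: _Unrooted, D) -> tuple[dict[frozenset[int], float], float]:
    """OLS branch lengths for a fixed topology; returns (lengths, clamped total)."""
    taxa_index = {t: i for i, t in enumerate(D.taxa)}
    edges = ut.edges()
    edge_pos = {e: k for k, e in enumerate(edges)}
    paths = ut.leaf_paths()
    pairs = sorted(paths)
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (src, dst) in enumerate(pairs):
        for e in paths[(src, dst)]:
            A[row, edge_pos[e]] = 1.0
        y[row] = D.values[taxa_index[ut.leaf_label[src]], taxa_index[ut.leaf_label[dst]]]
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    lengths = {e: float(sol[k]) for e, k in edge_pos.items()}
    total = float(np.clip(sol, 0.0, None).sum())
    return lengths, total


def _nni_alternatives(ut: _Unrooted, edge: frozenset[int]):
    """Yield the two NNI rearrangements of an internal edge as swap pairs."""
    u, v = sorted(edge)
    u_side = sorted(ut.adj[u] - {v})
    v_side = sorted(ut.adj[v] - {u})
    if len(u_side) < 2 or len(v_side) < 2:
        return
    b = u_side[1]
    for c in v_side:
        yield (u, b, v, c)


def _apply_swap(ut: _Unrooted, swap) -> None:
    u, b, v, c = swap
    lb = ut.lengths[frozenset((u, b))]
    lc = ut.lengths[frozenset((v, c))]
    ut.disconnect(u, b)
    ut.disconnect(v, c)
    ut.connect(u, c, lc)
    ut.connect(v, b, lb)


def me_refine(tree: dendropy.Tree, D, nni_rounds: int = 5) -> dendropy.Tree:
    """OLS branch lengths plus NNI hill-climbing under minimum evolution.

    Each round scans internal edges in deterministic order and greedily
    accepts the single best length-decreasing interchange; total (clamped)
    tree length never increases across accepted moves.
    """
    tree_taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if tree_taxa != sorted(D.taxa):
        raise ValueError("tree leaf set does not match distance matrix taxa")
    ut = _from_dendropy(tree)
    lengths, total = _ols_lengths(ut, D)
    for _ in range(max(nni_rounds, 0)):
        best = None
        for edge in ut.internal_edges():
            for swap in _nni_alternatives(ut, edge):
                _apply_swap(ut, swap)
                _, alt_total = _ols_lengths(ut, D)
                _apply_swap(ut, (swap[0], swap[3], swap[2], swap[1]))  # undo
                if alt_total < total - 1e-12 and (best is None or alt_total < best[1]):
                    best = (swap, alt_total)
        if best is None:
            break
        _apply_swap(ut, best[0])
        lengths, total = _ols_lengths(ut, D)
    for e, val in lengths.items():
        ut.lengths[e] = val
    return ut.to_dendropy()


def tree_length(tree: dendropy.Tree) -> float:
    """Sum of branch lengths, clamped non-negative."""
    total = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")
        total += max(float(edge.length), 0.0)
    return total
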