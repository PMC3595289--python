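"""Synthetic codon alignments and search/bootstrap outcome logs.

The codon simulator is deliberately two-layered rather than a full codon-model
CTMC: an amino-acid layer (Poisson substitutions at ``nonsyn_rate`` per unit
branch length, uniform exchangeabilities over the 20 amino acids) determines
the translation history, and a codon-usage layer (Poisson synonymous
resamplings at ``syn_rate``) chooses, conditionally on the amino acid, the
codon from the lineage's usage profile.  Synonymous resampling stays within a
codon's degen1 synonymy component, and the codon drawn after an amino-acid
substitution comes from the target amino acid's canonical component, so the
degen1 image of every simulated site is a function of the amino-acid layer
alone — the synonymous/nonsynonymous separation the rest of the package
relies on is exact by construction.

Lineages listed in ``biased_lineages`` (stem branch and all descendant
branches) use a codon profile weighting each codon by
``gc3_weight ** (number of G/C at its degenerate positions)``, emulating
lineage-specific GC bias at synonymously free sites; all other branches use a
uniform profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from degenphy.alignment import CodonAlignment, IUPAC_RESOLUTIONS
from degenphy.recoding import build_degen_table
from degenphy.searchstats import BootstrapRun


def sim_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with exponential waiting times.

    Leaves are labelled ``t01 .. tNN``; deterministic for a fixed seed.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    root.age_time = 0.0
    first, second = dendropy.Node(), dendropy.Node()
    root.add_child(first)
    root.add_child(second)
    tips = [first, second]
    t = 0.0
    birth_times = {first: 0.0, second: 0.0}
    while len(tips) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        idx = int(rng.integers(len(tips)))
        parent = tips.pop(idx)
        parent.edge.length = t - birth_times[parent]
        a, b = dendropy.Node(), dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        birth_times[a] = birth_times[b] = t
        tips.extend([a, b])
    t_end = t + rng.exponential(1.0 / (birth_rate * len(tips)))
    width = len(str(n_taxa))
    for i, tip in enumerate(sorted(tips, key=lambda n: birth_times[n])):
        tip.edge.length = t_end - birth_times[tip]
        tip.taxon = tns.require_taxon(label=f"t{i + 1:0{width}d}")
    tree.is_rooted = True
    return tree


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one codon-alignment simulation."""

    tree: dendropy.Tree | None = None
    n_taxa: int = 16
    birth_rate: float = 1.0
    n_codons: int = 500
    nonsyn_rate: float = 0.3
    syn_rate: float = 30.0
    biased_lineages: frozenset[str] = field(default_factory=frozenset)
    gc3_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "biased_lineages", frozenset(self.biased_lineages))
        if self.nonsyn_rate < 0 or self.syn_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.gc3_weight < 1:
            raise ValueError("gc3_weight must be >= 1")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


class _CodonModel:
    """Precomputed synonymy components, profiles and amino-acid bookkeeping."""

    def __init__(self, gc3_weight: float):
        from Bio.Data import CodonTable

        table = build_degen_table()
        code = CodonTable.unambiguous_dna_by_id[1]
        self.sense = sorted(code.forward_table)
        self.index = {c: i for i, c in enumerate(self.sense)}
        self.aa = [code.forward_table[c] for c in self.sense]
        self.amino_acids = sorted(set(self.aa))
        images = [table[c] for c in self.sense]

        # synonymy components share a degen1 image
        comp_ids: dict[str, int] = {}
        self.comp_of = np.empty(len(self.sense), dtype=int)
        members: list[list[int]] = []
        for i, img in enumerate(images):
            if img not in comp_ids:
                comp_ids[img] = len(members)
                members.append([])
            self.comp_of[i] = comp_ids[img]
            members[comp_ids[img]].append(i)
        self.members = members

        # canonical component per amino acid: smallest image lexicographically
        by_aa: dict[str, list[int]] = {}
        for img, cid in comp_ids.items():
            a = self.aa[members[cid][0]]
            by_aa.setdefault(a, []).append(cid)
        self.canonical_comp = {
            a: min(cids, key=lambda cid: images[members[cid][0]]) for a, cids in by_aa.items()
        }

        # biased weight: gc3_weight ** (#G/C at degenerate image positions)
        def weight(i: int) -> float:
            codon, img = self.sense[i], images[i]
            exponent = sum(
                1
                for pos in range(3)
                if len(IUPAC_RESOLUTIONS[img[pos]]) > 1 and codon[pos] in "GC"
            )
            return gc3_weight**exponent

        self.comp_probs_uniform = [
            np.full(len(m), 1.0 / len(m)) for m in members
        ]
        biased = []
        for m in members:
            w = np.array([weight(i) for i in m])
            biased.append(w / w.sum())
        self.comp_probs_biased = biased


def _biased_edges(tree: dendropy.Tree, biased_lineages: frozenset[str]) -> set[int]:
    """Edge ids whose head subtree's leaves all lie in the biased set."""
    if not biased_lineages:
        return set()
    biased = set()
    below: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is not None and below[node] <= biased_lineages:
            biased.add(id(node))
    return biased


def sim_codon_alignment(config: SimulationConfig) -> CodonAlignment:
    """Simulate an in-frame, gapless, stop-free codon alignment on a tree."""
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    if tree is None:
        tree = sim_tree(config.n_taxa, config.birth_rate, seed=int(rng.integers(2**31)))
    model = _CodonModel(config.gc3_weight)
    biased_edges = _biased_edges(tree, config.biased_lineages)
    n_sites = config.n_codons
    n_aa = len(model.amino_acids)
    aa_index = {a: i for i, a in enumerate(model.amino_acids)}

    def draw_codons(aa_states: np.ndarray, biased: bool) -> np.ndarray:
        """Codons from the canonical component of each amino-acid state."""
        out = np.empty(len(aa_states), dtype=int)
        for a_idx in np.unique(aa_states):
            cid = model.canonical_comp[model.amino_acids[a_idx]]
            m = model.members[cid]
            p = model.comp_probs_biased[cid] if biased else model.comp_probs_uniform[cid]
            sel = aa_states == a_idx
            out[sel] = rng.choice(m, size=int(sel.sum()), p=p)
        return out

    def resample_within_component(codons: np.ndarray, sites: np.ndarray, biased: bool) -> None:
        for cid in np.unique(model.comp_of[codons[sites]]):
            m = model.members[cid]
            p = model.comp_probs_biased[cid] if biased else model.comp_probs_uniform[cid]
            sel = sites[model.comp_of[codons[sites]] == cid]
            codons[sel] = rng.choice(m, size=len(sel), p=p)

    root_aa = rng.integers(0, n_aa, size=n_sites)
    root_codons = draw_codons(root_aa, biased=False)

    leaf_seqs: dict[str, np.ndarray] = {}
    # iterate edges in preorder carrying (aa_state, codon_state) per site
    states: dict[int, tuple[np.ndarray, np.ndarray]] = {
        id(tree.seed_node): (root_aa, root_codons)
    }
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_aa, parent_codons = states[id(node.parent_node)]
        aa = parent_aa.copy()
        codons = parent_codons.copy()
        t = float(node.edge.length or 0.0)
        biased = id(node) in biased_edges
        ns_counts = rng.poisson(config.nonsyn_rate * t, size=n_sites)
        s_counts = rng.poisson(config.syn_rate * t, size=n_sites)
        ns_sites = np.flatnonzero(ns_counts)
        for site in ns_sites:
            state = aa[site]
            for _ in range(ns_counts[site]):
                step = int(rng.integers(0, n_aa - 1))
                state = step if step < state else step + 1
            aa[site] = state
        if len(ns_sites):
            codons[ns_sites] = draw_codons(aa[ns_sites], biased)
        syn_only = np.flatnonzero((s_counts > 0) & (ns_counts == 0))
        if len(syn_only):
            resample_within_component(codons, syn_only, biased)
        states[id(node)] = (aa, codons)
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = codons

    taxa = sorted(leaf_seqs)
    sequences = tuple(
        "".join(model.sense[i] for i in leaf_seqs[t]) for t in taxa
    )
    return CodonAlignment(tuple(taxa), sequences)


def sim_search_replicates(p_success: float, n: int, seed: int = 0) -> np.ndarray:
    """n Bernoulli search outcomes (True = best topology recovered)."""
    if not 0 <= p_success <= 1:
        raise ValueError("p_success must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return rng.random(n) < p_success


def _nni_neighbors(tree: dendropy.Tree) -> list[dendropy.Tree]:
    """All nearest-neighbour-interchange neighbours of an unrooted tree."""
    from degenphy.distance_trees import _from_dendropy

    ut = _from_dendropy(tree)
    out = []
    for edge in ut.internal_edges():
        from degenphy.distance_trees import _apply_swap, _nni_alternatives

        for swap in _nni_alternatives(ut, edge):
            _apply_swap(ut, swap)
            out.append(ut.to_dendropy())
            _apply_swap(ut, (swap[0], swap[3], swap[2], swap[1]))
    return out


def sim_bootstrap_run(
    reference: dendropy.Tree,
    n_pseudoreplicates: int,
    k: int,
    pi_true: float,
    q_find: float,
    seed: int = 0,
) -> BootstrapRun:
    """Generative model of bootstrap pseudoreplicates with imperfect search.

    Each pseudoreplicate has a latent best topology: the reference with
    probability ``pi_true``, else a random NNI neighbour of it.  Each of the
    k search replicates finds the latent best with probability ``q_find``,
    else returns a further-degraded topology (a random NNI neighbour of the
    latent best) with a strictly lower score.
    """
    for name, val in (("pi_true", pi_true), ("q_find", q_find)):
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if k < 1 or n_pseudoreplicates < 1:
        raise ValueError("k and n_pseudoreplicates must be >= 1")
    rng = np.random.default_rng(seed)
    neighbor_pool = _nni_neighbors(reference)
    degraded_pools: dict[int, list[dendropy.Tree]] = {id(reference): neighbor_pool}

    pseudoreplicates = []
    for _ in range(n_pseudoreplicates):
        if rng.random() < pi_true:
            latent = reference
        else:
            latent = neighbor_pool[int(rng.integers(len(neighbor_pool)))]
        if id(latent) not in degraded_pools:
            degraded_pools[id(latent)] = _nni_neighbors(latent)
        pool = degraded_pools[id(latent)]
        latent_score = -1e5 - rng.exponential(1.0)
        replicates = []
        for _ in range(k):
            if rng.random() < q_find:
                replicates.append((latent, latent_score))
            else:
                worse = pool[int(rng.integers(len(pool)))]
                replicates.append((worse, latent_score - 0.1 - rng.exponential(1.0)))
        pseudoreplicates.append(replicates)
    return BootstrapRun(pseudoreplicates)
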