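"""Nucleotide-composition heterogeneity diagnostics.

Compositional heterogeneity — variation among taxa in overall A/C/G/T
proportions — can create non-phylogenetic attraction between unrelated taxa.
This module quantifies it: per-taxon composition vectors, pairwise Euclidean
composition distances (units are per cent / 100, so every distance lies in
[0, sqrt(2)]), minimum-evolution distance trees built on those distances, a
column-resampling composition bootstrap, and outlier-taxon flagging.  It also
provides uncorrected sequence p-distances for desk-scale tree-recovery
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from degenphy.alignment import GAP_CHARS, IUPAC_RESOLUTIONS, CodonAlignment
from degenphy.distance_trees import me_refine, nj_tree

_NUC = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(_NUC)}


@dataclass(frozen=True)
class CompositionVector:
    """Proportions of A, C, G, T in a sequence (per cent / 100)."""

    proportions: tuple[float, float, float, float]
    n_counted: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self.proportions, dtype=float)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative pairwise distance matrix with taxon order."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if (v < 0).any():
            raise ValueError("matrix has negative entries")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def subset(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in keep]
        return DistanceMatrix(tuple(keep), self.values[np.ix_(idx, idx)])


def _composition_from_counts(counts: np.ndarray) -> CompositionVector:
    n = float(counts.sum())
    props = counts / n if n > 0 else np.zeros(4)
    return CompositionVector(tuple(float(p) for p in props), n)


def composition_vector(sequence: str, ambiguity_rule: str = "exclude") -> CompositionVector:
    """Per-sequence nucleotide proportions.

    ``exclude`` counts unambiguous A/C/G/T only; ``fractional`` spreads each
    ambiguity code equally over its compatible nucleotides.  Gaps and ``?``
    are never counted; an empty countable set yields ``n_counted = 0``.
    """
    if ambiguity_rule not in ("exclude", "fractional"):
        raise ValueError(f"unknown ambiguity_rule {ambiguity_rule!r}")
    counts = np.zeros(4)
    for c in sequence.upper():
        if c in GAP_CHARS:
            continue
        if c in _NUC_INDEX:
            counts[_NUC_INDEX[c]] += 1.0
        elif ambiguity_rule == "fractional":
            res = IUPAC_RESOLUTIONS[c]
            w = 1.0 / len(res)
            for r in res:
                counts[_NUC_INDEX[r]] += w
    return _composition_from_counts(counts)


def composition_distance(v1: CompositionVector, v2: CompositionVector) -> float:
    """Euclidean distance between two composition vectors (per cent / 100)."""
    if v1.n_counted == 0 or v2.n_counted == 0:
        raise ValueError("composition vector with no counted sites")
    return float(math.sqrt(((v1.as_array() - v2.as_array()) ** 2).sum()))


def _composition_matrix(aln: CodonAlignment, ambiguity_rule: str) -> np.ndarray:
    """(n_taxa, 4) array of compositions; raises naming empty taxa."""
    rows = []
    for taxon, seq in zip(aln.taxa, aln.sequences):
        v = composition_vector(seq, ambiguity_rule)
        if v.n_counted == 0:
            raise ValueError(f"taxon {taxon!r} has zero countable sites")
        rows.append(v.as_array())
    return np.vstack(rows)


def composition_distance_matrix(
    aln: CodonAlignment, ambiguity_rule: str = "exclude"
) -> DistanceMatrix:
    """Pairwise Euclidean composition distances among all taxa."""
    if aln.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    comps = _composition_matrix(aln, ambiguity_rule)
    diff = comps[:, None, :] - comps[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(aln.taxa, (d + d.T) / 2.0)


def pdistance_matrix(aln: CodonAlignment) -> DistanceMatrix:
    """Uncorrected p-distances over columns unambiguous in both taxa."""
    if aln.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    # encode: 0..3 = ACGT, -1 = ambiguous/gap/missing
    code = np.full(256, -1, dtype=np.int8)
    for c, i in _NUC_INDEX.items():
        code[ord(c)] = i
        code[ord(c.lower())] = i
    arr = np.vstack([code[np.frombuffer(s.encode(), dtype=np.uint8)] for s in aln.sequences])
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] >= 0) & (arr[j] >= 0)
            total = int(ok.sum())
            if total == 0:
                raise ValueError(f"no comparable columns between {aln.taxa[i]!r} and {aln.taxa[j]!r}")
            d[i, j] = d[j, i] = float((arr[i][ok] != arr[j][ok]).sum()) / total
    return DistanceMatrix(aln.taxa, d)


def composition_tree(
    aln: CodonAlignment, ambiguity_rule: str = "exclude", nni_rounds: int = 5
):
    """Minimum-evolution tree on composition distances (NJ start + NNI)."""
    D = composition_distance_matrix(aln, ambiguity_rule)
    return me_refine(nj_tree(D), D, nni_rounds=nni_rounds)


def composition_bootstrap_splits(
    aln: CodonAlignment,
    n_pseudoreplicates: int = 500,
    seed: int = 0,
    ambiguity_rule: str = "exclude",
) -> dict[frozenset, float]:
    """Split frequencies (percent) over composition-bootstrap NJ trees.

    Each pseudoreplicate resamples alignment columns with replacement and
    builds the NJ tree on the Euclidean distances between the resampled
    per-taxon compositions; every non-trivial split observed is counted.
    """
    from degenphy.consensus import bipartitions

    if aln.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    # per-taxon, per-column counted-base index (-1 for uncountable) for speed
    code = np.full(256, -1, dtype=np.int8)
    for c, i in _NUC_INDEX.items():
        code[ord(c)] = i
    arr = np.vstack(
        [code[np.frombuffer(s.upper().encode(), dtype=np.uint8)] for s in aln.sequences]
    )
    n_taxa, n_cols = arr.shape
    use_fractional = ambiguity_rule == "fractional"
    frac_weights = None
    if use_fractional:
        frac_weights = np.zeros((n_taxa, n_cols, 4))
        for t in range(n_taxa):
            for j, ch in enumerate(aln.sequences[t].upper()):
                if ch in GAP_CHARS:
                    continue
                res = IUPAC_RESOLUTIONS[ch]
                w = 1.0 / len(res)
                for r in res:
                    frac_weights[t, j, _NUC_INDEX[r]] = w

    counts_list = []
    for _ in range(n_pseudoreplicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        if use_fractional:
            counts = frac_weights[:, cols, :].sum(axis=1)
        else:
            sub = arr[:, cols]
            counts = np.zeros((n_taxa, 4))
            for t in range(n_taxa):
                row = sub[t]
                row = row[row >= 0]
                counts[t] = np.bincount(row, minlength=4)
        counts_list.append(counts)

    split_counts: dict[frozenset, int] = {}
    for counts in counts_list:
        totals = counts.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            continue  # a taxon with no countable sites in this resample
        comps = counts / totals
        diff = comps[:, None, :] - comps[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(d, 0.0)
        rep_tree = nj_tree(DistanceMatrix(aln.taxa, (d + d.T) / 2.0))
        for s in bipartitions(rep_tree):
            split_counts[s] = split_counts.get(s, 0) + 1
    return {s: 100.0 * c / n_pseudoreplicates for s, c in split_counts.items()}


def composition_bootstrap(
    aln: CodonAlignment,
    n_pseudoreplicates: int = 500,
    seed: int = 0,
    ambiguity_rule: str = "exclude",
):
    """Composition bootstrap supports mapped onto the full-data tree.

    Majority-rule-style split frequencies from
    :func:`composition_bootstrap_splits` are written (as percent) onto the
    internal nodes of the full-data minimum-evolution composition tree.
    Reproducible for a fixed seed; supports are invariant to taxon input
    order because tree construction canonicalizes taxon order.
    """
    from degenphy.consensus import map_supports

    supports = composition_bootstrap_splits(aln, n_pseudoreplicates, seed, ambiguity_rule)
    reference = composition_tree(aln, ambiguity_rule)
    return map_supports(reference, supports)


def flag_heterogeneous_taxa(
    aln: CodonAlignment,
    method: str = "centroid_z",
    threshold: float = 3.0,
    ambiguity_rule: str = "exclude",
) -> list[str]:
    """Flag compositionally heterogeneous taxa.

    ``centroid_z`` flags taxa whose Euclidean distance to the mean composition
    exceeds ``threshold`` standard deviations (of those distances over taxa);
    ``tree_tail`` flags the ``int(threshold)`` taxa with the greatest
    root-to-tip path on the midpoint-rooted composition tree.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if aln.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if method == "centroid_z":
        comps = _composition_matrix(aln, ambiguity_rule)
        centroid = comps.mean(axis=0)
        dists = np.sqrt(((comps - centroid) ** 2).sum(axis=1))
        sd = dists.std()
        if sd == 0:
            return []
        z = (dists - dists.mean()) / sd
        return [t for t, zi in zip(aln.taxa, z) if zi > threshold]
    if method == "tree_tail":
        import dendropy

        tree = composition_tree(aln, ambiguity_rule)
        rooted = tree.clone(depth=1)
        rooted.reroot_at_midpoint(update_bipartitions=False)
        depths = rooted.calc_node_root_distances(return_leaf_distances_only=True)
        leaves = [lf.taxon.label for lf in rooted.leaf_node_iter()]
        order = sorted(zip(leaves, depths), key=lambda x: (-x[1], x[0]))
        k = int(threshold)
        return sorted(t for t, _ in order[:k])
    raise ValueError(f"unknown method {method!r}")
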