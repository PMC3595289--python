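"""Search-effort and bootstrap-convergence statistics for tree sets.

Heuristic maximum-likelihood searches are replicated many times; the fraction
of replicates landing within a relative log-likelihood threshold of the best
replicate measures how hard the optimum is to find, and

    n = ln(1 - confidence) / ln(1 - p)

is the number of independent searches needed for a given confidence of at
least one success at per-search success probability p.  Bootstrap analyses
run k search replicates per pseudoreplicate and keep the best; subsampling
the first k of those replicates shows how support values converge as search
effort per pseudoreplicate grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import pandas as pd

from degenphy.consensus import bipartitions, bootstrap_support, strict_consensus


@dataclass
class SearchRun:
    """Replicate heuristic-search results: one (tree, lnL) pair per replicate."""

    trees: list[dendropy.Tree]
    scores: list[float]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.trees) != len(self.scores):
            raise ValueError("trees and scores differ in length")
        if not self.trees:
            raise ValueError("empty search run")
        if not all(math.isfinite(s) for s in self.scores):
            raise ValueError("non-finite lnL score")
        if not self.ids:
            self.ids = [str(i) for i in range(len(self.trees))]

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def best(self) -> int:
        """Index of the highest-lnL replicate (earliest on ties)."""
        return max(range(len(self.scores)), key=lambda i: (self.scores[i], -i))


@dataclass
class BootstrapRun:
    """Pseudoreplicate-structured search results.

    ``pseudoreplicates[p]`` holds the k replicate (tree, score) pairs of
    pseudoreplicate p in generation order.
    """

    pseudoreplicates: list[list[tuple[dendropy.Tree, float]]]

    def __post_init__(self) -> None:
        if not self.pseudoreplicates or any(not p for p in self.pseudoreplicates):
            raise ValueError("every pseudoreplicate needs at least one replicate")

    @property
    def k(self) -> int:
        return min(len(p) for p in self.pseudoreplicates)


def within_threshold_set(run: SearchRun, rel_threshold: float) -> list[int]:
    """Replicate indices with lnL within ``rel_threshold`` (relative) of the best.

    The threshold is a fraction: the paper-style "within 10^-4 %" is
    ``rel_threshold=1e-6``.  The best replicate is always included.
    """
    if rel_threshold < 0:
        raise ValueError("threshold must be non-negative")
    best = run.scores[run.best]
    denom = abs(best)
    if denom == 0:
        return list(range(len(run)))
    return [i for i, s in enumerate(run.scores) if (best - s) / denom <= rel_threshold]


def recovery_fraction(run: SearchRun, rel_threshold: float) -> float:
    """Fraction of replicates within the relative lnL threshold of the best."""
    return len(within_threshold_set(run, rel_threshold)) / len(run)


def replicates_needed(p_recover: float, confidence: float = 0.95) -> int:
    """Searches needed for ``confidence`` probability of >= 1 success.

    Rounded to the nearest integer (minimum 1); this rounding convention is
    deliberate — the ceiling would give 6 and 726 instead of 6 and 725 for
    the worked search-effort examples this statistic is used for.
    """
    if not 0 < p_recover <= 1:
        raise ValueError("p_recover must lie in (0, 1]")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    if p_recover == 1:
        return 1
    n = math.log(1 - confidence) / math.log(1 - p_recover)
    return max(1, math.floor(n + 0.5))


def hard_to_recover_nodes(
    run: SearchRun, thresholds: Sequence[float]
) -> dict[float, dict[frozenset, bool]]:
    """Per-edge presence in strict consensuses of within-threshold subsets.

    For each threshold, the strict consensus of the replicates within that
    relative lnL distance of the best is computed; each internal split of the
    best tree is marked present (True) or collapsed/absent (False).
    """
    best_splits = bipartitions(run.trees[run.best])
    out: dict[float, dict[frozenset, bool]] = {}
    for thr in thresholds:
        subset = [run.trees[i] for i in within_threshold_set(run, thr)]
        cons_splits = bipartitions(strict_consensus(subset)) if len(subset) > 1 else best_splits
        out[thr] = {s: (s in cons_splits) for s in best_splits}
    return out


def best_of_k_supports(
    run: BootstrapRun, reference: dendropy.Tree, ks: Sequence[int]
) -> pd.DataFrame:
    """Bootstrap support on the reference at varying search effort per pseudoreplicate.

    For each k, the highest-score tree among the first k replicates of each
    pseudoreplicate is selected (earliest on ties) and support is the percent
    of pseudoreplicates whose selected tree contains each reference split.
    Returns a DataFrame indexed by split (frozenset) with one column per k.
    """
    ks = list(ks)
    if max(ks) > run.k:
        raise ValueError(f"k={max(ks)} exceeds available replicates ({run.k})")
    split_cache: dict[int, set] = {}

    def splits_of(tree: dendropy.Tree) -> set:
        key = id(tree)
        if key not in split_cache:
            split_cache[key] = bipartitions(tree)
        return split_cache[key]

    ref_splits = sorted(bipartitions(reference), key=sorted)
    n = len(run.pseudoreplicates)
    table = {}
    for k in ks:
        counts = {s: 0 for s in ref_splits}
        for pseudo in run.pseudoreplicates:
            head = pseudo[:k]
            best_idx = max(range(len(head)), key=lambda i: (head[i][1], -i))
            for s in splits_of(head[best_idx][0]):
                if s in counts:
                    counts[s] += 1
        table[k] = [100.0 * counts[s] / n for s in ref_splits]
    return pd.DataFrame(table, index=ref_splits)


def convergence_report(table: pd.DataFrame, delta: float = 5.0) -> pd.DataFrame:
    """Edges whose support at small k lags the largest-k value by >= delta points.

    Returns a DataFrame with columns (edge, k, support, support_at_max_k,
    difference); difference = support(k) - support(max k), reported when
    |difference| >= delta.
    """
    kmax = max(table.columns)
    rows = []
    for edge, row in table.iterrows():
        for k in table.columns:
            if k == kmax:
                continue
            diff = row[k] - row[kmax]
            if abs(diff) >= delta:
                rows.append(
                    {
                        "edge": edge,
                        "k": k,
                        "support": row[k],
                        "support_at_max_k": row[kmax],
                        "difference": diff,
                    }
                )
    return pd.DataFrame(rows, columns=["edge", "k", "support", "support_at_max_k", "difference"])
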