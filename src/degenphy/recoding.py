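"""degen1 codon recoding and nonsynonymous/synonymous character-set partitioning.

The degen1 scheme maps every codon to the IUPAC-coded union of all codons
reachable from it by synonymous point substitutions, so that all codons of one
amino acid (with the Leu/Phe and Arg/Ser2 families merged by the shared
first-position ambiguity) acquire a single representation.  This erases
synonymous signal while retaining nonsynonymous signal.  Under the standard
code the images are, e.g.::

    CAT -> CAY        (His)
    TTA, CTG -> YTN   (Leu family; YTN also resolves to Phe)
    AGA, CGC -> MGN   (Arg family; MGN also resolves to Ser2)
    TTT -> TTY        (Phe)          AGC -> AGY   (Ser2)
    TCA -> TCN        (Ser1)         ATG -> ATG   (Met, invariant)

The complementary character sets noLRall1nt2 (second positions plus first
positions of non-Leu/Arg codons: nonsynonymous-only change) and LRall1nt3
(third positions plus Leu/Arg first positions: mostly synonymous change)
partition the included columns of an alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product

from degenphy.alignment import (
    GAP_CHARS,
    IUPAC_CODE,
    IUPAC_RESOLUTIONS,
    CodonAlignment,
    resolve_codon,
)

logger = logging.getLogger(__name__)

_NUC = "ACGT"
_IUPAC_LETTERS = "ACGTRYSWKMBDHVN"


class StopCodonError(ValueError):
    """Raised when a stop codon is met under ``stop_policy='error'``."""


@dataclass(frozen=True)
class DegenerationTable:
    """Idempotent mapping from IUPAC codons to their degen1 images.

    ``mapping`` covers every codon over the 15-letter IUPAC alphabet; codons
    containing gaps or missing characters are handled position-wise at
    application time and are not table keys.
    """

    mapping: dict[str, str]
    genetic_code_id: int = 1
    stop_policy: str = "to_missing"

    def __getitem__(self, codon: str) -> str:
        return self.mapping[codon.upper()]

    def __contains__(self, codon: str) -> bool:
        return codon.upper() in self.mapping


def _positionwise_union(codons: set[str]) -> str:
    return "".join(
        IUPAC_CODE[frozenset().union(*(IUPAC_RESOLUTIONS[c[i]] for c in codons))]
        for i in range(3)
    )


def _synonymy_components(genetic_code_id: int) -> tuple[dict[str, str], frozenset[str]]:
    """Map each sense codon to its degen1 image; also return the stop set.

    Components are the connected components of the graph on sense codons with
    edges between single-position synonymous neighbours; the image of a
    component is the position-wise IUPAC union of its members.
    """
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    stops = frozenset(table.stop_codons)
    sense = sorted(table.forward_table)
    aa = dict(table.forward_table)

    parent = {c: c for c in sense}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for c in sense:
        for pos in range(3):
            for n in _NUC:
                if n == c[pos]:
                    continue
                d = c[:pos] + n + c[pos + 1 :]
                if d in aa and aa[d] == aa[c]:
                    ra, rb = find(c), find(d)
                    if ra != rb:
                        parent[ra] = rb

    members: dict[str, set[str]] = {}
    for c in sense:
        members.setdefault(find(c), set()).add(c)
    image = {}
    for comp in members.values():
        img = _positionwise_union(comp)
        for c in comp:
            image[c] = img
    return image, stops


def build_degen_table(genetic_code_id: int = 1, stop_policy: str = "to_missing") -> DegenerationTable:
    """Build the degen1 codon mapping for a translation table.

    Parameters
    ----------
    genetic_code_id:
        NCBI translation-table number (1 = standard code).
    stop_policy:
        ``to_missing`` maps stop codons to ``NNN`` with a logged warning at
        application time, ``passthrough`` leaves them unchanged, ``error``
        raises :class:`StopCodonError`.

    An ambiguous codon maps to the unique common degen1 image of its sense
    resolutions when one exists, to itself when it already is a degen1 image
    (keeping the table idempotent), and to ``NNN`` otherwise.
    """
    if stop_policy not in ("to_missing", "passthrough", "error"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    try:
        sense_image, stops = _synonymy_components(genetic_code_id)
    except KeyError as exc:
        raise ValueError(f"unknown genetic code id {genetic_code_id!r}") from exc

    images = set(sense_image.values())
    mapping: dict[str, str] = dict(sense_image)
    for codon in map("".join, product(_IUPAC_LETTERS, repeat=3)):
        if codon in mapping:
            continue
        if codon in images:
            mapping[codon] = codon  # degen1 images are fixed points
            continue
        if codon in stops:
            mapping[codon] = {"to_missing": "NNN", "passthrough": codon, "error": codon}[stop_policy]
            continue
        resolutions = resolve_codon(codon)
        sense_res = [c for c in resolutions if c in sense_image]
        if not sense_res:
            # resolves to stop codons only: treat like a stop
            mapping[codon] = "NNN" if stop_policy == "to_missing" else codon
            continue
        res_images = {sense_image[c] for c in sense_res}
        mapping[codon] = res_images.pop() if len(res_images) == 1 else "NNN"
    return DegenerationTable(mapping=mapping, genetic_code_id=genetic_code_id, stop_policy=stop_policy)


def degen1_codon(codon: str, table: DegenerationTable) -> str:
    """degen1 image of one codon; gap/missing positions pass through."""
    codon = codon.upper()
    if any(c in GAP_CHARS for c in codon):
        return codon
    resolutions = resolve_codon(codon)
    stops = _stop_set(table)
    if resolutions and all(r in stops for r in resolutions):
        if table.stop_policy == "error":
            raise StopCodonError(f"stop codon {codon!r}")
        if table.stop_policy == "to_missing":
            logger.warning("stop codon %s recoded to NNN", codon)
    return table[codon]


_STOP_CACHE: dict[int, frozenset[str]] = {}


def _stop_set(table: DegenerationTable) -> frozenset[str]:
    if table.genetic_code_id not in _STOP_CACHE:
        from Bio.Data import CodonTable

        _STOP_CACHE[table.genetic_code_id] = frozenset(
            CodonTable.unambiguous_dna_by_id[table.genetic_code_id].stop_codons
        )
    return _STOP_CACHE[table.genetic_code_id]


def _check_codon_exclusion(aln: CodonAlignment) -> list[int]:
    """Codon starts fully excluded; raise if a codon straddles the mask."""
    if not aln.excluded_columns:
        return []
    fully, partial = [], []
    for start in aln.codon_starts():
        n_excl = sum(1 for i in (start, start + 1, start + 2) if i in aln.excluded_columns)
        if n_excl == 3:
            fully.append(start)
        elif n_excl:
            partial.append(start)
    if partial:
        raise ValueError(
            "codons spanning an excluded-column boundary at start columns "
            f"{partial[:10]}{'...' if len(partial) > 10 else ''}"
        )
    return fully


def degen1_alignment(aln: CodonAlignment, table: DegenerationTable | None = None) -> CodonAlignment:
    """Apply degen1 recoding codon-wise to an in-frame alignment.

    Dimensions and taxon order are preserved; fully excluded codons and
    out-of-frame leading/trailing columns pass through unchanged.  The
    operation is idempotent.
    """
    if table is None:
        table = build_degen_table()
    coding = aln.length - aln.frame_offset
    if coding % 3:
        raise ValueError(
            f"alignment length {aln.length} minus frame offset {aln.frame_offset} "
            "is not divisible by 3"
        )
    excluded_starts = set(_check_codon_exclusion(aln))
    starts = aln.codon_starts()
    new_seqs = []
    for i in range(aln.n_taxa):
        seq = aln.sequences[i]
        parts = [seq[: aln.frame_offset]]
        for start in starts:
            codon = seq[start : start + 3]
            parts.append(codon if start in excluded_starts else degen1_codon(codon, table))
        new_seqs.append("".join(parts))
    return replace(aln, sequences=tuple(new_seqs))


@dataclass(frozen=True)
class CharsetPartition:
    """Disjoint, exhaustive split of included columns into two character sets.

    ``noLRall1nt2`` holds second codon positions plus first positions of
    non-Leu/Arg codons (nonsynonymous-only change); ``LRall1nt3`` holds third
    positions plus Leu/Arg first positions (mostly synonymous change).
    Indices are 0-based and sorted.
    """

    noLRall1nt2: tuple[int, ...]
    LRall1nt3: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "noLRall1nt2", tuple(sorted(self.noLRall1nt2)))
        object.__setattr__(self, "LRall1nt3", tuple(sorted(self.LRall1nt3)))
        if set(self.noLRall1nt2) & set(self.LRall1nt3):
            raise ValueError("character sets overlap")


_LEU_ARG = frozenset("LR")


def _codon_is_leu_arg(codon: str, aa_of: dict[str, str]) -> bool | None:
    """True/False when determinate; None for gap/missing/stop-only codons.

    Ambiguity-tolerant: counts as Leu/Arg only if *all* sense resolutions
    translate to Leu or Arg.
    """
    resolutions = resolve_codon(codon)
    aas = {aa_of[c] for c in resolutions if c in aa_of}
    if not aas:
        return None
    return aas <= _LEU_ARG


def classify_columns(
    aln: CodonAlignment, rule: str = "any_taxon", genetic_code_id: int = 1
) -> CharsetPartition:
    """Partition included columns into noLRall1nt2 and LRall1nt3.

    ``rule='any_taxon'``: a codon's first position joins LRall1nt3 when any
    taxon's codon there translates (all resolutions) to Leu or Arg;
    ``'all_taxa'``: when every taxon with a determinate codon does.
    """
    if rule not in ("any_taxon", "all_taxa"):
        raise ValueError(f"unknown rule {rule!r}")
    coding = aln.length - aln.frame_offset
    if coding % 3:
        raise ValueError("unresolvable reading frame: length not divisible by 3")
    from Bio.Data import CodonTable

    aa_of = dict(CodonTable.unambiguous_dna_by_id[genetic_code_id].forward_table)

    no_lr: list[int] = []
    lr: list[int] = []
    excluded = aln.excluded_columns
    for start in aln.codon_starts():
        flags = [
            _codon_is_leu_arg(seq[start : start + 3], aa_of) for seq in aln.sequences
        ]
        known = [f for f in flags if f is not None]
        if rule == "any_taxon":
            is_lr = any(known)
        else:
            is_lr = bool(known) and all(known)
        nt1, nt2, nt3 = start, start + 1, start + 2
        if nt1 not in excluded:
            (lr if is_lr else no_lr).append(nt1)
        if nt2 not in excluded:
            no_lr.append(nt2)
        if nt3 not in excluded:
            lr.append(nt3)
    # out-of-frame leading/trailing columns are not classifiable; report them
    # with the nonsynonymous set only if they are regular nt1/nt2 positions is
    # impossible, so they are left out of both sets (they are rare plumbing).
    return CharsetPartition(noLRall1nt2=tuple(no_lr), LRall1nt3=tuple(lr))
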