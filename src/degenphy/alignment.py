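"""In-frame codon alignment container and frame validation.

The central data object is :class:`CodonAlignment`: an aligned matrix of IUPAC
nucleotide codes (plus ``-`` for gaps and ``?`` for missing data) with a codon
reading frame.  Column coordinates are 0-based half-open internally; NEXUS
output converts to the 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

IUPAC_RESOLUTIONS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: reverse lookup: nucleotide set -> IUPAC code
IUPAC_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_RESOLUTIONS.items() if k != "U"}

GAP_CHARS = frozenset("-?")
VALID_CHARS = frozenset(IUPAC_RESOLUTIONS) | GAP_CHARS


def resolve_codon(codon: str) -> list[str]:
    """All unambiguous ACGT codons compatible with an IUPAC codon.

    Returns an empty list if the codon contains a gap or missing character.
    """
    if any(c in GAP_CHARS for c in codon):
        return []
    sets = [IUPAC_RESOLUTIONS[c] for c in codon]
    return [a + b + c for a in sorted(sets[0]) for b in sorted(sets[1]) for c in sorted(sets[2])]


@dataclass(frozen=True)
class CodonAlignment:
    """Aligned in-frame protein-coding nucleotide matrix.

    Parameters
    ----------
    taxa:
        Ordered, unique, non-empty taxon labels.
    sequences:
        One string per taxon, equal lengths, over IUPAC codes plus ``-``/``?``.
    frame_offset:
        Number of leading columns before the first complete codon.
    excluded_columns:
        0-based indices of masked (excluded) columns.
    """

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    frame_offset: int = 0
    excluded_columns: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "sequences", tuple(s.upper() for s in self.sequences))
        object.__setattr__(self, "excluded_columns", frozenset(self.excluded_columns))
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences must have equal length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        if any(not t for t in self.taxa):
            raise ValueError("taxon labels must be non-empty")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences differ in length: {sorted(lengths)}")
        for t, s in zip(self.taxa, self.sequences):
            bad = set(s) - VALID_CHARS
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in sequence of {t!r}")
        if self.excluded_columns and (
            min(self.excluded_columns) < 0 or max(self.excluded_columns) >= self.length
        ):
            raise ValueError("excluded_columns out of bounds")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence_of(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def codon_starts(self) -> list[int]:
        """Start columns of all complete codons in the reading frame."""
        return list(range(self.frame_offset, self.length - 2, 3))

    def iter_codons(self, taxon_index: int) -> Iterator[tuple[int, str]]:
        """Yield (start_column, codon) over complete in-frame codons."""
        seq = self.sequences[taxon_index]
        for start in self.codon_starts():
            yield start, seq[start : start + 3]

    def drop_excluded(self) -> "CodonAlignment":
        """Remove masked columns, compacting coordinates."""
        if not self.excluded_columns:
            return self
        keep = [i for i in range(self.length) if i not in self.excluded_columns]
        seqs = tuple("".join(s[i] for i in keep) for s in self.sequences)
        return CodonAlignment(self.taxa, seqs, frame_offset=self.frame_offset)

    def subset(self, keep: Sequence[str]) -> "CodonAlignment":
        """Restrict to the given taxa, preserving their requested order."""
        missing = [t for t in keep if t not in self.taxa]
        if missing:
            raise KeyError(f"unknown taxa: {missing}")
        idx = [self.taxa.index(t) for t in keep]
        return replace(
            self,
            taxa=tuple(self.taxa[i] for i in idx),
            sequences=tuple(self.sequences[i] for i in idx),
        )


@dataclass(frozen=True)
class FrameReport:
    """Outcome of frame validation; reporting only, never mutates data."""

    in_frame: bool
    #: columns (after frame_offset) not forming complete codons
    trailing_columns: int
    #: taxon -> 0-based codon indices of internal stop codons
    stop_codons: dict[str, tuple[int, ...]]

    @property
    def n_anomalies(self) -> int:
        n = sum(len(v) for v in self.stop_codons.values())
        if not self.in_frame:
            n += 1
        return n


_STOPS_BY_CODE: dict[int, frozenset[str]] = {}


def _stop_codons(genetic_code_id: int = 1) -> frozenset[str]:
    if genetic_code_id not in _STOPS_BY_CODE:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
        _STOPS_BY_CODE[genetic_code_id] = frozenset(table.stop_codons)
    return _STOPS_BY_CODE[genetic_code_id]


def validate_frame(aln: CodonAlignment, genetic_code_id: int = 1) -> FrameReport:
    """Check reading-frame consistency and scan for internal stop codons.

    A codon is counted as a stop only when every IUPAC resolution is a stop
    codon; a terminal stop (last complete codon) is not counted as internal.
    """
    stops = _stop_codons(genetic_code_id)
    coding = aln.length - aln.frame_offset
    trailing = coding % 3
    starts = aln.codon_starts()
    per_taxon: dict[str, tuple[int, ...]] = {}
    for i, taxon in enumerate(aln.taxa):
        hits = []
        for codon_idx, start in enumerate(starts[:-1]):  # internal only
            codon = aln.sequences[i][start : start + 3]
            res = resolve_codon(codon)
            if res and all(r in stops for r in res):
                hits.append(codon_idx)
        # the final codon is terminal, never internal
        if hits:
            per_taxon[taxon] = tuple(hits)
    return FrameReport(in_frame=(trailing == 0), trailing_columns=trailing, stop_codons=per_taxon)
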