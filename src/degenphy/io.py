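"""Readers and writers for NEXUS/FASTA alignments and newick/NEXUS tree files.

The NEXUS alignment dialect accepted is the simple one used for multi-gene
matrices: a DATA or CHARACTERS block (sequential or interleaved, bracketed
comments, quoted taxon names) optionally followed by a SETS block with
CHARSET and EXSET statements.  Charset coordinates are 1-based inclusive on
disk (the NEXUS convention, with ``a-b\\step`` strides and ``.`` for the last
character) and 0-based half-open in memory.  Tree IO is delegated to
dendropy, which honours TRANSLATE tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from degenphy.alignment import CodonAlignment


class AlignmentParseError(ValueError):
    """Malformed alignment file; message carries a line number when known."""


@dataclass(frozen=True)
class NexusDocument:
    """Parsed alignment plus any character sets defined alongside it."""

    alignment: CodonAlignment
    charsets: dict[str, tuple[int, ...]] = field(default_factory=dict)


_COMMENT_RE = re.compile(r"\[[^\]]*\]", re.S)


def _strip_comments(text: str) -> str:
    # preserve line structure so error messages keep meaningful line numbers
    return _COMMENT_RE.sub(lambda m: re.sub(r"[^\n]", " ", m.group(0)), text)


def _parse_positions(spec: str, nchar: int, line_no: int) -> tuple[int, ...]:
    """NEXUS 1-based position list ('1-30 45 60-90\\3 100-.') to 0-based indices."""
    out: list[int] = []
    for token in spec.split():
        m = re.fullmatch(r"(\d+|\.)(?:-(\d+|\.))?(?:\\(\d+))?", token)
        if not m:
            raise AlignmentParseError(f"line {line_no}: malformed charset token {token!r}")
        start = nchar if m.group(1) == "." else int(m.group(1))
        stop = start if m.group(2) is None else (nchar if m.group(2) == "." else int(m.group(2)))
        step = int(m.group(3) or 1)
        if not 1 <= start <= stop <= nchar:
            raise AlignmentParseError(
                f"line {line_no}: charset positions {token!r} out of bounds 1..{nchar}"
            )
        out.extend(range(start - 1, stop, step))
    return tuple(sorted(set(out)))


def _tokenize_matrix(
    body: list[tuple[int, str]], ntax: int, nchar: int, interleaved: bool
) -> tuple[list[str], list[str]]:
    taxa: list[str] = []
    chunks: dict[str, list[str]] = {}
    for line_no, line in body:
        line = line.strip()
        if not line:
            continue
        m = re.match(r"'([^']*)'\s*(.*)$|\"([^\"]*)\"\s*(.*)$|(\S+)\s*(.*)$", line)
        name = m.group(1) or m.group(3) or m.group(5)
        rest = (m.group(2) or m.group(4) or m.group(6) or "").replace(" ", "").replace("\t", "")
        if name in chunks and not interleaved:
            raise AlignmentParseError(f"line {line_no}: duplicate taxon {name!r}")
        if name not in chunks:
            if len(taxa) >= ntax and rest:
                raise AlignmentParseError(
                    f"line {line_no}: more than the declared NTAX={ntax} taxa"
                )
            taxa.append(name)
            chunks[name] = []
        chunks[name].append(rest)
    seqs = ["".join(chunks[t]) for t in taxa]
    if len(taxa) != ntax:
        raise AlignmentParseError(f"matrix has {len(taxa)} taxa, dimensions declare {ntax}")
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise AlignmentParseError(f"duplicate taxa in matrix: {dupes}")
    for t, s in zip(taxa, seqs):
        if len(s) != nchar:
            raise AlignmentParseError(
                f"sequence of {t!r} has {len(s)} characters, dimensions declare {nchar}"
            )
    return taxa, seqs


def _read_nexus(path: Path) -> NexusDocument:
    text = _strip_comments(path.read_text())
    lines = text.split("\n")
    if not lines or not lines[0].strip().lower().startswith("#nexus"):
        raise AlignmentParseError("line 1: file does not start with #NEXUS")

    joined = "\n".join(lines)
    block_re = re.compile(r"begin\s+(data|characters)\s*;(.*?)\bend\s*;", re.I | re.S)
    m = block_re.search(joined)
    if not m:
        raise AlignmentParseError("no DATA or CHARACTERS block found")
    block = m.group(2)
    block_line0 = joined[: m.start()].count("\n")

    dim = re.search(r"dimensions([^;]*);", block, re.I | re.S)
    if not dim:
        raise AlignmentParseError("no DIMENSIONS statement in data block")
    ntax_m = re.search(r"ntax\s*=\s*(\d+)", dim.group(1), re.I)
    nchar_m = re.search(r"nchar\s*=\s*(\d+)", dim.group(1), re.I)
    if not ntax_m or not nchar_m:
        raise AlignmentParseError("DIMENSIONS must declare NTAX and NCHAR")
    ntax, nchar = int(ntax_m.group(1)), int(nchar_m.group(1))
    fmt = re.search(r"format([^;]*);", block, re.I | re.S)
    interleaved = bool(fmt and re.search(r"interleave", fmt.group(1), re.I))

    mat = re.search(r"\bmatrix\b(.*?);", block, re.I | re.S)
    if not mat:
        raise AlignmentParseError("no MATRIX statement in data block")
    mat_line0 = block_line0 + block[: mat.start()].count("\n")
    body = [
        (mat_line0 + i + 1, line)
        for i, line in enumerate(mat.group(1).split("\n"))
    ]
    taxa, seqs = _tokenize_matrix(body, ntax, nchar, interleaved)

    charsets: dict[str, tuple[int, ...]] = {}
    excluded: tuple[int, ...] = ()
    sets_re = re.compile(r"begin\s+sets\s*;(.*?)\bend\s*;", re.I | re.S)
    sm = sets_re.search(joined)
    if sm:
        sets_line0 = joined[: sm.start()].count("\n")
        for stmt in re.finditer(
            r"(charset|exset)\s+(\S+?)\s*(?:\(\s*\S+\s*\))?\s*=\s*([^;]+);",
            sm.group(1),
            re.I | re.S,
        ):
            line_no = sets_line0 + sm.group(1)[: stmt.start()].count("\n") + 1
            positions = _parse_positions(" ".join(stmt.group(3).split()), nchar, line_no)
            if stmt.group(1).lower() == "charset":
                charsets[stmt.group(2)] = positions
            else:
                excluded = tuple(sorted(set(excluded) | set(positions)))

    aln = CodonAlignment(tuple(taxa), tuple(seqs), excluded_columns=frozenset(excluded))
    return NexusDocument(alignment=aln, charsets=charsets)


def _read_fasta(path: Path) -> NexusDocument:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentParseError(f"{path}: no FASTA records")
    aln = CodonAlignment(
        tuple(r.id for r in records), tuple(str(r.seq) for r in records)
    )
    return NexusDocument(alignment=aln)


def read_alignment(path, format: str | None = None) -> NexusDocument:
    """Read a NEXUS or FASTA alignment; format inferred from suffix if omitted."""
    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in (".nex", ".nexus", ".nxs") else "fasta"
    if format == "nexus":
        return _read_nexus(path)
    if format == "fasta":
        return _read_fasta(path)
    raise ValueError(f"unknown format {format!r}")


def _format_positions(indices: tuple[int, ...]) -> str:
    """0-based indices to compact 1-based inclusive NEXUS ranges."""
    out = []
    run_start = prev = None
    for i in indices:
        if run_start is None:
            run_start = prev = i
        elif i == prev + 1:
            prev = i
        else:
            out.append(f"{run_start + 1}" if run_start == prev else f"{run_start + 1}-{prev + 1}")
            run_start = prev = i
    if run_start is not None:
        out.append(f"{run_start + 1}" if run_start == prev else f"{run_start + 1}-{prev + 1}")
    return " ".join(out)


def write_alignment(
    doc: NexusDocument | CodonAlignment,
    path,
    format: str | None = None,
    wrap: int = 80,
) -> None:
    """Write NEXUS (DATA + optional SETS block) or FASTA."""
    if isinstance(doc, CodonAlignment):
        doc = NexusDocument(alignment=doc)
    aln = doc.alignment
    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in (".nex", ".nexus", ".nxs") else "fasta"
    if format == "fasta":
        with path.open("w") as fh:
            for t, s in zip(aln.taxa, aln.sequences):
                fh.write(f">{t}\n")
                for i in range(0, len(s), wrap):
                    fh.write(s[i : i + wrap] + "\n")
        return
    if format != "nexus":
        raise ValueError(f"unknown format {format!r}")

    def quote(name: str) -> str:
        return f"'{name}'" if re.search(r"[\s()\[\]{}/\\,;:=*'\"`<>]", name) else name

    name_w = max(len(quote(t)) for t in aln.taxa) + 2
    with path.open("w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={aln.n_taxa} NCHAR={aln.length};\n")
        fh.write("    FORMAT DATATYPE=DNA GAP=- MISSING=?;\n")
        fh.write("    MATRIX\n")
        for t, s in zip(aln.taxa, aln.sequences):
            fh.write(f"    {quote(t):<{name_w}}{s}\n")
        fh.write("    ;\nEND;\n")
        has_sets = doc.charsets or aln.excluded_columns
        if has_sets:
            fh.write("\nBEGIN SETS;\n")
            for name, idx in doc.charsets.items():
                fh.write(f"    CHARSET {name} = {_format_positions(tuple(idx))};\n")
            if aln.excluded_columns:
                excl = tuple(sorted(aln.excluded_columns))
                fh.write(f"    EXSET excluded = {_format_positions(excl)};\n")
            fh.write("END;\n")


def write_charsets_table(charsets: dict[str, tuple[int, ...]], path) -> None:
    """Plain two-column text table: character set name, 1-based positions."""
    with Path(path).open("w") as fh:
        fh.write("charset\tpositions\n")
        for name, idx in charsets.items():
            fh.write(f"{name}\t{_format_positions(tuple(idx))}\n")


def read_trees(path, format: str | None = None) -> list[dendropy.Tree]:
    """Read newick (one per line) or NEXUS TREES-block tree files."""
    path = Path(path)
    if format is None:
        head = path.read_text()[:200].lstrip().lower()
        format = "nexus" if head.startswith("#nexus") else "newick"
    trees = dendropy.TreeList.get(path=str(path), schema=format)
    return list(trees)


def write_trees(trees, path, format: str = "newick") -> None:
    """Write trees; internal-node labels (support) and lengths preserved."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    tlist = dendropy.TreeList()
    for t in trees:
        tlist.append(dendropy.Tree(t), taxon_import_strategy="migrate")
    tlist.write(path=str(path), schema=format, suppress_rooting=(format == "newick"))


def write_distance_matrix(D, path, format: str = "phylip") -> None:
    """PHYLIP-style square matrix or TSV."""
    path = Path(path)
    with path.open("w") as fh:
        if format == "phylip":
            fh.write(f"{len(D.taxa)}\n")
            for i, t in enumerate(D.taxa):
                row = " ".join(f"{v:.6f}" for v in D.values[i])
                fh.write(f"{t:<12} {row}\n")
        elif format == "tsv":
            fh.write("taxon\t" + "\t".join(D.taxa) + "\n")
            for i, t in enumerate(D.taxa):
                fh.write(t + "\t" + "\t".join(f"{v:.6f}" for v in D.values[i]) + "\n")
        else:
            raise ValueError(f"unknown format {format!r}")


def write_composition_table(aln: CodonAlignment, path, ambiguity_rule: str = "exclude") -> None:
    """Per-taxon A/C/G/T proportions as TSV."""
    from degenphy.composition import composition_vector

    with Path(path).open("w") as fh:
        fh.write("taxon\tA\tC\tG\tT\tn_counted\n")
        for t, s in zip(aln.taxa, aln.sequences):
            v = composition_vector(s, ambiguity_rule)
            props = "\t".join(f"{p:.6f}" for p in v.proportions)
            fh.write(f"{t}\t{props}\t{v.n_counted:g}\n")
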