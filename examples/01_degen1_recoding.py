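"""degen1-recode a small codon alignment and derive its character sets.

Builds a six-codon toy alignment, applies degen1 recoding (every position
free to vary synonymously becomes an IUPAC ambiguity code), and partitions
the columns into the nonsynonymous-only (noLRall1nt2) and mostly-synonymous
(LRall1nt3) character sets.
"""

from degenphy import (
    CodonAlignment,
    build_degen_table,
    classify_columns,
    degen1_alignment,
)

aln = CodonAlignment(
    taxa=("moth_a", "moth_b"),
    sequences=("CATTTAAGACTTGAAAGC", "CACCTGCGCCTAGAGTCA"),
)
table = build_degen_table()
recoded = degen1_alignment(aln, table)

print("raw    :", *aln.sequences)
print("degen1 :", *recoded.sequences)
# Both rows recode to the same degen1 sequence wherever the two taxa differ
# only synonymously (His CAT/CAC -> CAY, Leu TTA/CTG -> YTN, Arg AGA/CGC ->
# MGN ...); only nonsynonymous differences (here Ser2 AGC vs Ser1 TCA at the
# last codon) survive.

part = classify_columns(aln, rule="any_taxon")
print("noLRall1nt2 (1-based):", [i + 1 for i in part.noLRall1nt2])
print("LRall1nt3   (1-based):", [i + 1 for i in part.LRall1nt3])
# Third positions and the first positions of Leu/Arg codons carry mostly
# synonymous change and land in LRall1nt3; the rest is nonsynonymous-only.
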