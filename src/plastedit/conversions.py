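"""Strand bookkeeping for the two plastid editing chemistries.

Edits are defined on the transcript strand: C-to-U means a cytidine of the
transcript is deaminated to uridine.  In plus-strand (reference) space this
appears as C>T for plus-strand transcripts and G>A for minus-strand ones;
U-to-C is the mirror image.  Only these two mismatch classes are ever called.
"""

C_TO_U = "C-to-U"
U_TO_C = "U-to-C"
EDIT_TYPES = (C_TO_U, U_TO_C)

#: (edit_type, transcript strand) -> (plus-strand ref base, plus-strand edited base)
PLUS_STRAND_BASES = {
    (C_TO_U, "+"): ("C", "T"),
    (C_TO_U, "-"): ("G", "A"),
    (U_TO_C, "+"): ("T", "C"),
    (U_TO_C, "-"): ("A", "G"),
}

#: (plus-strand ref base, plus-strand alt base) -> (edit_type, transcript strand)
#: every reference base admits exactly one editing interpretation
FROM_MISMATCH = {v: k for k, v in PLUS_STRAND_BASES.items()}


def plus_strand_bases(edit_type: str, strand: str) -> tuple[str, str]:
    return PLUS_STRAND_BASES[(edit_type, strand)]
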