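"""Deterministic reverse translation for synthetic library construction.

One fixed codon per residue (the most frequently used codon for each amino
acid in Saccharomyces cerevisiae), so that a peptide always reverse-translates
to the same coding DNA and synthetic libraries are byte-reproducible.
"""

from __future__ import annotations

from Bio.Seq import Seq

#: Most-frequent S. cerevisiae codon per amino acid.
YEAST_PREFERRED_CODON: dict[str, str] = {
    "A": "GCT", "R": "AGA", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "TTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCA",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

CANONICAL_RESIDUES = frozenset(YEAST_PREFERRED_CODON)


def reverse_translate(peptide: str) -> str:
    """Map a peptide to coding DNA using the fixed yeast-preferred codon table."""
    try:
        return "".join(YEAST_PREFERRED_CODON[aa] for aa in peptide)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r} in {peptide!r}") from exc


def translate(dna: str) -> str:
    """Translate coding DNA (standard genetic code); '*' marks stop codons."""
    if len(dna) % 3 != 0:
        raise ValueError(f"DNA length {len(dna)} not a multiple of 3")
    return str(Seq(dna).translate())
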