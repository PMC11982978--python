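"""Docking-site library container and I/O.

A screened library is a whitelist of 14-mer docking-site peptides, each with
its coding DNA, a provenance label (source protein for designed libraries,
``synthetic`` for simulated ones) and a coarse motif class. Construction
validates the structural invariants; conformance to the library design
consensus is fatal for synthetic libraries and a warning for user-supplied
ones (real designs may include deliberate outliers or legacy members).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import CANONICAL_RESIDUES, translate
from .motifs import LIBRARY_CONSENSUS, scan_motif

PEPTIDE_LENGTH = 14
MOTIF_CLASSES = ("HEPTP_like", "Pro_phi", "other")

__all__ = ["LibraryMember", "DSiteLibrary", "LibraryError",
           "PEPTIDE_LENGTH", "MOTIF_CLASSES"]


class LibraryError(ValueError):
    """Raised when a library violates a structural invariant."""


@dataclass(frozen=True)
class LibraryMember:
    member_id: str
    source_name: str
    peptide: str
    dna: str
    motif_class: str = "other"


@dataclass
class DSiteLibrary:
    """Whitelist of screened docking-site variants.

    Parameters
    ----------
    members : iterable of LibraryMember
    strict_consensus : bool
        If True (synthetic libraries), a peptide that does not match the
        library consensus is an error; if False, a warning.
    """

    members: list = field(default_factory=list)
    strict_consensus: bool = False

    def __post_init__(self):
        self.members = list(self.members)
        self.validate()

    def validate(self) -> None:
        seen_ids, seen_dna = set(), {}
        nonconforming = []
        for m in self.members:
            if m.member_id in seen_ids:
                raise LibraryError(f"duplicate member_id {m.member_id!r}")
            seen_ids.add(m.member_id)
            if len(m.peptide) != PEPTIDE_LENGTH:
                raise LibraryError(
                    f"{m.member_id}: peptide length {len(m.peptide)} != {PEPTIDE_LENGTH}")
            bad = set(m.peptide) - CANONICAL_RESIDUES
            if bad:
                raise LibraryError(f"{m.member_id}: non-canonical residues {sorted(bad)}")
            if translate(m.dna) != m.peptide:
                raise LibraryError(f"{m.member_id}: DNA does not translate to peptide")
            if m.dna in seen_dna:
                raise LibraryError(
                    f"duplicate DNA for {seen_dna[m.dna]} and {m.member_id}")
            seen_dna[m.dna] = m.member_id
            if m.motif_class not in MOTIF_CLASSES:
                raise LibraryError(f"{m.member_id}: unknown motif class {m.motif_class!r}")
            if not scan_motif(m.peptide, LIBRARY_CONSENSUS):
                nonconforming.append(m.member_id)
        if nonconforming:
            msg = (f"{len(nonconforming)} member(s) do not match the library "
                   f"consensus (e.g. {nonconforming[:3]})")
            if self.strict_consensus:
                raise LibraryError(msg)
            warnings.warn(msg, stacklevel=2)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def member_ids(self) -> list:
        return [m.member_id for m in self.members]

    @property
    def dna_length(self) -> int:
        if not self.members:
            return 3 * PEPTIDE_LENGTH
        return len(self.members[0].dna)

    def dna_index(self) -> dict:
        return {m.dna: m.member_id for m in self.members}

    def peptide_index(self) -> dict:
        """Peptide -> member_id; first member wins on (DNA-distinct) collisions."""
        idx: dict = {}
        for m in self.members:
            idx.setdefault(m.peptide, m.member_id)
        return idx

    def peptides(self) -> dict:
        return {m.member_id: m.peptide for m in self.members}

    def get(self, member_id: str) -> LibraryMember:
        for m in self.members:
            if m.member_id == member_id:
                return m
        raise KeyError(member_id)

    # ---------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.member_id, m.source_name, m.peptide, m.dna, m.motif_class)
             for m in self.members],
            columns=["member_id", "source_name", "peptide", "dna", "motif_class"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strict_consensus: bool = False
                   ) -> "DSiteLibrary":
        members = [LibraryMember(str(r.member_id), str(r.source_name),
                                 str(r.peptide), str(r.dna), str(r.motif_class))
                   for r in df.itertuples(index=False)]
        return cls(members, strict_consensus=strict_consensus)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, strict_consensus: bool = False) -> "DSiteLibrary":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str),
                              strict_consensus=strict_consensus)

    def to_fasta(self, path, kind: str = "peptide") -> None:
        if kind not in ("peptide", "dna"):
            raise ValueError("kind must be 'peptide' or 'dna'")
        records = [SeqRecord(Seq(getattr(m, kind)), id=m.member_id, description="")
                   for m in self.members]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, kind: str = "peptide") -> "DSiteLibrary":
        """Build from FASTA (peptide or DNA). Missing provenance fields are
        filled with defaults; DNA is reverse-translated when absent."""
        from .codons import reverse_translate
        members = []
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if kind == "peptide":
                members.append(LibraryMember(rec.id, "unknown", seq,
                                             reverse_translate(seq)))
            else:
                members.append(LibraryMember(rec.id, "unknown", translate(seq), seq))
        return cls(members)
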