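"""Amplicon read counting: FASTQ -> member x sample count table.

Each sequencing read is expected to contain the library's variable region
flanked by fixed anchor sequences from the amplicon construct. Extraction is
exact-match and forward-strand only: the region between the first occurrence
of the 5' anchor and the first subsequent occurrence of the 3' anchor.
Whitelist assignment tries exact DNA first, then the exact translated
peptide, which tolerates synonymous PCR or sequencing artifacts without
introducing an error model. Every read is accounted for: it either
increments one member or one of four rejection reasons.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .library import DSiteLibrary
from .codons import translate
from .tables import CountTable, UNMATCHED_REASONS

__all__ = ["extract_variable_region", "translate_and_match", "count_samples"]

logger = logging.getLogger(__name__)

_DNA_ALPHABET = frozenset("ACGT")


def extract_variable_region(read_dna: str, anchors: tuple) -> str | None:
    """Substring strictly between the first 5' anchor occurrence and the
    first 3' anchor occurrence downstream of it; None when either is absent."""
    a5, a3 = anchors
    i = read_dna.find(a5)
    if i < 0:
        return None
    j = read_dna.find(a3, i + len(a5))
    if j < 0:
        return None
    return read_dna[i + len(a5):j]


class _WhitelistMatcher:
    """Member lookup by exact DNA, falling back to exact translated peptide."""

    def __init__(self, library: DSiteLibrary):
        self.dna_index = library.dna_index()
        self.peptide_index = library.peptide_index()
        self.expected_length = library.dna_length

    def match(self, region: str) -> tuple:
        """Return (member_id, None) on a hit or (None, reason) on rejection."""
        if len(region) != self.expected_length or len(region) % 3 != 0:
            return None, "bad_length"
        if not set(region) <= _DNA_ALPHABET:
            return None, "stop_or_ambiguous"
        member = self.dna_index.get(region)
        if member is not None:
            return member, None
        peptide = translate(region)
        if "*" in peptide:
            return None, "stop_or_ambiguous"
        member = self.peptide_index.get(peptide)
        if member is not None:
            return member, None
        return None, "not_in_whitelist"


def translate_and_match(region: str, library: DSiteLibrary) -> tuple:
    """Assign one extracted region to a whitelist member.

    Returns ``(member_id, None)`` or ``(None, reason)`` with reason one of
    ``bad_length``, ``stop_or_ambiguous``, ``not_in_whitelist``.
    """
    return _WhitelistMatcher(library).match(region)


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_samples(fastq_paths: dict, samples: pd.DataFrame,
                  library: DSiteLibrary,
                  anchors: tuple) -> CountTable:
    """Count whitelist members per sample from FASTQ files.

    Parameters
    ----------
    fastq_paths : mapping sample_id -> FASTQ path (optionally .gz)
    samples : sample metadata indexed by sample_id with columns genotype,
        condition, replicate, doublings; every (genotype, condition,
        replicate) screen must include a doublings-0 sample (the enrichment
        baseline is undefined without it).
    library : the screened whitelist
    anchors : (anchor5, anchor3) fixed flanking DNA
    """
    missing = set(samples.index) - set(fastq_paths)
    if missing:
        raise ValueError(f"no FASTQ given for samples {sorted(missing)}")
    matcher = _WhitelistMatcher(library)
    ids = library.member_ids
    row_of = {m: i for i, m in enumerate(ids)}
    counts = np.zeros((len(ids), len(samples.index)), dtype=np.int64)
    unmatched = pd.DataFrame(0, index=samples.index.copy(),
                             columns=list(UNMATCHED_REASONS), dtype=np.int64)

    for ci, sid in enumerate(samples.index):
        n_reads = 0
        with _open_maybe_gzip(fastq_paths[sid]) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                n_reads += 1
                region = extract_variable_region(str(rec.seq).upper(), anchors)
                if region is None:
                    unmatched.at[sid, "no_anchor"] += 1
                    continue
                member, reason = matcher.match(region)
                if member is None:
                    unmatched.at[sid, reason] += 1
                else:
                    counts[row_of[member], ci] += 1
        matched = int(counts[:, ci].sum())
        if n_reads == 0:
            logger.warning("sample %s: empty FASTQ", sid)
        else:
            logger.info("sample %s: %d/%d reads matched (%.1f%%)",
                        sid, matched, n_reads, 100.0 * matched / n_reads)

    table = pd.DataFrame(counts, index=pd.Index(ids, name="member_id"),
                         columns=samples.index.copy())
    return CountTable(table, samples, unmatched)
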