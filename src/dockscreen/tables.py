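"""Member x sample count table with screen metadata.

The central exchange object between the simulator / read counter and the
enrichment model: an integer (or, for the simulator's expected-count mode,
real) count matrix indexed by library member, with per-sample metadata
(genotype, selective vs nonselective condition, replicate index, cumulative
population doublings) and an optional per-sample report of discarded reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountTable", "UNMATCHED_REASONS", "CONDITIONS"]

UNMATCHED_REASONS = ("no_anchor", "bad_length", "stop_or_ambiguous",
                     "not_in_whitelist")
CONDITIONS = ("selective", "nonselective")

SAMPLE_COLUMNS = ["genotype", "condition", "replicate", "doublings"]


class CountTableError(ValueError):
    pass


def sample_order(samples: pd.DataFrame) -> list:
    """Canonical sample ordering: (genotype, condition, replicate, doublings)."""
    return list(samples.sort_values(SAMPLE_COLUMNS, kind="mergesort").index)


@dataclass
class CountTable:
    """Counts matrix (index member_id, columns sample_id) plus metadata.

    ``samples`` is indexed by sample_id with columns genotype, condition,
    replicate, doublings. ``unmatched`` (optional) is indexed by sample_id
    with one column per rejection reason.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unmatched: pd.DataFrame | None = None

    def __post_init__(self):
        self.samples = self.samples.copy()
        self.samples["replicate"] = self.samples["replicate"].astype(int)
        self.samples["doublings"] = self.samples["doublings"].astype(float)
        order = sample_order(self.samples)
        self.samples = self.samples.loc[order]
        self.counts = self.counts.loc[:, order]
        self.validate()

    def validate(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise CountTableError("counts columns and sample metadata disagree")
        if (self.counts.to_numpy() < 0).any():
            raise CountTableError("negative counts")
        if (self.samples["doublings"] < 0).any():
            raise CountTableError("negative doublings")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise CountTableError(f"unknown conditions {sorted(bad)}")
        for (g, c, r), grp in self.samples.groupby(
                ["genotype", "condition", "replicate"], sort=False):
            if not (grp["doublings"] == 0).any():
                raise CountTableError(
                    f"screen ({g}, {c}, replicate {r}) lacks a doublings-0 "
                    f"baseline sample")
        if self.unmatched is not None:
            missing = set(self.counts.columns) - set(self.unmatched.index)
            if missing:
                raise CountTableError(f"unmatched report missing samples {missing}")

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def member_ids(self) -> list:
        return list(self.counts.index)

    def screens(self):
        """Iterate (genotype, condition, replicate) -> sample metadata blocks,
        each sorted by doublings."""
        for key, grp in self.samples.groupby(
                ["genotype", "condition", "replicate"], sort=True):
            yield key, grp.sort_values("doublings")

    def subset(self, genotype=None, condition=None) -> "CountTable":
        mask = pd.Series(True, index=self.samples.index)
        if genotype is not None:
            mask &= self.samples["genotype"] == genotype
        if condition is not None:
            mask &= self.samples["condition"] == condition
        samples = self.samples[mask]
        unm = self.unmatched.loc[samples.index] if self.unmatched is not None else None
        return CountTable(self.counts[samples.index], samples, unm)

    # ---------------------------------------------------------------- I/O

    def write_tsv(self, prefix) -> None:
        """Write ``<prefix>.counts.tsv``, ``<prefix>.samples.tsv`` and, when
        present, ``<prefix>.unmatched.tsv``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.counts.rename_axis("member_id").to_csv(
            f"{prefix}.counts.tsv", sep="\t")
        self.samples.rename_axis("sample_id").to_csv(
            f"{prefix}.samples.tsv", sep="\t")
        if self.unmatched is not None:
            self.unmatched.rename_axis("sample_id").to_csv(
                f"{prefix}.unmatched.tsv", sep="\t")

    @classmethod
    def read_tsv(cls, prefix) -> "CountTable":
        prefix = Path(prefix)
        counts = pd.read_csv(f"{prefix}.counts.tsv", sep="\t", index_col="member_id")
        samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col="sample_id")
        unm_path = Path(f"{prefix}.unmatched.tsv")
        unmatched = (pd.read_csv(unm_path, sep="\t", index_col="sample_id")
                     if unm_path.exists() else None)
        return cls(counts, samples, unmatched)
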