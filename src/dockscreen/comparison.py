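"""Hit calling and cross-genotype interactome comparison.

A hit is a member whose replicate-averaged enrichment score stands more than
``z_threshold`` sample standard deviations above its screen mean (strictly
``Z > 3`` by default). Hits from the reference (wild-type) screen and two
mutant screens are categorized into:

* ``wt_unique`` — lost interactors: WT hits absent from both mutant hit sets;
* ``common`` — WT hits shared with at least one mutant;
* ``gained`` — hits in *both* mutants but not WT (the conservative reading of
  "uniquely hits for both mutants"; per-mutant-only sets are also reported).

Two follow-up analyses mirror the screen's interpretation steps: a relaxed
top-percent membership by mean ES (used to ask whether "gained" sequences
were merely borderline in the reference screen), and a ranking of
WT-selective candidates by the differential between the reference ES and the
mutant-average ES.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["call_hits", "categorize", "relaxed_rank_threshold",
           "rank_differential", "ComparisonResult", "compare_screens"]

logger = logging.getLogger(__name__)


def call_hits(z: pd.Series, z_threshold: float = 3.0, strict: bool = True) -> set:
    """Members with Z above threshold (strict > by default; the boundary
    value ``Z == z_threshold`` is excluded unless ``strict=False``)."""
    z = z.dropna()
    mask = z > z_threshold if strict else z >= z_threshold
    return set(z.index[mask])


@dataclass
class ComparisonResult:
    """Hit sets per genotype and their cross-screen categorization."""

    reference: str
    mutants: tuple
    hits: dict                       # genotype -> set
    wt_unique: set = field(init=False)
    common: set = field(init=False)       # WT hits shared with >=1 mutant
    common_both: set = field(init=False)  # WT hits shared with both mutants
    gained: set = field(init=False)       # hits in both mutants, not WT
    mutant_only: dict = field(init=False)  # per-mutant exclusive hits
    venn: dict = field(init=False)

    def __post_init__(self):
        wt = self.hits[self.reference]
        m1 = self.hits[self.mutants[0]]
        m2 = self.hits[self.mutants[1]]
        self.wt_unique = wt - (m1 | m2)
        self.common = wt & (m1 | m2)
        self.common_both = wt & m1 & m2
        self.gained = (m1 & m2) - wt
        self.mutant_only = {self.mutants[0]: m1 - (wt | m2),
                            self.mutants[1]: m2 - (wt | m1)}
        self.venn = {
            "wt_only": wt - m1 - m2,
            "m1_only": m1 - wt - m2,
            "m2_only": m2 - wt - m1,
            "wt_m1": (wt & m1) - m2,
            "wt_m2": (wt & m2) - m1,
            "m1_m2": (m1 & m2) - wt,
            "all": wt & m1 & m2,
        }

    def venn_counts(self) -> dict:
        return {k: len(v) for k, v in self.venn.items()}

    def summary(self) -> dict:
        """Machine-readable headline numbers for the three-screen comparison."""
        wt = self.hits[self.reference]
        out = {
            "hits": {g: len(h) for g, h in self.hits.items()},
            "venn": self.venn_counts(),
            "wt_unique": len(self.wt_unique),
            "common_any_mutant": len(self.common),
            "common_both_mutants": len(self.common_both),
            "gained": len(self.gained),
            "wt_unique_fraction": len(self.wt_unique) / len(wt) if wt else math.nan,
        }
        both = self.hits[self.mutants[0]] & self.hits[self.mutants[1]]
        out["gained_fraction_of_both"] = (len(self.gained) / len(both)
                                          if both else math.nan)
        return out


def categorize(hits_wt: set, hits_m1: set, hits_m2: set,
               labels: tuple = ("WT", "mutant1", "mutant2")) -> ComparisonResult:
    """Categorize three hit sets over a shared member universe."""
    return ComparisonResult(
        reference=labels[0], mutants=(labels[1], labels[2]),
        hits={labels[0]: set(hits_wt), labels[1]: set(hits_m1),
              labels[2]: set(hits_m2)})


def relaxed_rank_threshold(mean_es: pd.Series, pct: float = 3.0) -> set:
    """The ``ceil(pct * N / 100)`` members with highest mean ES.

    Boundary ties are broken by member_id lexicographic order (documented,
    deterministic). Missing scores are excluded from N.
    """
    if not 0 <= pct <= 100:
        raise ValueError("pct must be in [0, 100]")
    scored = mean_es.dropna()
    k = math.ceil(pct * len(scored) / 100.0)
    ranked = scored.sort_index().sort_values(ascending=False, kind="mergesort")
    return set(ranked.index[:k])


def rank_differential(es_by_genotype: pd.DataFrame, candidates: set,
                      n_top: int = 20, metric: str = "mean") -> pd.DataFrame:
    """Rank candidates by the reference-vs-mutant ES differential.

    ``es_by_genotype`` is a member x genotype mean-ES frame whose first
    column is the reference screen. The differential is
    ``delta = ES_ref - mean(ES_mutants)`` (``metric="mean"``) or
    ``ES_ref - max(ES_mutants)`` (``metric="max"``). Candidates missing any
    screen's score are dropped with a warning.
    """
    if metric not in ("mean", "max"):
        raise ValueError("metric must be 'mean' or 'max'")
    sub = es_by_genotype.loc[es_by_genotype.index.isin(candidates)]
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        logger.warning("rank_differential: dropped %d candidate(s) missing a "
                       "screen score", dropped)
    ref = complete.iloc[:, 0]
    mut = complete.iloc[:, 1:]
    delta = ref - (mut.mean(axis=1) if metric == "mean" else mut.max(axis=1))
    out = complete.copy()
    out["delta"] = delta
    # descending delta, member_id lexicographic on ties
    out = out.loc[out.index.sort_values()].sort_values(
        "delta", ascending=False, kind="mergesort")
    return out.head(n_top)


def compare_screens(scores, reference: str | None = None,
                    condition: str = "selective", z_threshold: float = 3.0,
                    strict: bool = True, relaxed_pct: float = 3.0,
                    n_top: int = 20) -> dict:
    """Full three-screen comparison from a fitted :class:`ScreenScores`.

    Returns a dict with the :class:`ComparisonResult`, the relaxed top-pct
    membership per genotype, the fraction of gained hits rescued by the
    relaxed reference threshold, and the top differential ranking.
    """
    genotypes = scores.genotypes()
    if reference is None:
        reference = "WT" if "WT" in genotypes else genotypes[0]
    mutants = [g for g in genotypes if g != reference]
    if len(mutants) != 2:
        raise ValueError(f"need exactly two mutant screens, got {mutants}")

    hit_sets = {g: call_hits(scores.z(g, condition), z_threshold, strict)
                for g in [reference, *mutants]}
    result = ComparisonResult(reference, tuple(mutants), hit_sets)

    es = pd.DataFrame({g: scores.mean_es(g, condition)
                       for g in [reference, *mutants]})
    relaxed = {g: relaxed_rank_threshold(es[g], relaxed_pct)
               for g in [reference, *mutants]}
    gained_rescued = (len(result.gained & relaxed[reference]) / len(result.gained)
                      if result.gained else math.nan)
    differential = rank_differential(es, result.wt_unique or set(es.index),
                                     n_top=n_top)
    return {"result": result, "es": es, "relaxed": relaxed,
            "gained_rescued_fraction": gained_rescued,
            "differential": differential}
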