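"""Short linear motif scanning and positional overrepresentation statistics.

Two motif grammars matter for MAPK docking-site screens:

* the docking-site library consensus ``[RK]x{0,2}[RK]x{3,5}[ILV]x[FILMV]`` —
  a basic patch joined to a hydrophobic phi-x-phi motif by a variable linker;
* the CD-site-dependent motif ``[IL]xxRR`` found near the N-terminus of
  docking sites that lose binding when the kinase's common-docking residues
  are mutated.

Motifs are written in a small grammar: ``[XYZ]`` is a residue class, a bare
uppercase letter is a singleton class, ``x`` is a single wildcard, and
``x{m,n}`` (or ``x{k}``) is a variable-length spacer. ``scan_motif``
enumerates every placement over all allowed spacer lengths, which is the
behaviour a regex with lazy quantifiers does not give for free.

``positional_overrepresentation`` implements a probability-logo statistic:
per-position, per-residue binomial tail p-values of foreground counts against
background frequencies, with letter heights ``-log10 p`` signed by the
direction of the deviation and a Bonferroni significance cut.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codons import CANONICAL_RESIDUES

__all__ = [
    "MotifElement",
    "MotifDefinition",
    "MotifMatch",
    "parse_motif",
    "scan_motif",
    "classify_peptides",
    "PositionalEnrichment",
    "positional_overrepresentation",
    "plot_logo",
    "LIBRARY_CONSENSUS",
    "HEPTP_MOTIF",
]


class MotifError(ValueError):
    """Raised for malformed motif definitions."""


@dataclass(frozen=True)
class MotifElement:
    """One fixed residue class plus the wildcard spacer that follows it."""

    residues: frozenset
    min_gap: int = 0  # wildcards between this element and the next
    max_gap: int = 0

    def __post_init__(self):
        if not self.residues:
            raise MotifError("empty residue class")
        if not self.residues <= CANONICAL_RESIDUES:
            bad = sorted(self.residues - CANONICAL_RESIDUES)
            raise MotifError(f"non-canonical residues in class: {bad}")
        if self.min_gap < 0 or self.max_gap < self.min_gap:
            raise MotifError(f"bad spacer range ({self.min_gap},{self.max_gap})")


@dataclass(frozen=True)
class MotifDefinition:
    """Ordered residue classes with inter-element spacing ranges.

    ``window`` restricts the 1-based start position of a match; ``None``
    allows a match anywhere in the peptide.
    """

    name: str
    elements: tuple
    window: tuple | None = None

    def __post_init__(self):
        if not self.elements:
            raise MotifError("motif needs at least one element")
        if self.elements[-1].max_gap != 0:
            raise MotifError("trailing spacer after last element is meaningless")
        if self.window is not None:
            lo, hi = self.window
            if lo < 1 or hi < lo:
                raise MotifError(f"bad start window {self.window}")

    @property
    def min_span(self) -> int:
        return len(self.elements) + sum(e.min_gap for e in self.elements)

    @property
    def max_span(self) -> int:
        return len(self.elements) + sum(e.max_gap for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    start: int  # 1-based position of the first element
    end: int    # 1-based position of the last element (inclusive)
    span: str   # matched substring of the peptide


_TOKEN = re.compile(
    r"\[(?P<cls>[A-Z]+)\]"        # residue class
    r"|x\{(?P<lo>\d+)(?:,(?P<hi>\d+))?\}"  # spacer with counts
    r"|(?P<x>x)"                  # single wildcard
    r"|(?P<lit>[A-Z])"            # bare literal residue
    r"|(?P<dash>-)"               # cosmetic separator, ignored
)


def parse_motif(pattern: str, name: str | None = None,
                window: tuple | None = None) -> MotifDefinition:
    """Parse a motif grammar string into a :class:`MotifDefinition`.

    >>> parse_motif("[IL]xxRR", name="HEPTP", window=(1, 4)).min_span
    5
    """
    classes: list[frozenset] = []
    gaps: list[list[int]] = []  # gap range after each class
    pos = 0
    while pos < len(pattern):
        m = _TOKEN.match(pattern, pos)
        if m is None:
            raise MotifError(f"cannot parse motif at {pattern[pos:]!r}")
        pos = m.end()
        if m.group("dash"):
            continue
        if m.group("cls") or m.group("lit"):
            classes.append(frozenset(m.group("cls") or m.group("lit")))
            gaps.append([0, 0])
        else:
            if not classes:
                raise MotifError("motif may not start with a spacer")
            lo = 1 if m.group("x") else int(m.group("lo"))
            hi = lo if m.group("x") or m.group("hi") is None else int(m.group("hi"))
            if hi < lo:
                raise MotifError(f"bad spacer x{{{lo},{hi}}}")
            gaps[-1][0] += lo
            gaps[-1][1] += hi
    if not classes:
        raise MotifError(f"no residue classes in {pattern!r}")
    elements = tuple(
        MotifElement(cls, lo, hi) for cls, (lo, hi) in zip(classes, gaps)
    )
    return MotifDefinition(name or pattern, elements, window)


def _extend(peptide: str, elements: tuple, pos: int) -> Iterable[int]:
    """Yield end positions (0-based, inclusive) of matches anchored at pos."""
    elem = elements[0]
    if pos >= len(peptide) or peptide[pos] not in elem.residues:
        return
    if len(elements) == 1:
        yield pos
        return
    for gap in range(elem.min_gap, elem.max_gap + 1):
        yield from _extend(peptide, elements[1:], pos + 1 + gap)


def scan_motif(peptide: str, motif: MotifDefinition) -> list:
    """Enumerate all placements of ``motif`` in ``peptide``.

    Matches are reported as 1-based (start, end) pairs with the covered
    substring. At a given start, shorter-spacing placements come first;
    starts are scanned left to right within the motif's window.
    """
    bad = set(peptide) - CANONICAL_RESIDUES
    if bad:
        raise ValueError(f"non-canonical residues {sorted(bad)} in peptide")
    if motif.window is None:
        starts = range(len(peptide))
    else:
        lo, hi = motif.window
        starts = range(lo - 1, min(hi, len(peptide)))
    out = []
    for s in starts:
        for e in _extend(peptide, motif.elements, s):
            out.append(MotifMatch(s + 1, e + 1, peptide[s:e + 1]))
    return out


#: Library design consensus: basic patch, linker, hydrophobic phi-x-phi.
LIBRARY_CONSENSUS = parse_motif("[RK]x{0,2}[RK]x{3,5}[ILV]x[FILMV]",
                                name="library_consensus")

#: WT-selective CD-site motif, constrained to start near the N-terminus.
HEPTP_MOTIF = parse_motif("[IL]xxRR", name="heptp_ilxxrr", window=(1, 4))


def classify_peptides(peptides, motifs) -> tuple:
    """Match every peptide against every motif.

    Parameters
    ----------
    peptides : mapping id -> peptide, or sequence of peptides
    motifs : mapping name -> MotifDefinition, or sequence of MotifDefinition

    Returns
    -------
    (table, fractions) : per-peptide boolean DataFrame and per-motif match
    fraction Series (NaN for an empty peptide set).
    """
    if not isinstance(peptides, dict):
        peptides = {p: p for p in peptides}
    if not isinstance(motifs, dict):
        motifs = {m.name: m for m in motifs}
    rows = {
        pid: {name: bool(scan_motif(pep, mot)) for name, mot in motifs.items()}
        for pid, pep in peptides.items()
    }
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(motifs)).astype(bool)
    if len(table):
        fractions = table.mean(axis=0)
    else:
        fractions = pd.Series(np.nan, index=list(motifs))
    return table, fractions


@dataclass
class PositionalEnrichment:
    """Per-position, per-residue binomial overrepresentation of a foreground
    peptide set against a background residue distribution."""

    table: pd.DataFrame  # columns: position, residue, k, p0, p_value, height, significant
    n_foreground: int
    length: int
    alpha: float
    bonferroni_alpha: float = field(init=False)

    def __post_init__(self):
        self.bonferroni_alpha = self.alpha / (20 * self.length)

    def heights(self) -> pd.DataFrame:
        """Wide position x residue matrix of signed logo heights."""
        return self.table.pivot(index="position", columns="residue",
                                values="height")

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)


def _column_frequencies(peptides: Sequence[str], length: int) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=range(1, length + 1),
                          columns=sorted(CANONICAL_RESIDUES), dtype=float)
    for pep in peptides:
        for i, aa in enumerate(pep):
            counts.at[i + 1, aa] += 1
    return counts


def positional_overrepresentation(foreground: Sequence[str],
                                  background: Sequence[str],
                                  alpha: float = 0.05) -> PositionalEnrichment:
    """Probability-logo statistic for aligned fixed-length peptides.

    For residue ``r`` at position ``j``, let ``k`` be its foreground count,
    ``n`` the foreground size and ``p0`` its background frequency at that
    position. The overrepresentation p-value is ``P(X >= k)`` and the
    underrepresentation p-value ``P(X <= k)`` for ``X ~ Binomial(n, p0)``
    (exact tails, no normal approximation). The logo height is ``-log10 p``
    of the favoured tail, positive for over- and negative for
    underrepresentation, and exactly 0 when ``k/n == p0``. Significance is
    Bonferroni-corrected over ``20 * length`` tests at level ``alpha``.
    """
    foreground = list(foreground)
    background = list(background)
    if not foreground:
        raise ValueError("empty foreground set")
    lengths = {len(p) for p in foreground} | {len(p) for p in background}
    if len(lengths) != 1:
        raise ValueError(f"peptides must share one length, got {sorted(lengths)}")
    L = lengths.pop()
    n = len(foreground)
    fg = _column_frequencies(foreground, L)
    bg = _column_frequencies(background, L)
    p0 = bg.div(bg.sum(axis=1), axis=0)

    records = []
    threshold = alpha / (20 * L)
    tiny = np.finfo(float).tiny
    for pos in range(1, L + 1):
        for aa in fg.columns:
            k = int(fg.at[pos, aa])
            p_bg = float(p0.at[pos, aa])
            if p_bg == 0.0 and k > 0:
                warnings.warn(
                    f"residue {aa} at position {pos} absent from background "
                    f"but present in foreground; p-value clamped", stacklevel=2)
                p_over, direction = tiny, 1.0
            else:
                p_over = float(stats.binom.sf(k - 1, n, p_bg))
                p_under = float(stats.binom.cdf(k, n, p_bg))
                if k / n > p_bg:
                    direction = 1.0
                elif k / n < p_bg:
                    direction = -1.0
                    p_over = p_under
                else:
                    direction = 0.0
                    p_over = 1.0
            p_val = min(max(p_over, tiny), 1.0)
            height = 0.0 if direction == 0.0 else direction * (-math.log10(p_val))
            records.append((pos, aa, k, p_bg, p_val, height,
                            direction != 0.0 and p_val < threshold))
    table = pd.DataFrame(records, columns=["position", "residue", "k", "p0",
                                           "p_value", "height", "significant"])
    return PositionalEnrichment(table, n, L, alpha)


def plot_logo(enrichment: PositionalEnrichment, ax=None, color_significant="crimson",
              color_other="0.6"):
    """Render a stacked-letter probability logo with matplotlib.

    Letters are scaled vertically to their signed heights; positive stacks
    grow upward (overrepresented), negative stacks downward. Bonferroni
    significant letters are coloured.
    """
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * enrichment.length + 1, 4))
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    tab = enrichment.table
    ymax = ymin = 0.0
    for pos, grp in tab.groupby("position"):
        for sign in (1, -1):
            sub = grp[np.sign(grp["height"]) == sign]
            sub = sub.reindex(sub["height"].abs().sort_values().index)
            base = 0.0
            for _, row in sub.iterrows():
                h = abs(row["height"])
                if h <= 0:
                    continue
                tp = TextPath((0, 0), row["residue"], size=1, prop=fp)
                bb = tp.get_extents()
                scale = Affine2D().translate(-bb.x0, -bb.y0).scale(
                    0.9 / bb.width, h / bb.height)
                shift = Affine2D().translate(pos - 0.45,
                                             base if sign > 0 else -(base + h))
                color = color_significant if row["significant"] else color_other
                ax.add_patch(PathPatch(tp.transformed(scale + shift),
                                       facecolor=color, edgecolor="none"))
                base += h
            if sign > 0:
                ymax = max(ymax, base)
            else:
                ymin = min(ymin, -base)
    thr = -math.log10(enrichment.bonferroni_alpha)
    ax.axhline(thr, ls="--", lw=0.8, color="k")
    ax.axhline(-thr, ls="--", lw=0.8, color="k")
    ax.axhline(0, lw=0.8, color="k")
    ax.set_xlim(0.25, enrichment.length + 0.75)
    ax.set_ylim(min(ymin, -thr) * 1.1 - 0.2, max(ymax, thr) * 1.1 + 0.2)
    ax.set_xticks(range(1, enrichment.length + 1))
    ax.set_xlabel("position")
    ax.set_ylabel(r"$-\log_{10} p$ (signed)")
    return ax
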