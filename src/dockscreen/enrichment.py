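"""Enrichment-score estimation for competitive selection screens.

For each library member in each replicate screen, the frequency trajectory
``F_t`` (reads over total reads) is summarised by the slope of
``ln(F_t / F_0)`` regressed on cumulative population doublings — the
enrichment score (ES). Replicate ES are averaged per member, and hits are
defined by the standard score of the replicate-averaged ES within its screen
(Z over all scored members of one genotype x condition).

The module follows a model/results split: build a :class:`ScreenModel` from
a :class:`~dockscreen.tables.CountTable`, call :meth:`ScreenModel.fit`, and
work with the returned :class:`ScreenScores`.

Estimation notes
----------------
* Frequencies get a uniform pseudocount (default 0.5) so logs are finite,
  but a member with a *raw* baseline count of zero in a replicate is
  excluded from that replicate's regression rather than rescued: a slope
  anchored at an imputed baseline measures the imputation, not the member.
* The regression uses ordinary least squares with a free intercept and
  includes the baseline point (0, 0) as data; the intercept absorbs
  baseline sampling error.
* Natural logarithms throughout; doublings are log2 units of population
  growth, so a member growing at the population-average rate has ES 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable

__all__ = ["FrequencyMatrix", "frequencies", "ScreenModel", "ScreenScores",
           "average_replicates", "zscores", "screen_correlation"]


class ScreenError(ValueError):
    pass


@dataclass
class FrequencyMatrix:
    """Per-sample member frequencies after pseudocounting.

    ``F`` columns each sum to 1; ``baseline_zero`` flags (member, sample)
    cells whose screen's raw baseline count was zero (excluded from ES).
    """

    F: pd.DataFrame
    pseudocount: float
    baseline_zero: pd.DataFrame
    source: CountTable

    def __post_init__(self):
        colsums = self.F.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ScreenError("frequency columns must sum to 1")


def frequencies(counts: CountTable, pseudocount: float = 0.5) -> FrequencyMatrix:
    """F_ij = (c_ij + pseudocount) / sum_i (c_ij + pseudocount).

    Raises on an all-zero sample (no reads — frequencies undefined).
    """
    if pseudocount < 0:
        raise ScreenError("pseudocount must be >= 0")
    c = counts.counts.astype(float)
    if (c.sum(axis=0) == 0).any():
        bad = list(c.columns[c.sum(axis=0) == 0])
        raise ScreenError(f"all-zero sample(s) {bad}")
    shifted = c + pseudocount
    totals = shifted.sum(axis=0)
    if (totals == 0).any():
        raise ScreenError("zero total after pseudocounting")
    F = shifted.div(totals, axis=1)
    if (F.to_numpy() <= 0).any() and pseudocount > 0:
        raise ScreenError("nonpositive frequency after pseudocounting")

    baseline_zero = pd.DataFrame(False, index=c.index, columns=c.columns)
    for (_, _, _), grp in counts.screens():
        base_sid = grp.index[grp["doublings"] == 0][0]
        zero = counts.counts[base_sid] == 0
        baseline_zero.loc[zero, grp.index] = True
    return FrequencyMatrix(F, pseudocount, baseline_zero, counts)


def _ols_slopes(D: np.ndarray, Y: np.ndarray):
    """Vectorised per-row OLS of Y (members x timepoints) on D.

    Returns slope, intercept, residual standard error, r-squared. This is
    the closed-form estimator; tests cross-check it against a general OLS
    implementation.
    """
    T = len(D)
    Dc = D - D.mean()
    ssd = float(np.sum(Dc ** 2))
    ybar = Y.mean(axis=1)
    slope = (Y - ybar[:, None]) @ Dc / ssd
    intercept = ybar - slope * D.mean()
    resid = Y - (intercept[:, None] + np.outer(slope, D))
    rss = np.sum(resid ** 2, axis=1)
    tss = np.sum((Y - ybar[:, None]) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stderr = np.sqrt(rss / (T - 2)) if T > 2 else np.full(len(Y), np.nan)
        r2 = np.where(tss > 0, 1.0 - rss / tss, np.nan)
    return slope, intercept, stderr, r2


class ScreenModel:
    """Enrichment-score model for one count table.

    Parameters
    ----------
    counts : CountTable
        Samples from one or more screens; each (genotype, condition,
        replicate) must include its doublings-0 baseline.
    pseudocount : float
        Uniform pseudocount for frequency computation (default 0.5).

    Examples
    --------
    >>> scores = ScreenModel(table).fit()          # doctest: +SKIP
    >>> scores.scores.head()                       # doctest: +SKIP
    >>> scores.hits("WT")                          # doctest: +SKIP
    """

    def __init__(self, counts: CountTable, pseudocount: float = 0.5):
        self.counts = counts
        self.pseudocount = pseudocount
        self.freqs = frequencies(counts, pseudocount)

    def fit(self) -> "ScreenScores":
        rows = []
        F = self.freqs.F
        for (genotype, condition, rep), grp in self.counts.screens():
            D = grp["doublings"].to_numpy(dtype=float)
            if len(D) < 2:
                raise ScreenError(
                    f"screen ({genotype}, {condition}, r{rep}) has fewer than "
                    f"2 timepoints")
            base_sid = grp.index[D == 0][0]
            sub = F[grp.index].to_numpy()
            f0 = F[base_sid].to_numpy()
            Y = np.log(sub / f0[:, None])
            slope, intercept, stderr, r2 = _ols_slopes(D, Y)
            excluded = self.freqs.baseline_zero[base_sid].to_numpy()
            slope = np.where(excluded, np.nan, slope)
            block = pd.DataFrame({
                "genotype": genotype, "condition": condition, "replicate": rep,
                "member_id": F.index, "es": slope,
                "intercept": np.where(excluded, np.nan, intercept),
                "stderr": np.where(excluded, np.nan, stderr),
                "r2": np.where(excluded, np.nan, r2),
                "n_points": np.where(excluded, 0, len(D)),
            })
            rows.append(block)
        per_replicate = pd.concat(rows, ignore_index=True)
        return ScreenScores(per_replicate, model=self)


def average_replicates(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean ES over replicates where defined.

    Input needs columns genotype, condition, replicate, member_id, es.
    Members with no usable replicate keep a missing (NaN) mean and
    ``n_replicates_used`` 0.
    """
    grouped = per_replicate.groupby(["genotype", "condition", "member_id"],
                                    sort=True)["es"]
    out = grouped.agg(mean_es="mean", n_replicates_used="count").reset_index()
    out["n_replicates_used"] = out["n_replicates_used"].astype(int)
    return out


def zscores(values: pd.Series) -> pd.Series:
    """Standard scores over the non-missing entries, sample (n-1) sd."""
    scored = values.dropna()
    if len(scored) < 2:
        raise ScreenError("need at least 2 scored members for Z-scores")
    sd = scored.std(ddof=1)
    if sd == 0:
        raise ScreenError("degenerate screen: zero ES standard deviation")
    return (values - scored.mean()) / sd


def screen_correlation(mean_es_a: pd.Series, mean_es_b: pd.Series) -> tuple:
    """Pearson R between two screens over members scored in both.

    Returns (r, n_shared). Requires at least 3 shared scored members.
    """
    joined = pd.concat([mean_es_a, mean_es_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ScreenError(f"only {len(joined)} shared scored members (need >= 3)")
    r, _ = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(r), len(joined)


@dataclass
class ScreenScores:
    """Fitted enrichment scores.

    Attributes
    ----------
    per_replicate : DataFrame
        One row per (genotype, condition, replicate, member): ES slope,
        intercept, residual standard error, r2, n_points. Per-replicate Z
        is added as column ``z_rep``.
    scores : DataFrame
        One row per (genotype, condition, member): replicate-averaged
        ``mean_es``, ``n_replicates_used`` and the screen-level ``z``.
    """

    per_replicate: pd.DataFrame
    model: ScreenModel | None = None
    scores: pd.DataFrame = field(init=False)

    def __post_init__(self):
        def safe_z(v):
            # a degenerate screen (constant or near-empty ES) gets missing Z
            # rather than aborting the whole fit; the standalone `zscores`
            # operation raises instead
            try:
                return zscores(v)
            except ScreenError:
                import warnings
                warnings.warn("degenerate screen: Z-scores undefined", stacklevel=2)
                return pd.Series(np.nan, index=v.index)

        self.per_replicate = self.per_replicate.copy()
        self.per_replicate["z_rep"] = (
            self.per_replicate.groupby(["genotype", "condition", "replicate"])
            ["es"].transform(safe_z))
        self.scores = average_replicates(self.per_replicate)
        self.scores["z"] = (
            self.scores.groupby(["genotype", "condition"])["mean_es"]
            .transform(safe_z))

    # ------------------------------------------------------------ accessors

    def screen(self, genotype: str, condition: str = "selective") -> pd.DataFrame:
        sel = self.scores[(self.scores["genotype"] == genotype)
                          & (self.scores["condition"] == condition)]
        if sel.empty:
            raise KeyError(f"no screen ({genotype}, {condition})")
        return sel.set_index("member_id")

    def mean_es(self, genotype: str, condition: str = "selective") -> pd.Series:
        return self.screen(genotype, condition)["mean_es"]

    def z(self, genotype: str, condition: str = "selective") -> pd.Series:
        return self.screen(genotype, condition)["z"]

    def genotypes(self) -> list:
        return sorted(self.scores["genotype"].unique())

    def hits(self, genotype: str, condition: str = "selective",
             z_threshold: float = 3.0, strict: bool = True) -> set:
        from .comparison import call_hits
        return call_hits(self.z(genotype, condition), z_threshold, strict)

    def correlation(self, genotype_a: str, genotype_b: str,
                    condition: str = "selective") -> tuple:
        return screen_correlation(self.mean_es(genotype_a, condition),
                                  self.mean_es(genotype_b, condition))

    # ------------------------------------------------------------ reporting

    def summary(self, z_threshold: float = 3.0) -> str:
        lines = ["Enrichment-score screen summary",
                 "=" * 64,
                 f"{'screen':<32}{'scored':>8}{'mean ES':>10}{'sd':>8}"
                 f"{'Z>' + format(z_threshold, 'g'):>6}"]
        for (g, c), grp in self.scores.groupby(["genotype", "condition"]):
            scored = grp["mean_es"].dropna()
            nhits = int((grp["z"] > z_threshold).sum())
            lines.append(f"{g + ' / ' + c:<32}{len(scored):>8}"
                         f"{scored.mean():>10.4f}{scored.std(ddof=1):>8.4f}"
                         f"{nhits:>6}")
        lines.append("=" * 64)
        lines.append(f"pseudocount={self.model.pseudocount if self.model else 'n/a'}; "
                     f"ES = OLS slope of ln(F_t/F_0) vs population doublings; "
                     f"Z over replicate-averaged ES per screen")
        return "\n".join(lines)

    def write_tsv(self, prefix) -> None:
        self.per_replicate.to_csv(f"{prefix}.es_replicates.tsv", sep="\t",
                                  index=False)
        self.scores.to_csv(f"{prefix}.es_scores.tsv", sep="\t", index=False)

    @classmethod
    def read_tsv(cls, prefix) -> "ScreenScores":
        per_rep = pd.read_csv(f"{prefix}.es_replicates.tsv", sep="\t")
        return cls(per_rep.drop(columns=["z_rep"], errors="ignore"))
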