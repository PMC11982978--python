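"""Competitive-inhibition dose-response (IC50) fitting.

Kinase activity in the presence of increasing competitor D-peptide is
normalized between a no-competitor maximum and a no-kinase minimum, then fit
to a four-parameter logistic (4PL) on the log10-concentration axis:

    y(c) = bottom + (top - bottom) / (1 + (c / IC50)^h)

with top, bottom, IC50 and Hill slope h free (a 3PL with bottom fixed at 0
is available). Replicate series are fit independently; the reported IC50 is
the replicate mean with a t-based 95% confidence interval, matching how
triplicate competitive kinase assays are conventionally summarised. Fold
changes between kinase variants are IC50 ratios with a delta-method CI on
the log scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["normalize_rates", "four_param_logistic", "fit_ic50",
           "FitResult", "FoldChange", "fold_change", "DoseResponseModel",
           "DoseResponseResults"]


def normalize_rates(raw, max_control: float, min_control: float) -> np.ndarray:
    """(raw - min) / (max - min); max from no-competitor wells, min from
    no-kinase wells."""
    if max_control <= min_control:
        raise ValueError("max_control must exceed min_control")
    return (np.asarray(raw, dtype=float) - min_control) / (max_control - min_control)


def four_param_logistic(conc, bottom, top, log10_ic50, hill):
    """4PL response at concentrations ``conc`` (same units as IC50)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** (hill * (np.log10(conc) - log10_ic50)))


@dataclass
class FitResult:
    """Replicate-summarised IC50 fit.

    ``ic50`` is the mean of per-replicate IC50s; ``ci_low``/``ci_high`` the
    95% CI from the t distribution across replicates (equal to the point
    estimate when only one replicate is available). ``flagged`` marks fits
    that did not converge, showed no inhibition, or placed the IC50 outside
    the tested concentration range — reported, never silently dropped.
    """

    ic50: float
    ci_low: float
    ci_high: float
    hill: float
    top: float
    bottom: float
    n_replicates: int
    replicate_ic50s: tuple = ()
    flagged: bool = False
    message: str = ""

    def __post_init__(self):
        if not self.flagged:
            if self.ic50 <= 0:
                raise ValueError("IC50 must be positive")
            if not (self.ci_low <= self.ic50 <= self.ci_high):
                raise ValueError("CI must bracket the IC50")
            if self.bottom > self.top:
                raise ValueError("bottom must not exceed top")

    @property
    def se(self) -> float:
        """Standard error of the mean IC50 implied by the 95% CI."""
        if self.n_replicates < 2:
            return 0.0
        tcrit = stats.t.ppf(0.975, self.n_replicates - 1)
        return (self.ci_high - self.ci_low) / (2.0 * tcrit)

    @classmethod
    def from_summary(cls, ic50: float, ci_low: float, ci_high: float,
                     n_replicates: int = 3) -> "FitResult":
        """Build from printed summary numbers (e.g. a published IC50 table)
        for downstream fold-change arithmetic."""
        return cls(ic50=ic50, ci_low=ci_low, ci_high=ci_high, hill=math.nan,
                   top=math.nan, bottom=math.nan, n_replicates=n_replicates)


def _fit_single(conc: np.ndarray, resp: np.ndarray, fix_bottom: float | None):
    """One 4PL least-squares fit. Returns (params dict, flagged, message)."""
    pos = conc > 0
    c, y = conc[pos], resp[pos]
    if len(np.unique(c)) < 4:
        return None, True, "fewer than 4 distinct positive concentrations"
    order = np.argsort(c)
    c, y = c[order], y[order]
    top0 = float(np.mean(y[c <= np.quantile(c, 0.25)]))
    bot0 = float(np.mean(y[c >= np.quantile(c, 0.75)])) if fix_bottom is None else fix_bottom
    # initial IC50: first crossing of the half response, else geometric centre
    half = (top0 + bot0) / 2.0
    below = np.nonzero(y <= half)[0]
    ic0 = c[below[0]] if len(below) else math.sqrt(c[0] * c[-1])

    if fix_bottom is None:
        def f(cc, bottom, top, log_ic50, hill):
            return four_param_logistic(cc, bottom, top, log_ic50, hill)
        p0 = [bot0, top0, math.log10(ic0), 1.0]
    else:
        def f(cc, top, log_ic50, hill):
            return four_param_logistic(cc, fix_bottom, top, log_ic50, hill)
        p0 = [top0, math.log10(ic0), 1.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(f, c, y, p0=p0, maxfev=20_000)
    except RuntimeError as exc:
        return None, True, f"no convergence: {exc}"
    if fix_bottom is None:
        bottom, top, log_ic50, hill = popt
    else:
        (top, log_ic50, hill), bottom = popt, fix_bottom
    ic50 = 10.0 ** log_ic50
    params = {"ic50": float(ic50), "hill": float(hill),
              "top": float(top), "bottom": float(bottom)}
    if hill <= 0 or top - bottom <= 1e-3:
        return params, True, "no inhibition detected (non-decreasing response)"
    if not (c.min() <= ic50 <= c.max()):
        return params, True, "IC50 outside the tested concentration range"
    return params, False, ""


def fit_ic50(concentrations, responses, fix_bottom: float | None = None
             ) -> FitResult:
    """Fit replicate dose-response series and summarise the IC50.

    Parameters
    ----------
    concentrations : 1-D array of concentrations (uM); zero-concentration
        points are used only upstream for normalization and are excluded
        from the logistic fit.
    responses : 1-D array (single series) or 2-D array / list of 1-D arrays,
        one row per replicate, of normalized rates.
    fix_bottom : fix the lower plateau (e.g. 0.0 for a 3PL); default free.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.atleast_2d(np.asarray(responses, dtype=float))
    if resp.shape[1] != len(conc):
        raise ValueError("responses do not align with concentrations")
    if (conc < 0).any():
        raise ValueError("negative concentrations")

    fits, problems = [], []
    for row in resp:
        params, flagged, msg = _fit_single(conc, row, fix_bottom)
        if flagged:
            problems.append(msg)
        if params is not None:
            fits.append((params, flagged))
    if not fits or all(flag for _, flag in fits):
        params = fits[0][0] if fits else {"ic50": math.nan, "hill": math.nan,
                                          "top": math.nan, "bottom": math.nan}
        return FitResult(ic50=params["ic50"], ci_low=math.nan, ci_high=math.nan,
                         hill=params["hill"], top=params["top"],
                         bottom=params["bottom"], n_replicates=resp.shape[0],
                         replicate_ic50s=tuple(p["ic50"] for p, _ in fits),
                         flagged=True, message="; ".join(problems))

    good = [p for p, flag in fits if not flag]
    ic50s = np.array([p["ic50"] for p in good])
    mean = float(ic50s.mean())
    if len(ic50s) >= 2:
        sem = float(ic50s.std(ddof=1) / math.sqrt(len(ic50s)))
        tcrit = stats.t.ppf(0.975, len(ic50s) - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    else:
        lo = hi = mean
    return FitResult(
        ic50=mean, ci_low=lo, ci_high=hi,
        hill=float(np.mean([p["hill"] for p in good])),
        top=float(np.mean([p["top"] for p in good])),
        bottom=float(np.mean([p["bottom"] for p in good])),
        n_replicates=len(good), replicate_ic50s=tuple(ic50s),
        flagged=bool(problems),
        message="; ".join(problems))


@dataclass
class FoldChange:
    """IC50 ratio B/A with a delta-method CI propagated on the log scale."""

    ratio: float
    ci_low: float
    ci_high: float
    flagged: bool = False
    message: str = ""


def fold_change(fit_a: FitResult, fit_b: FitResult) -> FoldChange:
    """Ratio ``IC50_B / IC50_A`` (conventionally mutant over reference).

    The CI comes from the delta method on ``log(ratio)``:
    ``se_log ~= sqrt((se_A/IC50_A)^2 + (se_B/IC50_B)^2)``.
    """
    if fit_a.flagged or fit_b.flagged:
        return FoldChange(ratio=math.nan, ci_low=math.nan, ci_high=math.nan,
                          flagged=True,
                          message="flagged input fit(s): "
                                  f"{fit_a.message or 'ok'} / {fit_b.message or 'ok'}")
    ratio = fit_b.ic50 / fit_a.ic50
    se_log = math.sqrt((fit_a.se / fit_a.ic50) ** 2
                       + (fit_b.se / fit_b.ic50) ** 2)
    return FoldChange(ratio=ratio,
                      ci_low=ratio * math.exp(-1.96 * se_log),
                      ci_high=ratio * math.exp(1.96 * se_log))


class DoseResponseModel:
    """Model object over a tidy dose-response table.

    ``data`` needs columns ``peptide_id, kinase, replicate,
    concentration_uM, rate``; rates are assumed already normalized to [0, 1]
    unless per-(peptide, kinase, replicate) ``max_control``/``min_control``
    columns are present, in which case :func:`normalize_rates` is applied.
    """

    REQUIRED = ["peptide_id", "kinase", "replicate", "concentration_uM", "rate"]

    def __init__(self, data: pd.DataFrame, fix_bottom: float | None = None):
        missing = set(self.REQUIRED) - set(data.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        data = data.copy()
        if {"max_control", "min_control"} <= set(data.columns):
            data["rate"] = [
                normalize_rates(r.rate, r.max_control, r.min_control)
                for r in data.itertuples()]
        self.data = data
        self.fix_bottom = fix_bottom

    def fit(self) -> "DoseResponseResults":
        rows = {}
        for (pep, kin), grp in self.data.groupby(["peptide_id", "kinase"],
                                                 sort=True):
            reps = []
            conc = None
            for _, rep_grp in grp.groupby("replicate", sort=True):
                rep_grp = rep_grp.sort_values("concentration_uM")
                c = rep_grp["concentration_uM"].to_numpy()
                if conc is None:
                    conc = c
                elif not np.array_equal(conc, c):
                    raise ValueError(
                        f"({pep}, {kin}): replicates use different "
                        f"concentration grids")
                reps.append(rep_grp["rate"].to_numpy())
            rows[(pep, kin)] = fit_ic50(conc, np.vstack(reps),
                                        fix_bottom=self.fix_bottom)
        return DoseResponseResults(rows, model=self)


@dataclass
class DoseResponseResults:
    """Per-(peptide, kinase) :class:`FitResult` with tabular access."""

    fits: dict
    model: DoseResponseModel | None = None

    @property
    def table(self) -> pd.DataFrame:
        recs = [
            {"peptide_id": pep, "kinase": kin, "ic50_uM": f.ic50,
             "ci_low": f.ci_low, "ci_high": f.ci_high, "hill": f.hill,
             "top": f.top, "bottom": f.bottom, "n_replicates": f.n_replicates,
             "flagged": f.flagged, "message": f.message}
            for (pep, kin), f in self.fits.items()]
        return pd.DataFrame(recs)

    def fold_changes(self, reference_kinase: str) -> pd.DataFrame:
        """Mutant/reference IC50 ratio per peptide and non-reference kinase."""
        recs = []
        for (pep, kin), fit in self.fits.items():
            if kin == reference_kinase:
                continue
            ref = self.fits.get((pep, reference_kinase))
            if ref is None:
                continue
            fc = fold_change(ref, fit)
            recs.append({"peptide_id": pep, "kinase": kin, "fold": fc.ratio,
                         "ci_low": fc.ci_low, "ci_high": fc.ci_high,
                         "flagged": fc.flagged})
        return pd.DataFrame(recs)

    def summary(self) -> str:
        lines = ["Dose-response IC50 fits", "=" * 72,
                 f"{'peptide':<16}{'kinase':<10}{'IC50 (uM)':>12}"
                 f"{'95% CI':>20}{'Hill':>7}  flag"]
        for (pep, kin), f in self.fits.items():
            ci = f"[{f.ci_low:.3g}, {f.ci_high:.3g}]"
            lines.append(f"{pep:<16}{kin:<10}{f.ic50:>12.4g}{ci:>20}"
                         f"{f.hill:>7.2f}  {'!' if f.flagged else ''}")
        lines.append("=" * 72)
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
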