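"""Diagnostics quantifying copy-number-driven bias in differential results.

When counts are not corrected for copy number, the per-peak log2 fold
change tracks the local log2 copy-number ratio: a LOESS trend of log2FC
against log2CNR has slope near 1, peaks in gained regions are skewed
towards "up" calls, and region-level status proportions deviate from the
genome-wide ones.  After correction the trend flattens.  This module
computes those summaries as plain tables (MA data, the fitted bias trend,
per-CNR-bin status proportions, and a chi-square enrichment test of a
region's status composition against a reference set).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .diff import STATUS_DOWN, STATUS_ND, STATUS_UP
from .normalize import PeakAssignment
from .core import ValidationError

MIN_TREND_PEAKS = 30
DEFAULT_SPAN = 0.3
STATUSES = (STATUS_UP, STATUS_DOWN, STATUS_ND)


@dataclass
class BiasTrend:
    """LOESS summary of log2FC versus log2CNR."""

    grid: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    slope: float
    intercept: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "log2cnr": self.grid,
                "fitted": self.fitted,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass
class StatusTable:
    """Status counts/proportions for a region set vs a reference set."""

    subset_counts: Dict[str, int]
    reference_counts: Optional[Dict[str, int]]
    proportions: Dict[str, float]
    chi2: Optional[float] = None
    df: Optional[int] = None
    p: Optional[float] = None
    warning: Optional[str] = None


def _join_fc_cnr(
    results: pd.DataFrame, assignments: Sequence[PeakAssignment]
) -> Tuple[np.ndarray, np.ndarray]:
    cnr_by_name = {a.peak_name: a.log2cnr for a in assignments}
    x, y = [], []
    for peak, fc in zip(results["peak"], results["log2fc"]):
        if peak in cnr_by_name and np.isfinite(fc):
            x.append(cnr_by_name[peak])
            y.append(fc)
    return np.asarray(x), np.asarray(y)


def bias_trend(
    results: pd.DataFrame,
    assignments: Sequence[PeakAssignment],
    span: float = DEFAULT_SPAN,
    n_grid: int = 50,
) -> BiasTrend:
    """LOESS (tricube, locally linear) fit of log2FC on log2CNR.

    The slope comes from ordinary least squares on the same points; the 95%
    band is a local-residual normal approximation (sd of residuals in the
    span window around each grid point, scaled by sqrt(n_local)).
    Requires >= 30 peaks with finite log2FC and an assigned log2CNR.
    """
    x, y = _join_fc_cnr(results, assignments)
    n = len(x)
    if n < MIN_TREND_PEAKS:
        raise ValidationError(
            f"bias_trend needs >= {MIN_TREND_PEAKS} usable peaks, got {n}"
        )
    if np.ptp(x) == 0:
        # degenerate: a single CNR value; flat trend at the mean
        grid = np.full(n_grid, x[0])
        fitted = np.full(n_grid, y.mean())
        half = 1.96 * y.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        return BiasTrend(grid, fitted, fitted - half, fitted + half, 0.0, float(y.mean()), n)

    grid = np.linspace(x.min(), x.max(), n_grid)
    # peaks sharing a segment give heavily tied x; the lowess internals then
    # hit 0/0 weight normalizations that resolve correctly but warn
    with np.errstate(invalid="ignore", divide="ignore"):
        fitted = lowess(y, x, frac=span, xvals=grid)
        fit_at_x = lowess(y, x, frac=span, xvals=x)
    if np.any(~np.isfinite(fitted)):
        # fall back to nearest finite grid neighbour (extreme tie pathologies)
        ok = np.isfinite(fitted)
        fitted = np.interp(grid, grid[ok], fitted[ok])
    fit_at_x = np.where(np.isfinite(fit_at_x), fit_at_x, np.interp(x, grid, fitted))
    resid = y - fit_at_x

    k = max(int(np.ceil(span * n)), 2)
    ci_low = np.empty(n_grid)
    ci_high = np.empty(n_grid)
    order = np.argsort(x)
    xs, rs = x[order], resid[order]
    for i, g in enumerate(grid):
        nearest = np.argsort(np.abs(xs - g))[:k]
        sd = rs[nearest].std(ddof=1)
        half = 1.96 * sd / np.sqrt(k)
        ci_low[i] = fitted[i] - half
        ci_high[i] = fitted[i] + half

    slope, intercept = np.polyfit(x, y, 1)
    return BiasTrend(grid, fitted, ci_low, ci_high, float(slope), float(intercept), n)


def status_proportions(
    results: pd.DataFrame, subset: Optional[Sequence[str]] = None
) -> StatusTable:
    """Counts and percentages of up/down/nd, optionally within a peak subset.

    Percentages are rounded to two decimals in the returned table.
    """
    if len(results) == 0:
        raise ValidationError("results are empty")
    sub = results
    if subset is not None:
        names = set(subset)
        sub = results[results["peak"].isin(names)]
        if len(sub) == 0:
            raise ValidationError("subset matches no peaks")
    counts = {s: int((sub["status"] == s).sum()) for s in STATUSES}
    total = sum(counts.values())
    props = {s: round(100.0 * counts[s] / total, 2) for s in STATUSES}
    return StatusTable(subset_counts=counts, reference_counts=None, proportions=props)


def pearson_chi2(table: np.ndarray) -> Tuple[float, int]:
    """Pearson chi-square on a contingency table, df = (r-1)(c-1).

    Cells in columns with zero marginal expectation contribute nothing
    (their observed totals are zero too, by construction of the marginals).
    """
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total <= 0:
        raise ValidationError("contingency table is all zeros")
    expected = row * col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return float(terms.sum()), df


def enrichment_chisq(
    subset_counts: Tuple[int, int, int],
    reference_counts: Tuple[int, int, int],
) -> StatusTable:
    """Chi-square homogeneity test of a region's (up, down, nd) composition.

    When the subset is contained in the reference (elementwise <= with a
    strictly smaller total), the comparison rows are subset vs reference
    minus subset; otherwise the two sets are compared as given.  df = 2 for
    the three-status table.  A warning is attached when any expected cell
    falls below 1.
    """
    sub = np.asarray(subset_counts, dtype=float)
    ref = np.asarray(reference_counts, dtype=float)
    if np.any(ref <= 0):
        raise ValidationError("all reference counts must be > 0")
    if np.all(sub <= ref) and sub.sum() < ref.sum():
        other = ref - sub
    else:
        other = ref
    table = np.vstack([sub, other])
    chi2, df = pearson_chi2(table)
    p = float(stats.chi2.sf(chi2, df))
    expected = table.sum(axis=1, keepdims=True) * table.sum(axis=0, keepdims=True) / table.sum()
    warning = None
    if np.any(expected < 1):
        warning = "expected cell count < 1; chi-square approximation unreliable"
    counts_sub = dict(zip(STATUSES, (int(v) for v in sub)))
    counts_ref = dict(zip(STATUSES, (int(v) for v in ref)))
    total = sub.sum()
    props = {s: round(100.0 * counts_sub[s] / total, 2) for s in STATUSES}
    return StatusTable(
        subset_counts=counts_sub,
        reference_counts=counts_ref,
        proportions=props,
        chi2=chi2,
        df=df,
        p=p,
        warning=warning,
    )


def ma_data(results: pd.DataFrame, alpha_sig: float = 0.05) -> pd.DataFrame:
    """Per-peak (mean, log2FC, padj) table for MA plotting.

    ``log10_mean`` is provided as axis metadata; significance mirrors the
    result status.
    """
    out = results[["peak", "base_mean", "log2fc", "padj"]].copy()
    with np.errstate(divide="ignore"):
        out["log10_mean"] = np.log10(out["base_mean"].to_numpy())
    out["significant"] = results["status"].isin([STATUS_UP, STATUS_DOWN]).to_numpy()
    return out


def cnr_binned_status(
    results: pd.DataFrame,
    assignments: Sequence[PeakAssignment],
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Status proportions per log2CNR bin.

    ``bin_edges`` must be strictly increasing; peaks outside the outer edges
    are dropped.  Empty bins are reported with n = 0 and NaN proportions.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges must be strictly increasing with >= 2 edges")
    cnr_by_name = {a.peak_name: a.log2cnr for a in assignments}
    x = results["peak"].map(cnr_by_name)
    rows = []
    which = np.digitize(x.to_numpy(dtype=float), edges) - 1
    for b in range(len(edges) - 1):
        in_bin = results[(which == b) & x.notna().to_numpy()]
        n = len(in_bin)
        row = {"bin_low": edges[b], "bin_high": edges[b + 1], "n": n}
        for s in STATUSES:
            row[f"prop_{s}"] = float((in_bin["status"] == s).mean()) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
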