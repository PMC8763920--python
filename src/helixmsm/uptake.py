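"""Quantification statistics for confocal cellular-uptake experiments.

Consumes per-cell mean-intensity tables produced upstream by image
segmentation and reproduces the downstream analysis: Freedman-Diaconis
histogram binning, lognormal maximum-likelihood fits of the intensity
distribution, iterative two-sided Grubbs outlier removal (on the log scale
by default, consistent with the lognormal model), Welch two-sample t-tests
against a reference treatment, and fold-change normalization where the
reference group's mean is defined as 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellIntensityTable",
    "FoldChangeSummary",
    "fd_bin_width",
    "fit_lognormal",
    "grubbs_remove",
    "welch_t",
    "normalize_fold",
]


@dataclass
class CellIntensityTable:
    """Tidy per-cell table with columns cell, intensity, area, group."""

    data: pd.DataFrame

    REQUIRED = ("cell", "intensity", "group")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"table lacks required columns: {missing}")
        inten = self.data["intensity"].to_numpy(dtype=float)
        if not np.isfinite(inten).all():
            raise ValueError("intensities must be finite")
        if (inten < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.data["group"].nunique() < 1:
            raise ValueError("need at least one treatment group")

    def group_values(self, group: str) -> np.ndarray:
        vals = self.data.loc[self.data["group"] == group, "intensity"]
        return vals.to_numpy(dtype=float)


@dataclass
class FoldChangeSummary:
    reference: str
    table: pd.DataFrame  # group, n, mean, fold, fold_sem, t, df, p


def fd_bin_width(values: Sequence[float]) -> Tuple[float, bool]:
    """Freedman-Diaconis histogram bin width 2 * IQR * n^(-1/3).

    Returns (width, degenerate): constant data has zero IQR, for which the
    width is returned as 0 with the degenerate flag set (callers fall back
    to a single bin)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    q75, q25 = np.percentile(x, [75, 25])  # linear-interpolation quantiles
    iqr = q75 - q25
    width = 2.0 * iqr * x.size ** (-1.0 / 3.0)
    return width, width == 0.0


def fit_lognormal(values: Sequence[float]) -> Tuple[float, float]:
    """Maximum-likelihood lognormal fit: (mu, sigma) are the mean and
    population standard deviation of ln(values)."""
    x = np.asarray(values, dtype=float)
    bad = np.flatnonzero(x <= 0)
    if bad.size:
        raise ValueError(
            f"lognormal fit requires positive values; offending rows: "
            f"{bad[:10].tolist()}"
        )
    logs = np.log(x)
    return float(logs.mean()), float(logs.std(ddof=0))


def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value at level alpha for sample size n."""
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    if not np.isfinite(t2):
        # alpha -> 0 limit: the statistic is bounded by (n-1)/sqrt(n)
        return (n - 1) / np.sqrt(n)
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_remove(
    values: Sequence[float],
    alpha: float = 0.05,
    log_scale: bool = True,
    max_iter: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs outlier removal.

    At each step the most extreme point (largest studentized deviation
    G = max |x - xbar| / s, with sample sd) is tested against the Grubbs
    critical value and removed if significant; iteration stops at the first
    non-rejection, after ``max_iter`` removals, or when fewer than 3 points
    remain.  When ``log_scale`` is set the test statistics are computed on
    ln(values), matching a lognormal intensity model; the returned arrays are
    always on the original scale.

    Returns (kept, removed) in the original input order.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    if log_scale and (x <= 0).any():
        raise ValueError("log-scale Grubbs requires positive values")
    keep = np.ones(x.size, dtype=bool)
    removed_order = []
    iters = 0
    while keep.sum() >= 3:
        if max_iter is not None and iters >= max_iter:
            break
        sub = np.log(x[keep]) if log_scale else x[keep]
        s = sub.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(sub - sub.mean())
        i_local = int(np.argmax(dev))
        G = dev[i_local] / s
        if G <= _grubbs_critical(int(keep.sum()), alpha):
            break
        i_global = np.flatnonzero(keep)[i_local]
        keep[i_global] = False
        removed_order.append(i_global)
        iters += 1
    return x[keep], x[sorted(removed_order)]


def welch_t(a: Sequence[float], b: Sequence[float]
            ) -> Tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns (t, df, p) with the Welch-Satterthwaite degrees of freedom and a
    two-sided p-value.  Two zero-variance samples with equal means give
    t = 0, p = 1 by convention.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    if se2 == 0:
        if x.mean() == y.mean():
            return 0.0, float(nx + ny - 2), 1.0
        return np.inf, float(nx + ny - 2), 0.0
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def normalize_fold(
    table: CellIntensityTable,
    reference_group: str,
) -> FoldChangeSummary:
    """Per-group mean intensities as fold of the reference group's mean
    (reference fold = 1 by construction), with the group's own SEM
    propagated through the division, and a Welch t-test of each group
    against the reference."""
    groups = list(dict.fromkeys(table.data["group"]))
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in table")
    ref = table.group_values(reference_group)
    ref_mean = ref.mean()
    if ref_mean == 0:
        raise ValueError("reference group has zero mean intensity")
    rows = []
    for g in sorted(groups, key=lambda g: (g != reference_group, g)):
        vals = table.group_values(g)
        n = vals.size
        sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        if g == reference_group:
            t, df, p = np.nan, np.nan, np.nan
        else:
            t, df, p = welch_t(vals, ref)
        rows.append({
            "group": g,
            "n": n,
            "mean": vals.mean(),
            "fold": vals.mean() / ref_mean,
            "fold_sem": sem / ref_mean,
            "t": t,
            "df": df,
            "p": p,
        })
    return FoldChangeSummary(reference=reference_group,
                             table=pd.DataFrame(rows))
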