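"""Model II major-axis (MA) regression.

MA regression fits the line minimising summed squared perpendicular
distances, appropriate when both variables are random and share a
dimensionless scale (here per-window synchrony phi and variability CV).
The fitted axis is the leading eigenvector of the 2x2 sample covariance
matrix; the line passes through the centroid. Significance is the
standard two-sided Pearson correlation t-test, t = r*sqrt(df/(1-r^2))
with df = n - 2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MAFit", "ma_regression", "ma_regression_from_metrics"]


@dataclass
class MAFit:
    slope: float
    intercept: float
    r: float
    df: int
    p: float
    r2: float
    n: int
    n_excluded: int = 0  # undefined windows dropped pairwise


def ma_regression(x, y, n_excluded: int = 0) -> MAFit:
    """Major-axis fit of y on x.

    NaN pairs are deleted pairwise and counted. Degenerate inputs (fewer
    than 3 finite pairs, zero variance on both axes, or a circular cloud
    with no major axis) raise ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    ok = np.isfinite(x) & np.isfinite(y)
    n_excluded += int((~ok).sum())
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 defined points, have {n}")
    sxx = x.var(ddof=1)
    syy = y.var(ddof=1)
    if sxx == 0.0 and syy == 0.0:
        raise ValueError("zero variance on both axes")
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxy == 0.0:
        if sxx == syy:
            raise ValueError("major axis undefined: circular point cloud")
        slope = 0.0 if sxx > syy else math.inf
    else:
        slope = (syy - sxx + math.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)
    intercept = (
        float(y.mean() - slope * x.mean()) if math.isfinite(slope) else math.nan
    )
    if sxx == 0.0 or syy == 0.0:
        r = 0.0
    else:
        r = float(np.clip(sxy / math.sqrt(sxx * syy), -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return MAFit(
        slope=float(slope),
        intercept=intercept,
        r=r,
        df=df,
        p=p,
        r2=r * r,
        n=n,
        n_excluded=n_excluded,
    )


def ma_regression_from_metrics(metrics: pd.DataFrame) -> MAFit:
    """MA fit of CV on phi from a windowed metric table
    (columns window_start, window_end, phi, cv, defined)."""
    return ma_regression(
        metrics["phi"].where(metrics["defined"]),
        metrics["cv"].where(metrics["defined"]),
    )
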