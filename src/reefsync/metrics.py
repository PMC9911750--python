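"""Community synchrony (phi) and community variability (CV).

phi is the Loreau & de Mazancourt community-wide synchrony statistic,

    phi = Var(x_T) / (sum_i sd(x_i))^2,

where x_i is the cover time series of element i and x_T = sum_i x_i the
total. phi is 1 when all elements rise and fall together and 0 when
fluctuations are perfectly compensatory. CV = sd(x_T) / mean(x_T) is the
temporal coefficient of variation of total cover, an inverse proxy for
community stability. Both use the sample (n-1) variance convention; the
convention cancels in phi but not in CV.

Elements default to taxon-by-habitat series ("across habitats"): each
taxon's trajectory in each habitat is a separate element. A pooled mode
(taxon summed over habitats) is available. Metrics are evaluated in
sliding windows of consecutive surveys (default 2, so 14 annual surveys
yield 13 windows); for a 2-point window phi reduces to the closed form
(sum_i d_i)^2 / (sum_i |d_i|)^2 with d_i the between-year change.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SeriesMatrix",
    "MetricSeries",
    "aggregate_cover",
    "synchrony_phi",
    "community_cv",
    "pairwise_synchrony",
    "windowed_metrics",
]

ElementMode = Literal["habitat_taxon", "pooled"]


@dataclass
class SeriesMatrix:
    """Element x time matrix of mean percent cover."""

    elements: list[str]
    times: list[int]
    values: np.ndarray  # shape (n_elements, n_times)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.elements), len(self.times)):
            raise ValueError("values shape does not match element/time labels")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")

    @property
    def total(self) -> np.ndarray:
        """x_T: total cover series."""
        return self.values.sum(axis=0)


@dataclass
class MetricSeries:
    """Per-window phi and CV (the synchrony/variability trajectory)."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: window_start, window_end, phi, cv, defined

    def defined(self) -> pd.DataFrame:
        return self.frame[self.frame["defined"]]


def aggregate_cover(table: pd.DataFrame) -> pd.DataFrame:
    """Mean cover (+- SE, n) per habitat x year x taxon.

    Absent (unit, taxon) pairs count as zero cover, so the taxon grid is
    completed over all taxa seen anywhere in the table before averaging.
    Units named ``"<group>/<quadrat>"`` (bommie nesting) are averaged
    within group first, and SE is computed over the n groups; flat units
    use the n quadrats directly.
    """
    if table.empty:
        raise ValueError("cover table is empty")
    taxa = sorted(table["taxon"].unique())
    out_rows = []
    for (habitat, year), sub in table.groupby(["habitat", "year"], sort=True):
        # zero-fill the unit x taxon grid
        wide = (
            sub.pivot_table(index="unit", columns="taxon", values="cover", fill_value=0.0)
            .reindex(columns=taxa, fill_value=0.0)
        )
        units = wide.index.to_series()
        groups = units.str.split("/", n=1).str[0]
        nested = units.str.contains("/").all() and groups.nunique() > 1
        if nested:
            unit_means = wide.groupby(groups).mean()
        else:
            unit_means = wide
        n = len(unit_means)
        means = unit_means.mean(axis=0)
        sds = unit_means.std(axis=0, ddof=1) if n > 1 else pd.Series(0.0, index=taxa)
        ses = sds / math.sqrt(n)
        for taxon in taxa:
            out_rows.append(
                (habitat, int(year), taxon, means[taxon], ses[taxon], n)
            )
    return pd.DataFrame(
        out_rows, columns=["habitat", "year", "taxon", "mean_cover", "se", "n"]
    )


def synchrony_phi(m: SeriesMatrix) -> float:
    """Community synchrony in [0, 1]; NaN when every series is constant."""
    if len(m.times) < 2:
        raise ValueError("phi needs at least two time points")
    sd_sum = m.values.std(axis=1, ddof=1).sum()
    if sd_sum == 0.0:
        return float("nan")
    var_total = m.total.var(ddof=1)
    # Cauchy-Schwarz bounds the ratio by 1; guard rounding at the boundary
    return float(min(max(var_total / sd_sum**2, 0.0), 1.0))


def community_cv(m: SeriesMatrix) -> float:
    """Temporal CV of total cover; NaN when mean total cover is zero."""
    if len(m.times) < 2:
        raise ValueError("CV needs at least two time points")
    total = m.total
    u = total.mean()
    if u == 0.0:
        return float("nan")
    return float(total.std(ddof=1) / u)


def pairwise_synchrony(a: Sequence[float], b: Sequence[float]) -> float:
    """phi for the two-element community {a, b} (e.g. two habitats' DTR)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be equal-length 1-d arrays")
    m = SeriesMatrix(["a", "b"], list(range(len(a))), np.vstack([a, b]))
    return synchrony_phi(m)


def build_series_matrix(
    agg: pd.DataFrame, years: Sequence[int], mode: ElementMode = "habitat_taxon"
) -> SeriesMatrix:
    """Assemble the element x time matrix from aggregated mean cover.

    Raises ``KeyError`` if any habitat surveyed elsewhere is missing a
    year in ``years`` (callers treat that window as undefined).
    """
    years = list(years)
    wide = agg.pivot_table(
        index=["habitat", "taxon"], columns="year", values="mean_cover"
    )
    missing = [y for y in years if y not in wide.columns]
    if missing or wide[years].isna().any().any():
        raise KeyError(f"missing habitat-year cells for years {missing or years}")
    wide = wide[years]
    if mode == "pooled":
        wide = wide.groupby(level="taxon").sum()
        elements = [str(t) for t in wide.index]
    elif mode == "habitat_taxon":
        elements = [f"{h}:{t}" for h, t in wide.index]
    else:
        raise ValueError(f"unknown element mode {mode!r}")
    return SeriesMatrix(elements, years, wide.to_numpy())


def windowed_metrics(
    agg: pd.DataFrame,
    mode: ElementMode = "habitat_taxon",
    window: int = 2,
) -> MetricSeries:
    """phi and CV in sliding windows of ``window`` consecutive surveys.

    Windows containing missing habitat-year cells, or on which a statistic
    is undefined (all-constant series for phi, zero mean total for CV),
    are flagged ``defined=False`` rather than dropped; downstream stages
    decide exclusion.
    """
    if window < 2:
        raise ValueError("window must span at least 2 surveys")
    years = sorted(agg["year"].unique())
    if len(years) < window:
        raise ValueError(f"need at least {window} surveys, have {len(years)}")
    rows = []
    for i in range(len(years) - window + 1):
        wyears = years[i : i + window]
        try:
            m = build_series_matrix(agg, wyears, mode=mode)
            phi = synchrony_phi(m)
            cv = community_cv(m)
        except KeyError:
            phi = cv = float("nan")
        rows.append(
            {
                "window_start": wyears[0],
                "window_end": wyears[-1],
                "phi": phi,
                "cv": cv,
                "defined": not (math.isnan(phi) or math.isnan(cv)),
            }
        )
    return MetricSeries(pd.DataFrame(rows))
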