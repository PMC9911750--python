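"""Physical environment covariates from logger series.

Temperature loggers (nominal 20-minute cadence) are reduced to daily
mean, maximum, minimum and diurnal temperature range (DTR = Tmax - Tmin),
with a per-day coverage fraction against the expected record count; days
below the coverage threshold are flagged rather than silently kept. Gaps
in a primary logger can be filled from a nearby donor logger at the same
depth, but only after a concordance check on their overlap. Wave records
(significant wave height H_sig, dominant period T_w) are converted to
energy flux

    P = rho * g^2 * H_sig^2 * T_w / (64 * pi)        [W/m, reported kW/m]

with rho = 1028 kg/m^3 and g = 9.8 m/s^2, and aggregated over a spawning
season window (default 1 September - 31 January, labelled by start year)
as either a sum or a mean.

Days are calendar days in local standard time; French Polynesia has no
daylight saving, so no DST logic is applied.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SEAWATER_DENSITY",
    "GRAVITY",
    "GapFillError",
    "daily_stats",
    "gap_fill",
    "season_label",
    "seasonal_dtr",
    "wave_energy_flux",
    "seasonal_flux",
    "qc_temperature",
]

SEAWATER_DENSITY = 1028.0  # kg m^-3, mean seawater
GRAVITY = 9.8  # m s^-2

DEFAULT_SEASON = ((9, 1), (1, 31))  # spawning + pelagic larval window


class GapFillError(RuntimeError):
    """Raised when the donor logger disagrees too much with the primary."""

    def __init__(self, message: str, report: "ConcordanceReport"):
        super().__init__(message)
        self.report = report


@dataclass
class ConcordanceReport:
    n_overlap: int
    mean_diff_c: float  # mean(primary - donor) on the overlap
    sd_diff_c: float  # sd(primary) - sd(donor) on the overlap
    n_filled: int
    n_unfilled: int


def qc_temperature(
    series: pd.DataFrame, bounds: tuple[float, float] = (20.0, 35.0)
) -> tuple[pd.DataFrame, int]:
    """Drop readings outside plausible bounds; returns (clean, n_dropped)."""
    ok = series["temp_c"].between(*bounds)
    return series[ok].reset_index(drop=True), int((~ok).sum())


def daily_stats(
    series: pd.DataFrame,
    cadence_min: int = 20,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Daily mean / Tmax / Tmin / DTR with coverage flags.

    ``coverage`` is records observed over records expected at the nominal
    cadence; days under ``min_coverage`` get ``complete=False``. Days with
    no records at all are omitted.
    """
    if series.empty:
        raise ValueError("temperature series is empty")
    expected = 24 * 60 / cadence_min
    t = series.assign(date=pd.to_datetime(series["timestamp"]).dt.normalize())
    g = t.groupby("date")["temp_c"]
    out = pd.DataFrame(
        {
            "mean_c": g.mean(),
            "tmax_c": g.max(),
            "tmin_c": g.min(),
            "n_records": g.size(),
        }
    )
    out["dtr_c"] = out["tmax_c"] - out["tmin_c"]
    out["coverage"] = out["n_records"] / expected
    out["complete"] = out["coverage"] >= min_coverage
    return out.reset_index()


def gap_fill(
    primary: pd.DataFrame,
    donor: pd.DataFrame,
    cadence_min: int = 20,
    max_mean_diff_c: float = 0.1,
) -> tuple[pd.DataFrame, ConcordanceReport]:
    """Fill missing records in ``primary`` from ``donor``.

    The expected timeline is the full cadence grid between the primary's
    first and last records; grid points absent from the primary are gaps.
    Filling is refused (``GapFillError``) when the absolute mean
    temperature difference on the overlap exceeds ``max_mean_diff_c``.
    Gap points missing from the donor too remain unfilled and are counted.
    """
    p = primary.set_index("timestamp")["temp_c"]
    d = donor.set_index("timestamp")["temp_c"]
    overlap = p.index.intersection(d.index)
    if len(overlap) == 0:
        raise ValueError("donor does not overlap the primary series")
    mean_diff = float(p[overlap].mean() - d[overlap].mean())
    sd_diff = float(p[overlap].std(ddof=1) - d[overlap].std(ddof=1))

    grid = pd.date_range(p.index[0], p.index[-1], freq=f"{cadence_min}min")
    gaps = grid.difference(p.index)
    fillable = gaps.intersection(d.index)
    report = ConcordanceReport(
        n_overlap=len(overlap),
        mean_diff_c=mean_diff,
        sd_diff_c=sd_diff,
        n_filled=len(fillable),
        n_unfilled=len(gaps) - len(fillable),
    )
    if abs(mean_diff) > max_mean_diff_c:
        raise GapFillError(
            f"donor mean offset {mean_diff:+.3f} C exceeds "
            f"{max_mean_diff_c} C; refusing to fill",
            report,
        )
    if report.n_unfilled:
        warnings.warn(
            f"{report.n_unfilled} gap records missing from donor remain unfilled",
            stacklevel=2,
        )
    filled = pd.concat([p, d[fillable]]).sort_index()
    filled = filled.rename("temp_c").rename_axis("timestamp")
    return filled.reset_index(), report


def season_label(dates: pd.Series, season=DEFAULT_SEASON) -> pd.Series:
    """Season membership and label (start year) for a window that may span
    the year boundary; dates outside the window get label -1."""
    dates = pd.to_datetime(dates)
    (m0, d0), (m1, d1) = season
    key = dates.dt.month * 100 + dates.dt.day
    start, end = m0 * 100 + d0, m1 * 100 + d1
    if start <= end:  # within one calendar year
        in_season = (key >= start) & (key <= end)
        label = dates.dt.year
    else:  # spans the year boundary, e.g. Sep 1 - Jan 31
        in_season = (key >= start) | (key <= end)
        label = dates.dt.year.where(key >= start, dates.dt.year - 1)
    return label.where(in_season, -1)


def _season_length_days(season) -> float:
    (m0, d0), (m1, d1) = season
    t0 = pd.Timestamp(2001, m0, d0)
    t1 = pd.Timestamp(2001 if (m0, d0) <= (m1, d1) else 2002, m1, d1)
    return (t1 - t0).days + 1


def seasonal_dtr(
    daily: pd.DataFrame,
    season=DEFAULT_SEASON,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Mean DTR per season over complete days; labelled by start year.

    Seasons observing fewer than ``min_fraction`` of their days are
    flagged ``estimated=False`` (their mean is still reported as NaN).
    """
    days = daily[daily["complete"]].copy()
    days["season"] = season_label(days["date"], season)
    days = days[days["season"] >= 0]
    need = _season_length_days(season) * min_fraction
    g = days.groupby("season")["dtr_c"]
    out = pd.DataFrame({"mean_dtr_c": g.mean(), "n_days": g.size()})
    out["estimated"] = out["n_days"] >= need
    out.loc[~out["estimated"], "mean_dtr_c"] = np.nan
    return out.reset_index()


def wave_energy_flux(waves: pd.DataFrame) -> pd.DataFrame:
    """Per-record energy flux in kW/m; records with T_w <= 0 are rejected
    with a warning, negative H_sig is an error."""
    if (waves["hsig_m"] < 0).any():
        raise ValueError("significant wave height must be nonnegative")
    bad = waves["tw_s"] <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} records with nonpositive period dropped",
                      stacklevel=2)
    w = waves[~bad].copy()
    p_si = (
        SEAWATER_DENSITY * GRAVITY**2 * w["hsig_m"] ** 2 * w["tw_s"] / (64 * np.pi)
    )
    w["flux_kw_m"] = p_si / 1000.0
    return w


def seasonal_flux(
    flux: pd.DataFrame,
    season=DEFAULT_SEASON,
    mode: str = "mean",
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Seasonal aggregate (sum or mean) of wave energy flux.

    Coverage is the observed record count against the count expected at
    the series' median cadence; under-covered seasons are flagged
    ``estimated=False`` with value NaN ("not estimated").
    """
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    f = flux.copy()
    f["season"] = season_label(f["timestamp"], season)
    f = f[f["season"] >= 0]
    ts = pd.to_datetime(flux["timestamp"])
    cadence_h = ts.diff().median().total_seconds() / 3600.0 if len(ts) > 1 else 1.0
    expected = _season_length_days(season) * 24.0 / cadence_h
    g = f.groupby("season")["flux_kw_m"]
    agg = g.sum() if mode == "sum" else g.mean()
    # seasons fully inside a data gap must still appear, flagged
    (m0, d0), _ = season
    all_seasons = pd.Index(
        [
            y
            for y in range(ts.min().year - 1, ts.max().year + 1)
            if ts.min().normalize() <= pd.Timestamp(y, m0, d0) <= ts.max()
        ],
        name="season",
    )
    out = pd.DataFrame(
        {
            f"flux_{mode}_kw_m": agg.reindex(all_seasons),
            "n_records": g.size().reindex(all_seasons, fill_value=0),
        }
    )
    out["estimated"] = out["n_records"] >= expected * min_coverage
    out.loc[~out["estimated"], f"flux_{mode}_kw_m"] = np.nan
    return out.reset_index()
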