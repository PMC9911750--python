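"""CSV dialects for cover surveys, logger series and derived tables.

All files are UTF-8 CSV with a header row. Habitat and taxon labels are
open vocabularies and pass through untouched. Floats are written with
Python's shortest round-trip representation, so write(read(f)) preserves
every value exactly.

cover:        habitat,year,unit,taxon,cover       (cover % in [0, 100])
temperature:  habitat,timestamp,temp_c            (ISO-8601 timestamps)
waves:        timestamp,hsig_m,tw_s
metrics:      window_start,window_end,phi,cv,defined
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "FormatError",
    "read_cover",
    "write_cover",
    "read_temperature",
    "write_temperature",
    "read_waves",
    "write_waves",
    "read_metrics",
    "write_metrics",
]

COVER_COLUMNS = ["habitat", "year", "unit", "taxon", "cover"]
TEMP_COLUMNS = ["habitat", "timestamp", "temp_c"]
WAVE_COLUMNS = ["timestamp", "hsig_m", "tw_s"]
METRIC_COLUMNS = ["window_start", "window_end", "phi", "cv", "defined"]


class FormatError(ValueError):
    """A malformed input file; the message carries 1-based line numbers."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")


def _lines(mask: pd.Series) -> str:
    # +2: header line plus 1-based numbering
    return ", ".join(str(i + 2) for i in mask[mask].index[:10])


def read_cover(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, COVER_COLUMNS, path)
    bad = ~df["cover"].between(0.0, 100.0) | df["cover"].isna()
    if bad.any():
        raise FormatError(
            f"{path}: cover outside [0, 100] at line(s) {_lines(bad)}"
        )
    dup = df.duplicated(subset=["habitat", "year", "unit", "taxon"])
    if dup.any():
        raise FormatError(
            f"{path}: duplicate (habitat, year, unit, taxon) at line(s) {_lines(dup)}"
        )
    return df[COVER_COLUMNS]


def write_cover(df: pd.DataFrame, path: str | Path) -> None:
    df[COVER_COLUMNS].to_csv(path, index=False)


def _parse_timestamps(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        # ISO-8601, with or without seconds, parsed uniformly
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except ValueError as err:
        raise FormatError(f"{path}: unparseable timestamp ({err})") from err
    return df


def read_temperature(path: str | Path) -> dict[str, pd.DataFrame]:
    """One file may hold several habitats; returns {habitat: series}."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TEMP_COLUMNS, path)
    df = _parse_timestamps(df, path)
    out = {}
    for habitat, sub in df.groupby("habitat", sort=False):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        if sub["timestamp"].duplicated().any():
            raise FormatError(f"{path}: duplicate timestamps for {habitat!r}")
        out[str(habitat)] = sub[["timestamp", "temp_c"]]
    return out


def write_temperature(series: dict[str, pd.DataFrame], path: str | Path) -> None:
    frames = [s.assign(habitat=h)[TEMP_COLUMNS] for h, s in series.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_waves(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, WAVE_COLUMNS, path)
    df = _parse_timestamps(df, path)
    bad = (df["hsig_m"] < 0) | df["hsig_m"].isna()
    if bad.any():
        raise FormatError(f"{path}: negative H_sig at line(s) {_lines(bad)}")
    return df[WAVE_COLUMNS].sort_values("timestamp").reset_index(drop=True)


def write_waves(df: pd.DataFrame, path: str | Path) -> None:
    df[WAVE_COLUMNS].to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, METRIC_COLUMNS, path)
    return df[METRIC_COLUMNS]


def write_metrics(df: pd.DataFrame, path: str | Path) -> None:
    df[METRIC_COLUMNS].to_csv(path, index=False)
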