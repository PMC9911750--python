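"""Seeded synthetic data: cover surveys, temperature loggers, wave records.

Quadrat-level percent cover is drawn from a mean-corrected logit-normal
around the deterministic habitat x year x taxon expectation, which keeps
draws inside [0, 100] without truncation while leaving the configured
expectation exactly recoverable by averaging. Temperature series are
seasonal + diurnal sinusoids plus AR(1) noise; wave series are a constant
base state punctuated by Poisson-timed storm episodes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import ConfigurationError, SimulationConfig, TempParams, WaveParams

__all__ = [
    "generate_cover_surveys",
    "generate_temperature_series",
    "generate_wave_series",
    "logit_normal_location",
]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(64)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _expit(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def logit_normal_location(p: np.ndarray, sigma: float) -> np.ndarray:
    """Location mu such that E[expit(N(mu, sigma^2))] = p, for p in (0, 1).

    Solved by Newton iteration on a Gauss-Hermite estimate of the mean;
    without this correction the logit-normal mean is biased away from
    expit(logit(p)) by the Jensen gap, noticeably so for rare taxa.
    """
    p = np.asarray(p, dtype=float)
    if sigma == 0.0:
        with np.errstate(divide="ignore"):
            return np.log(p / (1.0 - p))
    mu = np.log(p / (1.0 - p))  # start at the naive logit
    z = sigma * _GH_NODES  # quadrature offsets
    for _ in range(50):
        f = _expit(mu[..., None] + z)
        mean = f @ _GH_WEIGHTS
        grad = (f * (1.0 - f)) @ _GH_WEIGHTS
        step = (mean - p) / np.maximum(grad, 1e-300)
        mu = mu - np.clip(step, -4.0, 4.0)
        if np.max(np.abs(mean - p)) < 1e-12:
            break
    return mu


def expected_cover_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic habitat x year x taxon expectations (%), pre-noise.

    Raises ``ConfigurationError`` naming the habitat/year if expectations
    sum above 100% of the substratum.
    """
    rows = []
    for habitat in config.habitats:
        for year in config.year_list():
            total = 0.0
            for taxon in config.taxa:
                e = config.expectation(habitat, taxon, year)
                total += e
                rows.append((habitat, year, taxon.name, e))
            if total > 100.0 + 1e-9:
                raise ConfigurationError(
                    f"expected cover in {habitat!r} year {year} sums to "
                    f"{total:.1f}% > 100%"
                )
    return pd.DataFrame(rows, columns=["habitat", "year", "taxon", "expected"])


def generate_cover_surveys(config: SimulationConfig) -> pd.DataFrame:
    """Simulate quadrat-level percent-cover surveys.

    Returns a long-format table with one row per (habitat, year, unit,
    taxon). Nested (bommie) designs encode units as ``"b<i>/q<j>"`` and add
    a bommie-level random effect on the logit scale; the location is
    corrected for the combined bommie + quadrat variance so habitat-level
    means stay unbiased. Per-quadrat totals are rescaled down in the rare
    event the independent taxon draws sum above 100%.
    """
    expected = expected_cover_table(config)
    rng = np.random.default_rng(config.seed)
    taxa = [t.name for t in config.taxa]
    frames: list[pd.DataFrame] = []
    for habitat in config.habitats:
        design = config.design_for(habitat)
        units = design.unit_ids()
        n_units = len(units)
        sigma_q = config.noise
        sigma_b = design.bommie_sd if design.nested else 0.0
        sigma_tot = float(np.hypot(sigma_q, sigma_b))
        for year in config.year_list():
            exp_ht = expected.query("habitat == @habitat and year == @year")
            p = exp_ht.set_index("taxon").loc[taxa, "expected"].to_numpy() / 100.0
            if sigma_tot > 0.0 and np.any(p >= 1.0):
                raise ConfigurationError(
                    f"expectation of 100% with noise in {habitat!r} year {year}"
                )
            cover = np.zeros((n_units, len(taxa)))
            pos = p > 0.0
            if pos.any():
                if sigma_tot == 0.0:
                    cover[:, pos] = 100.0 * p[pos]
                else:
                    mu = logit_normal_location(p[pos], sigma_tot)
                    eps = rng.normal(0.0, sigma_q, size=(n_units, pos.sum()))
                    if design.nested:
                        b = rng.normal(0.0, sigma_b, size=(design.n_bommies, pos.sum()))
                        eps += np.repeat(b, design.quadrats_per_bommie, axis=0)
                    cover[:, pos] = 100.0 * _expit(mu + eps)
            totals = cover.sum(axis=1)
            over = totals > 100.0
            if over.any():
                cover[over] *= (100.0 / totals[over])[:, None]
            frames.append(
                pd.DataFrame(
                    {
                        "habitat": habitat,
                        "year": year,
                        "unit": np.repeat(units, len(taxa)),
                        "taxon": np.tile(taxa, n_units),
                        "cover": cover.ravel(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _drop_gaps(frame: pd.DataFrame, gaps) -> pd.DataFrame:
    """Remove records inside [start, end] gap windows; a date-only end
    bound covers that whole day."""
    for g0, g1 in gaps:
        start, end = pd.Timestamp(g0), pd.Timestamp(g1)
        if end == end.normalize():
            end = end + pd.Timedelta(days=1) - pd.Timedelta(seconds=1)
        frame = frame[(frame.timestamp < start) | (frame.timestamp > end)]
    return frame.reset_index(drop=True)


def _temperature_one(
    params: TempParams,
    start: str,
    end: str,
    rng: np.random.Generator,
    anomaly: dict[int, float] | None = None,
) -> pd.DataFrame:
    if (24 * 60) % params.cadence_min != 0:
        raise ConfigurationError("temperature cadence must divide 24 h")
    ts = pd.date_range(start, end, freq=f"{params.cadence_min}min")
    doy = ts.dayofyear.to_numpy() + ts.hour.to_numpy() / 24.0
    hour = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    temp = (
        params.mean_c
        + params.seasonal_amp_c * np.cos(2 * np.pi * (doy - params.peak_doy) / 365.25)
        + params.diurnal_amp_c * np.cos(2 * np.pi * (hour - params.peak_hour) / 24.0)
    )
    if anomaly:
        temp = temp + np.array([anomaly.get(y, 0.0) for y in ts.year])
    if params.ar_sd_c > 0.0:
        innov_sd = params.ar_sd_c * np.sqrt(1.0 - params.ar_coef**2)
        innov = rng.normal(0.0, innov_sd, size=len(ts))
        x0 = rng.normal(0.0, params.ar_sd_c)  # stationary start
        noise, _ = lfilter([1.0], [1.0, -params.ar_coef], innov, zi=[params.ar_coef * x0])
        temp = temp + noise
    out = pd.DataFrame({"timestamp": ts, "temp_c": temp})
    return _drop_gaps(out, params.gaps)


def generate_temperature_series(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Per-habitat logger series spanning the survey years at the
    configured cadence; habitats without temp_params are omitted."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    start = f"{config.years[0]}-01-01"
    end = f"{config.years[1]}-12-31 23:59"
    # regional warm/cool years are shared by every habitat's logger
    anomaly = {
        y: float(rng.normal(0.0, config.regional_anomaly_sd_c))
        for y in config.year_list()
    }
    return {
        habitat: _temperature_one(
            config.temp_params[habitat], start, end, rng, anomaly
        )
        for habitat in config.habitats
        if habitat in config.temp_params
    }


def generate_wave_series(config: SimulationConfig) -> pd.DataFrame:
    """Hourly-scale H_sig / T_w records with Poisson-timed storm seasons.

    Storm counts are drawn per September-December season; each storm
    multiplies H_sig by the configured factor for its duration. With a
    storm rate of zero the series is constant at the base state.
    """
    wp: WaveParams = config.wave_params
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    ts = pd.date_range(
        f"{config.years[0]}-01-01",
        f"{config.years[1]}-12-31 23:59",
        freq=f"{int(wp.cadence_h * 60)}min",
    )
    hsig = np.full(len(ts), wp.base_hsig_m)
    for year in config.year_list():
        n_storms = rng.poisson(wp.storm_rate)
        season_start = pd.Timestamp(f"{year}-09-01")
        season_end = pd.Timestamp(f"{year}-12-31 23:59")
        span_h = (season_end - season_start).total_seconds() / 3600.0
        for _ in range(n_storms):
            t0 = season_start + pd.Timedelta(hours=float(rng.uniform(0, span_h)))
            t1 = t0 + pd.Timedelta(hours=wp.storm_duration_h)
            in_storm = (ts >= t0) & (ts <= t1)
            hsig[in_storm] = wp.base_hsig_m * wp.storm_multiplier
    out = pd.DataFrame({"timestamp": ts, "hsig_m": hsig, "tw_s": wp.base_tw_s})
    return _drop_gaps(out, wp.gaps)
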