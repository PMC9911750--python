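"""End-to-end analysis: cover surveys -> synchrony/stability statistics.

``run_full_analysis`` chains the stages in the order an analyst would run
them by hand: aggregate quadrat cover, windowed phi/CV, per-habitat NMDS
ordinations, quadrat-level two-factor PERMANOVA, temperature and wave
covariates, and the model II regression of CV on phi. Every intermediate
is written to the output directory; the report ends with a provenance
block (config hash, root seed, package version) sufficient to reproduce
the run. All randomness flows from the single root seed, split per stage.
"""
from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, io
from .association import MAFit, ma_regression_from_metrics
from .config import ConfigurationError, SimulationConfig, moorea_preset
from .environment import (
    DEFAULT_SEASON,
    daily_stats,
    qc_temperature,
    seasonal_dtr,
    seasonal_flux,
    wave_energy_flux,
)
from .metrics import aggregate_cover, pairwise_synchrony, windowed_metrics
from .multivariate import (
    Ordination,
    PermanovaResult,
    nmds,
    permanova_two_way,
    zero_adjusted_bray_curtis,
)
from .synthetic import (
    generate_cover_surveys,
    generate_temperature_series,
    generate_wave_series,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "StageError", "run_full_analysis"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class AnalysisConfig:
    # inputs: either file paths or a simulation config (paths win if both)
    cover_path: str | None = None
    temperature_path: str | None = None
    waves_path: str | None = None
    simulation: SimulationConfig | None = None
    # analysis settings
    element_mode: str = "habitat_taxon"
    window: int = 2
    nmds_restarts: int = 20
    nmds_stress_tol: float = 0.02
    n_permutations: int = 999
    season: tuple = DEFAULT_SEASON
    flux_mode: str = "mean"
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "AnalysisConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim == "moorea" or sim == {"preset": "moorea"}:
            sim = moorea_preset(seed=raw.get("seed", 0))
        elif isinstance(sim, dict):
            raise ConfigurationError(
                "inline simulation configs are not supported; use the "
                "'moorea' preset or construct SimulationConfig in code"
            )
        season = raw.pop("season", None)
        cfg = cls(simulation=sim, **raw)
        if season is not None:
            cfg.season = ((season[0][0], season[0][1]), (season[1][0], season[1][1]))
        return cfg

    def digest(self) -> str:
        # outdir is run plumbing, not analysis configuration
        blob = json.dumps(
            {
                k: (asdict(v) if isinstance(v, SimulationConfig) else v)
                for k, v in asdict(self).items()
                if k != "outdir"
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    aggregated: pd.DataFrame
    metrics: pd.DataFrame
    ordinations: dict[str, Ordination]
    permanova: PermanovaResult | None
    daily_temperature: dict[str, pd.DataFrame]
    seasonal_dtr: pd.DataFrame | None
    temperature_synchrony: pd.DataFrame | None
    seasonal_flux: pd.DataFrame | None
    ma_fit: MAFit | None
    dropped: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def summary(self) -> dict[str, Any]:
        out: dict[str, Any] = {"provenance": self.provenance}
        defined = self.metrics[self.metrics["defined"]]
        out["windows"] = {
            "n_total": int(len(self.metrics)),
            "n_defined": int(len(defined)),
            "phi_range": [float(defined["phi"].min()), float(defined["phi"].max())]
            if len(defined)
            else None,
            "cv_range": [float(defined["cv"].min()), float(defined["cv"].max())]
            if len(defined)
            else None,
        }
        if self.ma_fit is not None:
            out["ma_fit"] = asdict(self.ma_fit)
        if self.permanova is not None and not self.permanova.undefined:
            out["permanova"] = self.permanova.terms.to_dict("index")
            out["permanova"]["residual"] = {
                "ss": self.permanova.residual_ss,
                "df": self.permanova.residual_df,
            }
        out["ordinations"] = {
            h: {"stress": o.stress, "n_restarts_used": o.n_restarts_used}
            for h, o in self.ordinations.items()
        }
        if self.temperature_synchrony is not None:
            out["temperature_synchrony"] = self.temperature_synchrony.to_dict("records")
        out["dropped"] = self.dropped
        return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as err:  # noqa: BLE001 - re-tagged with stage name
                raise StageError(name, err) from err

        return wrapped

    return deco


@_stage("inputs")
def _load_inputs(config: AnalysisConfig):
    cover = temps = waves = None
    if config.cover_path:
        cover = io.read_cover(config.cover_path)
    if config.temperature_path:
        temps = io.read_temperature(config.temperature_path)
    if config.waves_path:
        waves = io.read_waves(config.waves_path)
    if config.simulation is not None:
        sim = config.simulation
        if cover is None:
            cover = generate_cover_surveys(sim)
        if temps is None:
            temps = generate_temperature_series(sim)
        if waves is None:
            waves = generate_wave_series(sim)
    if cover is None:
        raise ConfigurationError("no cover input: give cover_path or simulation")
    return cover, temps, waves


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    dropped: dict[str, int] = {}
    cover, temps, waves = _load_inputs(config)

    agg = _stage("aggregate")(aggregate_cover)(cover)
    metrics = _stage("metrics")(windowed_metrics)(
        agg, mode=config.element_mode, window=config.window
    ).frame

    ordinations = _run_ordinations(config, agg)
    permanova = _run_permanova(config, cover)

    daily, sdtr, tsync = _run_temperature(config, temps, dropped)
    sflux = _run_waves(config, waves)

    ma_fit = None
    if metrics["defined"].sum() >= 3:
        try:
            ma_fit = ma_regression_from_metrics(metrics)
        except ValueError as err:  # degenerate phi/CV cloud, e.g. phi == 1
            warnings.warn(f"MA regression degenerate: {err}", stacklevel=2)
    else:
        warnings.warn("fewer than 3 defined windows: MA regression skipped",
                      stacklevel=2)

    report = AnalysisReport(
        aggregated=agg,
        metrics=metrics,
        ordinations=ordinations,
        permanova=permanova,
        daily_temperature=daily,
        seasonal_dtr=sdtr,
        temperature_synchrony=tsync,
        seasonal_flux=sflux,
        ma_fit=ma_fit,
        dropped=dropped,
        provenance={
            "config_sha256": config.digest(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    if outdir:
        _write_report(report, cover, outdir)
    return report


@_stage("ordination")
def _run_ordinations(config: AnalysisConfig, agg: pd.DataFrame):
    """Per-habitat NMDS of annual communities (years as samples)."""
    out: dict[str, Ordination] = {}
    for habitat, sub in agg.groupby("habitat", sort=True):
        wide = sub.pivot_table(index="year", columns="taxon", values="mean_cover")
        if len(wide) < 4:
            continue
        dm = zero_adjusted_bray_curtis(wide, labels=[str(y) for y in wide.index])
        out[str(habitat)] = nmds(
            dm,
            restarts=config.nmds_restarts,
            stress_tol=config.nmds_stress_tol,
            seed=np.random.SeedSequence([config.seed, 10]).generate_state(1)[0]
            % 2**31,
        )
    return out


@_stage("permanova")
def _run_permanova(config: AnalysisConfig, cover: pd.DataFrame):
    """Quadrat-level two-factor PERMANOVA on zero-adjusted Bray-Curtis."""
    wide = cover.pivot_table(
        index=["habitat", "year", "unit"],
        columns="taxon",
        values="cover",
        fill_value=0.0,
    )
    habitat = wide.index.get_level_values("habitat").to_numpy()
    year = wide.index.get_level_values("year").to_numpy()
    if len(np.unique(habitat)) < 2 or len(np.unique(year)) < 2:
        return None
    dm = zero_adjusted_bray_curtis(wide.to_numpy())
    return permanova_two_way(
        dm,
        habitat,
        year,
        n_perm=config.n_permutations,
        seed=np.random.SeedSequence([config.seed, 11]).generate_state(1)[0] % 2**31,
    )


@_stage("environment")
def _run_temperature(config: AnalysisConfig, temps, dropped):
    if not temps:
        return {}, None, None
    daily: dict[str, pd.DataFrame] = {}
    sdtr_frames = []
    for habitat, series in temps.items():
        clean, n_bad = qc_temperature(series)
        dropped[f"temperature_qc_{habitat}"] = n_bad
        d = daily_stats(clean)
        daily[habitat] = d
        s = seasonal_dtr(d, season=config.season).assign(habitat=habitat)
        sdtr_frames.append(s)
    sdtr = pd.concat(sdtr_frames, ignore_index=True)

    # between-habitat synchrony of annual mean temperature vs annual DTR
    rows = []
    annual_mean = {
        h: d[d["complete"]].groupby(d["date"].dt.year)["mean_c"].mean()
        for h, d in daily.items()
    }
    annual_dtr = {
        h: d[d["complete"]].groupby(d["date"].dt.year)["dtr_c"].mean()
        for h, d in daily.items()
    }
    for a, b in itertools.combinations(sorted(daily), 2):
        years = annual_mean[a].index.intersection(annual_mean[b].index)
        if len(years) < 2:
            continue
        rows.append(
            {
                "habitat_a": a,
                "habitat_b": b,
                "phi_mean_temp": pairwise_synchrony(
                    annual_mean[a][years], annual_mean[b][years]
                ),
                "phi_dtr": pairwise_synchrony(
                    annual_dtr[a][years], annual_dtr[b][years]
                ),
            }
        )
    tsync = pd.DataFrame(rows) if rows else None
    return daily, sdtr, tsync


@_stage("waves")
def _run_waves(config: AnalysisConfig, waves):
    if waves is None or waves.empty:
        return None
    flux = wave_energy_flux(waves)
    return seasonal_flux(flux, season=config.season, mode=config.flux_mode)


@_stage("write")
def _write_report(report: AnalysisReport, cover: pd.DataFrame, outdir: Path) -> None:
    io.write_cover(cover, outdir / "cover.csv")
    report.aggregated.to_csv(outdir / "aggregated_cover.csv", index=False)
    io.write_metrics(report.metrics, outdir / "metrics.csv")
    for habitat, ordn in report.ordinations.items():
        pd.DataFrame(ordn.coordinates, columns=["nmds1", "nmds2"]).to_csv(
            outdir / f"nmds_{habitat}.csv", index=False
        )
    if report.permanova is not None and not report.permanova.undefined:
        report.permanova.terms.to_csv(outdir / "permanova.csv")
    if report.seasonal_dtr is not None:
        report.seasonal_dtr.to_csv(outdir / "seasonal_dtr.csv", index=False)
    if report.seasonal_flux is not None:
        report.seasonal_flux.to_csv(outdir / "seasonal_flux.csv", index=False)
    if report.temperature_synchrony is not None:
        report.temperature_synchrony.to_csv(
            outdir / "temperature_synchrony.csv", index=False
        )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, default=float)
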