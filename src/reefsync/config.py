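"""Configuration objects for the simulator and the analysis pipeline.

The simulator emulates a four-habitat fringing/back-reef/fore-reef survey
design: annual percent-cover surveys of coral taxa in fixed quadrats, plus
in-situ temperature loggers and a wave meter. All stochastic behaviour is
driven by a single integer seed so that reruns are bit-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping, Sequence

__all__ = [
    "DisturbanceEvent",
    "TaxonSpec",
    "QuadratDesign",
    "TempParams",
    "WaveParams",
    "SimulationConfig",
    "ConfigurationError",
    "moorea_preset",
]


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis configuration is inconsistent."""


@dataclass(frozen=True)
class DisturbanceEvent:
    """A press (multi-year) or pulse (single-event) mortality episode.

    ``survival`` is the fraction of cover retained: per elapsed year for a
    press (e.g. a multi-year corallivore outbreak), once for a pulse (e.g.
    a cyclone). ``habitats``/``taxa`` of ``None`` mean "all".
    """

    kind: Literal["press", "pulse"]
    start_year: int
    end_year: int
    survival: float
    habitats: tuple[str, ...] | None = None
    taxa: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("press", "pulse"):
            raise ConfigurationError(f"unknown disturbance kind {self.kind!r}")
        if not (0.0 < self.survival <= 1.0):
            raise ConfigurationError(
                f"survival must be in (0, 1], got {self.survival}"
            )
        if self.start_year > self.end_year:
            raise ConfigurationError("disturbance start_year > end_year")

    def factor(self, habitat: str, taxon: str, year: int) -> float:
        """Cumulative survival multiplier applied to cover in ``year``."""
        if self.habitats is not None and habitat not in self.habitats:
            return 1.0
        if self.taxa is not None and taxon not in self.taxa:
            return 1.0
        if year < self.start_year:
            return 1.0
        if self.kind == "pulse":
            return self.survival
        years_applied = min(year, self.end_year) - self.start_year + 1
        return self.survival**years_applied


@dataclass(frozen=True)
class TaxonSpec:
    """Baseline mean cover (%) and geometric per-year trend per habitat.

    The deterministic expectation in year ``y`` is
    ``baseline[h] * trend[h] ** (y - first_year)`` times the product of all
    applicable disturbance survival factors. Habitats absent from
    ``baseline`` carry zero cover.
    """

    name: str
    baseline: Mapping[str, float]
    trend: Mapping[str, float] = field(default_factory=dict)

    def expectation(
        self,
        habitat: str,
        year: int,
        first_year: int,
        disturbances: Sequence[DisturbanceEvent],
    ) -> float:
        base = float(self.baseline.get(habitat, 0.0))
        if base == 0.0:
            return 0.0
        growth = float(self.trend.get(habitat, 1.0)) ** (year - first_year)
        surv = 1.0
        for ev in disturbances:
            surv *= ev.factor(habitat, self.name, year)
        return base * growth * surv


@dataclass(frozen=True)
class QuadratDesign:
    """Sampling layout for one habitat.

    Flat designs use ``n_quadrats`` independent quadrats. Nested designs
    (``n_bommies`` > 0) group ``quadrats_per_bommie`` quadrats on each of
    ``n_bommies`` patch reefs, with a bommie-level random effect of sd
    ``bommie_sd`` on the logit-cover scale.
    """

    n_quadrats: int = 40
    n_bommies: int = 0
    quadrats_per_bommie: int = 0
    bommie_sd: float = 0.0

    @property
    def nested(self) -> bool:
        return self.n_bommies > 0

    def unit_ids(self) -> list[str]:
        if self.nested:
            return [
                f"b{b + 1}/q{q + 1:02d}"
                for b in range(self.n_bommies)
                for q in range(self.quadrats_per_bommie)
            ]
        return [f"q{q + 1:02d}" for q in range(self.n_quadrats)]


@dataclass(frozen=True)
class TempParams:
    """Seawater temperature model for one habitat logger.

    temp(t) = mean + seasonal_amp*cos(2*pi*(doy - peak_doy)/365.25)
                   + diurnal_amp*cos(2*pi*(hour - peak_hour)/24) + AR(1).
    ``ar_sd`` is the stationary sd of the AR(1) term. The default seasonal
    peak (early March) follows the southern-hemisphere convention.
    """

    mean_c: float = 27.8
    seasonal_amp_c: float = 1.3
    diurnal_amp_c: float = 0.3
    ar_sd_c: float = 0.05
    ar_coef: float = 0.8
    cadence_min: int = 20
    peak_doy: float = 66.0
    peak_hour: float = 15.0
    gaps: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class WaveParams:
    """Wave climate at the fore-reef meter.

    Significant wave height sits at ``base_hsig_m`` except during storm
    episodes, whose count per storm season (September-December) is Poisson
    with mean ``storm_rate``; a storm multiplies H_sig by
    ``storm_multiplier`` for ``storm_duration_h`` hours.
    """

    base_hsig_m: float = 1.0
    base_tw_s: float = 12.0
    storm_rate: float = 0.9
    storm_multiplier: float = 2.5
    storm_duration_h: float = 72.0
    cadence_h: float = 1.0
    gaps: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class SimulationConfig:
    habitats: tuple[str, ...]
    years: tuple[int, int]  # inclusive survey range
    taxa: tuple[TaxonSpec, ...]
    disturbances: tuple[DisturbanceEvent, ...] = ()
    quadrat_design: Mapping[str, QuadratDesign] = field(default_factory=dict)
    noise: float = 0.35  # quadrat overdispersion, logit-scale sd
    temp_params: Mapping[str, TempParams] = field(default_factory=dict)
    # yearly regional temperature anomaly (e.g. ENSO-scale warm/cool
    # years), shared by all habitat loggers; drives high between-habitat
    # synchrony of annual mean temperature without touching daily range
    regional_anomaly_sd_c: float = 0.15
    wave_params: WaveParams = field(default_factory=WaveParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years[0] > self.years[1]:
            raise ConfigurationError("years range is reversed")
        if self.noise < 0:
            raise ConfigurationError("noise sd must be nonnegative")
        for h, tp in self.temp_params.items():
            for name in ("seasonal_amp_c", "diurnal_amp_c", "ar_sd_c"):
                if getattr(tp, name) < 0:
                    raise ConfigurationError(f"{h}: {name} must be nonnegative")
        wp = self.wave_params
        if wp.base_hsig_m < 0 or wp.base_tw_s <= 0 or wp.storm_rate < 0:
            raise ConfigurationError("invalid wave parameters")
        for h in self.habitats:
            total = sum(t.baseline.get(h, 0.0) for t in self.taxa)
            if total > 100.0 + 1e-9:
                raise ConfigurationError(
                    f"baseline covers in habitat {h!r} sum to {total:.1f}% > 100%"
                )

    def design_for(self, habitat: str) -> QuadratDesign:
        return self.quadrat_design.get(habitat, QuadratDesign())

    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def expectation(self, habitat: str, taxon: TaxonSpec, year: int) -> float:
        return taxon.expectation(habitat, year, self.years[0], self.disturbances)

    def to_dict(self) -> dict:
        return asdict(self)


# Habitat labels used throughout the Moorea-style preset.
FRINGING = "fringing"
BACK_REEF = "back_reef"
FORE_REEF_10 = "fore_reef_10m"
FORE_REEF_17 = "fore_reef_17m"
FORE_REEF = (FORE_REEF_10, FORE_REEF_17)


def moorea_preset(seed: int = 0, noise: float = 0.35) -> SimulationConfig:
    """Four-habitat preset emulating the 2006-2019 Moorea LTER-style design.

    Lagoon habitats (fringing, back reef) carry Porites-dominated
    assemblages in slow monotonic decline; the two fore-reef depths start
    near 45% cover, crash under a multi-year corallivore press (2007-2009)
    followed by a cyclone pulse (2010), then recover rapidly, led by
    Pocillopora. Temperature loggers differ mainly in diurnal range
    (fringing ~1.07 C vs fore reef ~0.33 C daily range); the wave meter
    sees episodic storm seasons.
    """
    fr10, fr17 = FORE_REEF
    taxa = (
        TaxonSpec(
            "Porites",
            baseline={FRINGING: 25.0, BACK_REEF: 31.0, fr10: 13.0, fr17: 23.0},
            trend={FRINGING: 0.82, BACK_REEF: 0.89, fr10: 1.22, fr17: 1.28},
        ),
        TaxonSpec(
            "Pocillopora",
            baseline={FRINGING: 1.0, BACK_REEF: 1.0, fr10: 22.0, fr17: 8.0},
            trend={FRINGING: 0.95, BACK_REEF: 1.08, fr10: 1.62, fr17: 1.62},
        ),
        TaxonSpec(
            "Acropora",
            baseline={fr10: 8.0, fr17: 4.5},
            trend={fr10: 1.30, fr17: 1.30},
        ),
        TaxonSpec(
            "Montipora",
            baseline={FRINGING: 1.5, BACK_REEF: 4.0, fr10: 2.0, fr17: 5.0},
            trend={FRINGING: 0.92, BACK_REEF: 0.97, fr10: 1.30, fr17: 1.25},
        ),
        TaxonSpec(
            "Pavona",
            baseline={BACK_REEF: 0.6, fr10: 0.6, fr17: 1.6},
            trend={BACK_REEF: 0.95, fr10: 1.25, fr17: 1.22},
        ),
        TaxonSpec(
            "Millepora",
            baseline={BACK_REEF: 0.2, fr17: 1.0},
            trend={BACK_REEF: 0.98, fr17: 1.18},
        ),
        TaxonSpec(
            "Acanthastrea",
            baseline={FRINGING: 1.2},
            trend={FRINGING: 0.93},
        ),
        TaxonSpec(
            "Fungiidae",
            baseline={FRINGING: 1.3, fr10: 0.4, fr17: 0.5},
            trend={FRINGING: 0.96, fr10: 1.28, fr17: 1.25},
        ),
    )
    disturbances = (
        # Corallivorous seastar outbreak: press mortality on the fore reef.
        DisturbanceEvent(
            kind="press",
            start_year=2007,
            end_year=2009,
            survival=0.38,
            habitats=FORE_REEF,
        ),
        # Cyclone pulse removing most remaining fore-reef cover.
        DisturbanceEvent(
            kind="pulse",
            start_year=2010,
            end_year=2010,
            survival=0.12,
            habitats=FORE_REEF,
        ),
    )
    quadrat_design = {
        FRINGING: QuadratDesign(n_quadrats=40),
        BACK_REEF: QuadratDesign(
            n_quadrats=0, n_bommies=5, quadrats_per_bommie=20, bommie_sd=0.15
        ),
        fr10: QuadratDesign(n_quadrats=40),
        fr17: QuadratDesign(n_quadrats=40),
    }
    temp_params = {
        FRINGING: TempParams(mean_c=27.86, diurnal_amp_c=0.535, ar_sd_c=0.03),
        BACK_REEF: TempParams(mean_c=27.80, diurnal_amp_c=0.40, ar_sd_c=0.03),
        fr10: TempParams(mean_c=27.78, diurnal_amp_c=0.165, ar_sd_c=0.03),
        fr17: TempParams(mean_c=27.73, diurnal_amp_c=0.13, ar_sd_c=0.03),
    }
    return SimulationConfig(
        habitats=(FRINGING, BACK_REEF, fr10, fr17),
        years=(2006, 2019),
        taxa=taxa,
        disturbances=disturbances,
        quadrat_design=quadrat_design,
        noise=noise,
        temp_params=temp_params,
        wave_params=WaveParams(),
        seed=seed,
    )
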