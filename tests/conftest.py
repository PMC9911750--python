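import numpy as np
import pandas as pd
import pytest

from reefsync.config import (
    DisturbanceEvent,
    QuadratDesign,
    SimulationConfig,
    TaxonSpec,
    TempParams,
    WaveParams,
    moorea_preset,
)
from reefsync.metrics import aggregate_cover
from reefsync.synthetic import generate_cover_surveys


def small_config(seed=0, noise=0.3, **overrides):
    """Two-habitat, four-year toy survey used by fast unit tests."""
    base = dict(
        habitats=("lagoon", "slope"),
        years=(2000, 2003),
        taxa=(
            TaxonSpec(
                "A", baseline={"lagoon": 20.0, "slope": 30.0},
                trend={"lagoon": 0.9, "slope": 1.1},
            ),
            TaxonSpec("B", baseline={"lagoon": 5.0, "slope": 10.0}),
        ),
        quadrat_design={
            "lagoon": QuadratDesign(n_quadrats=8),
            "slope": QuadratDesign(n_quadrats=8),
        },
        noise=noise,
        temp_params={
            "lagoon": TempParams(diurnal_amp_c=0.5, ar_sd_c=0.0, seasonal_amp_c=1.0),
            "slope": TempParams(diurnal_amp_c=0.2, ar_sd_c=0.0, seasonal_amp_c=1.0),
        },
        wave_params=WaveParams(storm_rate=0.0),
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def moorea_cover():
    return generate_cover_surveys(moorea_preset(seed=7))


@pytest.fixture(scope="session")
def moorea_aggregated(moorea_cover):
    return aggregate_cover(moorea_cover)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_cover_table(values):
    """Long cover table from {(habitat, year, unit, taxon): cover}."""
    rows = [
        {"habitat": h, "year": y, "unit": u, "taxon": t, "cover": c}
        for (h, y, u, t), c in values.items()
    ]
    return pd.DataFrame(rows)
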