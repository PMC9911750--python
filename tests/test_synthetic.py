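"""The simulator must be seed-deterministic, respect cover bounds, and
recover its configured expectations under averaging."""
import numpy as np
import pandas as pd
import pytest

from reefsync.config import (
    ConfigurationError,
    DisturbanceEvent,
    QuadratDesign,
    SimulationConfig,
    TaxonSpec,
    TempParams,
    WaveParams,
    moorea_preset,
)
from reefsync.environment import daily_stats, seasonal_flux, wave_energy_flux
from reefsync.synthetic import (
    expected_cover_table,
    generate_cover_surveys,
    generate_temperature_series,
    generate_wave_series,
    logit_normal_location,
)

from conftest import small_config


class TestCoverSurveys:
    def test_identical_seed_gives_byte_identical_tables(self):
        a = generate_cover_surveys(small_config(seed=5))
        b = generate_cover_surveys(small_config(seed=5))
        assert a.to_csv() == b.to_csv()
        c = generate_cover_surveys(small_config(seed=6))
        assert not a.equals(c)

    def test_zero_noise_yields_exact_expectations(self):
        cfg = small_config(
            noise=0.0,
            taxa=(TaxonSpec("A", baseline={"lagoon": 30.0, "slope": 30.0}),),
        )
        cover = generate_cover_surveys(cfg)
        assert (cover["cover"] == 30.0).all()

    def test_cover_bounds_and_quadrat_total(self):
        cfg = small_config(seed=11, noise=1.2)
        cover = generate_cover_surveys(cfg)
        assert cover["cover"].between(0, 100).all()
        totals = cover.groupby(["habitat", "year", "unit"])["cover"].sum()
        assert (totals <= 100.0 + 1e-9).all()

    def test_pulse_reduces_next_year_mean_by_survival_fraction(self):
        """Survival 0.1 in the pulse year leaves ~10% of the prior-year
        mean, within Monte-Carlo error across seeds."""
        ratios = []
        for seed in range(100):
            cfg = small_config(
                seed=seed,
                noise=0.35,
                taxa=(TaxonSpec("A", baseline={"lagoon": 30.0, "slope": 30.0}),),
                disturbances=(
                    DisturbanceEvent("pulse", 2001, 2001, 0.1, habitats=("slope",)),
                ),
            )
            cover = generate_cover_surveys(cfg)
            m = cover.query("habitat == 'slope'").groupby("year")["cover"].mean()
            ratios.append(m[2001] / m[2000])
        ratios = np.asarray(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.1) < 3 * se + 0.01

    def test_mean_recovers_analytic_expectation(self):
        """Mean-corrected logit-normal noise leaves habitat x year x taxon
        means unbiased (within 3 Monte-Carlo SE over 100 seeds)."""
        cells = []
        for seed in range(100):
            cfg = small_config(seed=seed, noise=0.5)
            cover = generate_cover_surveys(cfg)
            cells.append(
                cover.groupby(["habitat", "year", "taxon"])["cover"].mean()
            )
        stack = pd.concat(cells, axis=1)
        expected = expected_cover_table(cfg).set_index(
            ["habitat", "year", "taxon"]
        )["expected"]
        mean = stack.mean(axis=1)
        se = stack.std(axis=1, ddof=1) / np.sqrt(stack.shape[1])
        resid = (mean - expected.reindex(mean.index)).abs()
        assert (resid <= 3 * se + 1e-9).mean() > 0.95  # ~99.7% nominal

    def test_disturbance_never_increases_expectations(self):
        cfg = small_config()
        press = DisturbanceEvent("press", 2001, 2002, 0.5)
        cfg_dist = small_config(disturbances=(press,))
        e0 = expected_cover_table(cfg).set_index(["habitat", "year", "taxon"])
        e1 = expected_cover_table(cfg_dist).set_index(["habitat", "year", "taxon"])
        assert (e1["expected"] <= e0["expected"] + 1e-12).all()

    def test_expectation_above_100_names_habitat_and_year(self):
        cfg = small_config(
            taxa=(
                TaxonSpec("A", baseline={"slope": 60.0}, trend={"slope": 1.3}),
                TaxonSpec("B", baseline={"slope": 35.0}),
            ),
        )
        with pytest.raises(ConfigurationError, match="slope.*2001"):
            generate_cover_surveys(cfg)

    def test_baseline_sum_above_100_rejected(self):
        with pytest.raises(ConfigurationError, match="sum"):
            small_config(
                taxa=(
                    TaxonSpec("A", baseline={"lagoon": 70.0}),
                    TaxonSpec("B", baseline={"lagoon": 40.0}),
                )
            )

    def test_nested_design_unit_ids_and_bommie_structure(self):
        cfg = small_config(
            quadrat_design={
                "lagoon": QuadratDesign(
                    n_quadrats=0, n_bommies=3, quadrats_per_bommie=4, bommie_sd=0.3
                ),
                "slope": QuadratDesign(n_quadrats=8),
            }
        )
        cover = generate_cover_surveys(cfg)
        lagoon_units = cover.query("habitat == 'lagoon'")["unit"].unique()
        assert len(lagoon_units) == 12
        assert all("/" in u for u in lagoon_units)

    def test_moorea_preset_trajectories(self):
        """Fore reef crashes to near-zero by the pulse year then recovers;
        fringing declines monotonically without recovery."""
        cover = generate_cover_surveys(moorea_preset(seed=0))
        total = cover.groupby(["habitat", "year", "unit"])["cover"].sum()
        mean = total.groupby(["habitat", "year"]).mean().unstack("habitat")
        fore = mean["fore_reef_10m"]
        assert fore[2006] > 40
        assert fore[2010] < 3
        assert fore[2019] > 30  # recovery
        fringe = mean["fringing"]
        assert fringe[2019] < 0.3 * fringe[2006]
        assert fringe[2019] == pytest.approx(fringe.min(), rel=0.6)


class TestLogitNormalLocation:
    def test_mean_matches_target(self, rng):
        p = np.array([0.001, 0.05, 0.3, 0.7, 0.95])
        mu = logit_normal_location(p, 0.8)
        draws = 1 / (1 + np.exp(-(mu + 0.8 * rng.standard_normal((400_000, 5)))))
        assert np.allclose(draws.mean(axis=0), p, atol=3e-3)

    def test_zero_sigma_is_plain_logit(self):
        assert logit_normal_location(np.array([0.25]), 0.0) == pytest.approx(
            np.log(0.25 / 0.75)
        )


class TestTemperature:
    def test_zero_diurnal_amplitude_and_noise_gives_zero_dtr(self):
        cfg = small_config(
            temp_params={
                "lagoon": TempParams(
                    diurnal_amp_c=0.0, ar_sd_c=0.0, seasonal_amp_c=0.0
                )
            },
            years=(2000, 2000),
        )
        series = generate_temperature_series(cfg)["lagoon"]
        d = daily_stats(series)
        assert np.allclose(d["dtr_c"], 0.0)

    def test_diurnal_amplitude_sets_dtr_to_twice_amplitude(self):
        a = 0.5
        cfg = small_config(
            temp_params={
                "lagoon": TempParams(diurnal_amp_c=a, ar_sd_c=0.0, seasonal_amp_c=0.0)
            },
            years=(2000, 2000),
        )
        d = daily_stats(generate_temperature_series(cfg)["lagoon"])
        # within the discretization error of one 20-minute cadence step
        step = 2 * np.pi * 20 / (24 * 60)
        assert np.allclose(d["dtr_c"], 2 * a, atol=2 * a * (1 - np.cos(step / 2)) + 1e-9)

    def test_calibrated_amplitudes_reproduce_habitat_dtr_contrast(self):
        """Amplitudes of 0.535 and 0.165 C give long-run mean DTRs near
        1.07 and 0.33 C (the fringing vs fore-reef contrast)."""
        cfg = small_config(
            temp_params={
                "lagoon": TempParams(
                    diurnal_amp_c=0.535, ar_sd_c=0.0, seasonal_amp_c=0.0
                ),
                "slope": TempParams(
                    diurnal_amp_c=0.165, ar_sd_c=0.0, seasonal_amp_c=0.0
                ),
            },
            years=(2000, 2001),
        )
        series = generate_temperature_series(cfg)
        dtr = {h: daily_stats(s)["dtr_c"].mean() for h, s in series.items()}
        assert dtr["lagoon"] == pytest.approx(1.07, abs=0.02)
        assert dtr["slope"] == pytest.approx(0.33, abs=0.02)

    def test_cadence_must_divide_day(self):
        cfg = small_config(
            temp_params={"lagoon": TempParams(cadence_min=70)},
        )
        with pytest.raises(ConfigurationError, match="cadence"):
            generate_temperature_series(cfg)

    def test_gap_injection_removes_records(self):
        cfg = small_config(
            years=(2000, 2000),
            temp_params={
                "lagoon": TempParams(
                    ar_sd_c=0.0, gaps=(("2000-06-01", "2000-06-30"),)
                )
            },
        )
        series = generate_temperature_series(cfg)["lagoon"]
        assert not series["timestamp"].dt.month.eq(6).any()


class TestWaves:
    def test_no_storms_means_constant_base_height(self):
        cfg = small_config(wave_params=WaveParams(storm_rate=0.0, base_hsig_m=1.3))
        waves = generate_wave_series(cfg)
        assert (waves["hsig_m"] == 1.3).all()

    def test_storm_flux_ratio_follows_height_squared(self):
        """A season whose records are all storm-multiplied carries m^2
        times the flux of a calm season (period unchanged)."""
        m = 2.5
        cfg = small_config(
            years=(2000, 2001),
            wave_params=WaveParams(storm_rate=0.0, base_hsig_m=1.0, base_tw_s=10.0),
        )
        waves = generate_wave_series(cfg)
        season0 = (waves["timestamp"] >= "2000-09-01") & (
            waves["timestamp"] <= "2000-12-31 23:59"
        )
        storm = waves.copy()
        storm.loc[season0, "hsig_m"] *= m
        flux = wave_energy_flux(storm)
        agg = seasonal_flux(flux, season=((9, 1), (12, 31)), mode="sum")
        s = agg.set_index("season")["flux_sum_kw_m"]
        assert s[2000] / s[2001] == pytest.approx(m**2, rel=1e-9)

    def test_year_long_gap_flags_season_not_estimated(self):
        cfg = small_config(
            years=(2000, 2002),
            wave_params=WaveParams(
                storm_rate=0.0, gaps=(("2001-01-01", "2001-12-31"),)
            ),
        )
        flux = wave_energy_flux(generate_wave_series(cfg))
        agg = seasonal_flux(flux, season=((9, 1), (12, 31)), mode="mean")
        flags = agg.set_index("season")["estimated"]
        assert not flags[2001]
        assert flags[2000] and flags[2002]

    def test_wave_determinism(self):
        cfg = small_config(wave_params=WaveParams(storm_rate=2.0), seed=3)
        assert generate_wave_series(cfg).equals(generate_wave_series(cfg))
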