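"""Tests of the synthetic platform-scene generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from phenotherm.synthetic_scene import (
    GenotypeParams,
    SceneConfig,
    distance_factor,
    environment_at,
    generate_environment,
    render_spectrum,
    render_thermal_frame,
    saturation_vapor_pressure,
    simulate_experiment,
    simulate_plant_day,
    soil_water_response,
    stomatal_conductance,
    vpd_from_t_rh,
)
from phenotherm.thermography import extract_plant_temperature, raw_to_temperature


class TestVPD:
    @pytest.mark.parametrize(
        "t_a,rh,expected",
        [
            (25.0, 100.0, 0.0),  # saturation
            (0.0, 0.0, 0.61078),  # e_s at 0 degC is the Tetens coefficient
        ],
    )
    def test_anchor_values(self, t_a, rh, expected):
        assert vpd_from_t_rh(t_a, rh) == pytest.approx(expected, abs=1e-12)

    def test_half_saturation_matches_direct_tetens(self):
        expected = 0.5 * 0.61078 * np.exp(17.27 * 25.0 / (25.0 + 237.3))
        assert vpd_from_t_rh(25.0, 50.0) == pytest.approx(expected, rel=1e-12)

    def test_rh_domain_error(self):
        with pytest.raises(ValueError):
            vpd_from_t_rh(25.0, 120.0)
        with pytest.raises(ValueError):
            vpd_from_t_rh(25.0, -1.0)


class TestEnvironment:
    def test_midnight_air_temperature_is_night_setpoint(self):
        cfg = SceneConfig()
        state = environment_at(cfg, 0.0, "gz")
        assert state["T_a"] == pytest.approx(22.0, abs=1e-9)
        assert state["VPD"] == pytest.approx(1.5, abs=1e-9)
        assert state["PAR"] == 0.0

    def test_daytime_par_plateau_near_280(self):
        cfg = SceneConfig()
        env = generate_environment(cfg, 3)
        gz = env[env["position"] == "gz"]
        hours = pd.to_datetime(gz["timestamp"]).dt.hour
        day = gz[(hours >= 7) & (hours < 21)]
        assert day["PAR"].mean() == pytest.approx(280.0, abs=10.0)

    def test_zero_noise_series_is_periodic(self):
        cfg = SceneConfig()
        cfg.env.t_noise_sd = 0.0
        cfg.env.vpd_noise_sd = 0.0
        cfg.env.par_noise_sd = 0.0
        env = generate_environment(cfg, 2, rng=None)
        gz = env[env["position"] == "gz"]["T_a"].to_numpy()
        n = len(gz) // 2
        np.testing.assert_allclose(gz[:n], gz[n:], atol=1e-12)

    def test_position_offsets_ordered_out_in_gz(self):
        env = generate_environment(SceneConfig(), 2)
        means = env.groupby("position")["T_a"].mean()
        assert means["out"] >= means["in"] >= means["gz"]
        vpd = env.groupby("position")["VPD"].mean()
        assert vpd["out"] >= vpd["in"] >= vpd["gz"]

    def test_vpd_consistent_with_t_rh(self):
        env = generate_environment(SceneConfig(), 1)
        recomputed = vpd_from_t_rh(env["T_a"].to_numpy(), env["RH"].to_numpy())
        np.testing.assert_allclose(env["VPD"].to_numpy(), recomputed, atol=1e-9)

    def test_seeded_determinism(self):
        a = generate_environment(SceneConfig(random_seed=3), 2)
        b = generate_environment(SceneConfig(random_seed=3), 2)
        pd.testing.assert_frame_equal(a, b)


class TestPlantModel:
    def test_soil_water_response_normalised_at_ww(self):
        g = GenotypeParams()
        assert soil_water_response(g, 2.4) == pytest.approx(1.0, abs=1e-12)
        assert soil_water_response(g, 1.4) < 0.5

    def test_night_conductance_is_nocturnal_floor(self):
        g = GenotypeParams(g_night=0.015)
        assert stomatal_conductance(g, 2.4, 1.5, 0.0) == pytest.approx(0.015)

    def test_zero_floor_gives_zero_transpiration_at_night(self):
        g = GenotypeParams(g_night=0.0)
        assert stomatal_conductance(g, 2.4, 2.0, 0.0) == 0.0

    def test_drought_reduces_transpiration_same_environment(self):
        cfg = SceneConfig()
        env_day = {p: environment_at(cfg, 10.0, p) for p in ("gz", "in", "out")}
        ww = simulate_plant_day(GenotypeParams(), 2.4, env_day, cfg)
        wd = simulate_plant_day(GenotypeParams(), 1.4, env_day, cfg)
        assert wd.E_true < ww.E_true
        assert wd.T_p_true > ww.T_p_true  # warmer when transpiring less
        assert wd.psi_true < ww.psi_true

    def test_e_monotone_in_gs_and_tp_monotone_in_e(self):
        cfg = SceneConfig()
        env_day = {p: environment_at(cfg, 11.0, p) for p in ("gz", "in", "out")}
        g_maxes = [0.1, 0.2, 0.3, 0.4]
        truths = [
            simulate_plant_day(GenotypeParams(), 2.4, env_day, cfg, g_max=g)
            for g in g_maxes
        ]
        e_vals = [t.E_true for t in truths]
        t_vals = [t.T_p_true for t in truths]
        assert e_vals == sorted(e_vals)
        assert t_vals == sorted(t_vals, reverse=True)

    def test_soil_water_domain(self):
        cfg = SceneConfig()
        env_day = {p: environment_at(cfg, 10.0, p) for p in ("gz", "in", "out")}
        with pytest.raises(ValueError):
            simulate_plant_day(GenotypeParams(), 0.2, env_day, cfg)


class TestThermalRendering:
    def test_zero_noise_round_trip_recovers_plant_temperature(self, small_config):
        cfg = dataclasses.replace(small_config, thermal_dn_sd=0.0, texture_sd=0.0)
        frame, mask = render_thermal_frame(24.5, 27.0, {"T_a": 25.0, "RH": 40.0}, cfg)
        T = raw_to_temperature(frame)
        res = extract_plant_temperature(T, mask, cfg.plate_region)
        assert res["T_p"] == pytest.approx(24.5, abs=0.01)
        assert res["T_dry"] == pytest.approx(27.0, abs=0.01)

    def test_mask_pixel_count_equals_silhouette_area(self, small_config):
        frame, mask = render_thermal_frame(24.5, 27.0, {"T_a": 25.0, "RH": 40.0}, small_config)
        nrow, ncol = small_config.frame_shape
        rr, cc = np.mgrid[0:nrow, 0:ncol]
        expected = (
            (rr - nrow / 2.0) ** 2 + (cc - ncol / 2.0) ** 2 <= small_config.plant_radius_px**2
        ).sum()
        assert mask.sum() == expected

    def test_drift_offset_appears_in_imaged_plate(self, small_config):
        cfg = dataclasses.replace(small_config, thermal_dn_sd=0.0, texture_sd=0.0)
        frame, _ = render_thermal_frame(
            24.5, 27.0, {"T_a": 25.0, "RH": 40.0}, cfg, drift_offset=2.0
        )
        T = raw_to_temperature(frame)
        r0, r1, c0, c1 = cfg.plate_region
        imaged = np.median(T[r0:r1, c0:c1])
        assert imaged - frame.plate_thermocouple_T == pytest.approx(2.0, abs=0.05)

    def test_overlapping_reference_regions_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(plate_region=(20, 60, 20, 100), foil_region=(30, 70, 50, 150))


class TestSpectra:
    def test_distance_factor_is_one_at_reference(self):
        assert distance_factor(1.2) == pytest.approx(1.0, abs=1e-15)

    def test_distance_factor_monotone_decreasing(self):
        d = np.linspace(1.2, 3.0, 30)
        h = distance_factor(d)
        assert np.all(np.diff(h) < 0)
        assert np.all(h > 0)

    def test_water_trough_deepens_with_leaf_water(self):
        wl, wet = render_spectrum(0.9, 1.0, 1.2)
        _, dry = render_spectrum(0.5, 1.0, 1.2)
        band = np.argmin(np.abs(wl - 1450.0))
        assert wet[band] < dry[band]

    def test_zero_noise_spectra_bit_identical(self):
        _, a = render_spectrum(0.8, 1.0, 2.0)
        _, b = render_spectrum(0.8, 1.0, 2.0)
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            render_spectrum(0.8, 1.0, 0.0)


class TestExperiment:
    def test_designed_drought_contrast_every_day_after_onset(self):
        """At matched environment the WD plant transpires strictly less on
        every day after drought onset (the soil-water ramp is monotone)."""
        cfg = SceneConfig()
        env_day = {p: environment_at(cfg, 10.0, p) for p in ("gz", "in", "out")}
        from phenotherm.synthetic_scene import soil_water_trajectory

        for day in range(1, cfg.n_days):
            ww = simulate_plant_day(
                GenotypeParams(), soil_water_trajectory(cfg, "WW", day), env_day, cfg
            )
            wd = simulate_plant_day(
                GenotypeParams(), soil_water_trajectory(cfg, "WD", day), env_day, cfg
            )
            assert wd.E_true < ww.E_true

    def test_sampled_experiment_shows_contrast_after_ramp(self, small_config):
        truth = simulate_experiment(small_config)["truth"]
        daily = truth.groupby(["treatment", "day_after_V5"])["E_true"].mean().unstack(0)
        after = daily.index >= small_config.wd_ramp_days // 2
        assert (daily.loc[after, "WD"] < daily.loc[after, "WW"]).all()

    def test_experiment_is_seed_deterministic(self, small_config):
        a = simulate_experiment(small_config)["truth"]
        b = simulate_experiment(small_config)["truth"]
        pd.testing.assert_frame_equal(a, b)

    def test_end_to_end_truth_consistency_zero_noise(self, small_config):
        """Rendering a frame from truth and processing it recovers T_p_true."""
        cfg = dataclasses.replace(small_config, thermal_dn_sd=0.0, texture_sd=0.0, n_days=2)
        truth = simulate_experiment(cfg)["truth"].head(5)
        for _, row in truth.iterrows():
            frame, mask = render_thermal_frame(
                row["T_p_true"], row["T_dry_true"], {"T_a": row["T_a_in"], "RH": row["RH_in"]}, cfg
            )
            res = extract_plant_temperature(raw_to_temperature(frame), mask, cfg.plate_region)
            assert abs(res["T_p"] - row["T_p_true"]) < 0.02
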