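import numpy as np
import pytest

from landclim import synth
from landclim import transitions as tr
from landclim.attribution import (
    RegressionSpec,
    bootstrap_attribution,
    fit_once,
    make_blocks,
    split_blocks,
)
from landclim.energy_balance import balance_residual
from landclim.io import state_from_dataset
from landclim.pft import DEFAULT_SCHEMA


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            synth.SyntheticConfig(fine_grid_shape=(0, 10))
        with pytest.raises(ValueError):
            synth.SyntheticConfig(coarsen_factor=7)  # does not divide 120
        with pytest.raises(ValueError):
            synth.SyntheticConfig(ar1_coefficient=1.0)
        with pytest.raises(ValueError):
            synth.SyntheticConfig(noise_sd_space=-0.1)

    def test_coarse_shape(self):
        cfg = synth.SyntheticConfig(fine_grid_shape=(30, 60), coarsen_factor=3)
        assert cfg.coarse_grid_shape == (10, 20)


class TestLandSystems:
    def test_no_change_case(self):
        cfg = synth.SyntheticConfig(
            fine_grid_shape=(30, 30), coarsen_factor=3, scenario_change_fraction=0.0
        )
        land = synth.generate_land_systems(cfg)
        np.testing.assert_array_equal(land.reference_map, land.scenario_map)

    def test_change_count_matches_cellwise_comparison(self):
        cfg = synth.SyntheticConfig(
            fine_grid_shape=(100, 100), coarsen_factor=2, scenario_change_fraction=0.3, seed=5
        )
        land = synth.generate_land_systems(cfg)
        n_diff = int((land.reference_map != land.scenario_map).sum())
        # Bernoulli(0.3) per cell: stay within 5 sigma of 3000
        sd = np.sqrt(10000 * 0.3 * 0.7)
        assert abs(n_diff - 3000) < 5 * sd

    def test_crosswalk_referential_integrity(self, small_config):
        land = synth.generate_land_systems(small_config)
        for code in np.unique(np.stack([land.reference_map, land.scenario_map])):
            assert int(code) in land.crosswalk
            assert len(land.crosswalk[int(code)]) >= 1
        for habs in land.crosswalk.values():
            for h in habs:
                assert h in land.suitability
                s = land.suitability[h]
                assert np.all(np.isfinite(s)) and np.all(s >= 0)

    def test_deterministic_under_seed(self, small_config):
        a = synth.generate_land_systems(small_config)
        b = synth.generate_land_systems(small_config)
        np.testing.assert_array_equal(a.reference_map, b.reference_map)
        np.testing.assert_array_equal(a.scenario_map, b.scenario_map)
        assert a.crosswalk == b.crosswalk


class TestPlots:
    def test_every_habitat_represented(self, small_config):
        plots, species_to_pft = synth.generate_plot_table(small_config)
        assert set(plots["habitat"]) == set(range(small_config.n_habitats))
        assert np.all(plots["cover"] > 0)

    def test_species_map_to_vegetated_slots(self, small_config):
        _, species_to_pft = synth.generate_plot_table(small_config)
        bare = DEFAULT_SCHEMA.names[DEFAULT_SCHEMA.bare_index]
        assert bare not in set(species_to_pft["pft"])
        assert set(species_to_pft["pft"]) <= set(DEFAULT_SCHEMA.names)
        assert species_to_pft["species"].is_unique

    def test_tables_deterministic(self, small_config):
        p1, s1 = synth.generate_plot_table(small_config)
        p2, s2 = synth.generate_plot_table(small_config)
        assert p1.equals(p2) and s1.equals(s2)


class TestClimateFields:
    def test_energy_balance_closes_everywhere(self, small_world):
        for key in ("ds_ref", "ds_scen"):
            state = state_from_dataset(small_world[key])
            assert np.abs(balance_residual(state)).max() < 1e-9

    def test_mean_delta_ts_equals_planted_model(self, small_world):
        delta = (
            small_world["ds_scen"]["ts"] - small_world["ds_ref"]["ts"]
        ).mean("year").values
        np.testing.assert_allclose(
            delta, small_world["truth"].delta_ts_target, atol=1e-10
        )

    def test_null_response_without_sensitivities(self):
        cfg = synth.SyntheticConfig(
            fine_grid_shape=(24, 24),
            coarsen_factor=3,
            n_years=3,
            n_days_per_year=10,
            true_sensitivities={k: 0.0 for k in synth._default_sensitivities()},
            nonlocal_offset=0.0,
            noise_sd_space=0.0,
        )
        grid_ref, grid_scen, _, _ = synth.generate_pft_grids(cfg)
        truth = synth.make_truth(cfg)
        ds_ref, ds_scen = synth.generate_climate_fields(cfg, grid_ref, grid_scen, truth)
        np.testing.assert_allclose(
            ds_scen["ts"].mean("year").values,
            ds_ref["ts"].mean("year").values,
            atol=1e-12,
        )

    def test_missing_sensitivity_names_transition(self, small_config, small_world):
        cfg = small_config
        truth = synth.SyntheticTruth(
            true_sensitivities={}, realized_offset=0.0, noise=np.zeros(cfg.coarse_grid_shape)
        )
        with pytest.raises(KeyError, match="no configured sensitivity"):
            synth.generate_climate_fields(
                cfg, small_world["grid_ref"], small_world["grid_scen"], truth
            )

    def test_datasets_deterministic(self, small_config, small_world):
        grid_ref, grid_scen = small_world["grid_ref"], small_world["grid_scen"]
        truth = synth.make_truth(small_config)
        ds_ref, _ = synth.generate_climate_fields(small_config, grid_ref, grid_scen, truth)
        np.testing.assert_array_equal(
            ds_ref["t2m_daily_max"].values,
            small_world["ds_ref"]["t2m_daily_max"].values,
        )

    def test_txx_diff_tracks_planted_response(self, small_world):
        """Shared daily excursions make the TXx response equal Δt2m."""
        from landclim.stats import txx

        d = txx(small_world["ds_scen"]["t2m_daily_max"].values) - txx(
            small_world["ds_ref"]["t2m_daily_max"].values
        )
        expected = small_world["truth"].delta_ts_target
        np.testing.assert_allclose(d.mean(axis=0), expected, atol=1e-4)


class TestRecentClimate:
    def test_offset_and_independent_anomalies(self, small_config, small_world):
        ds_recent = synth.generate_recent_climate(small_config, small_world["ds_ref"])
        ref_mean = small_world["ds_ref"]["ts"].mean("year").values
        delta = ref_mean - ds_recent["ts"].mean("year").values
        # background warming is uniform; interannual noise shifts it jointly
        assert np.ptp(delta) < 1e-9
        ref_anom = small_world["ds_ref"]["ts"].values.mean(axis=(1, 2))
        rec_anom = ds_recent["ts"].values.mean(axis=(1, 2))
        assert not np.allclose(ref_anom - ref_anom.mean(), rec_anom - rec_anom.mean())


class TestAr1:
    def test_sample_autocorrelation_near_configured(self):
        rng = np.random.default_rng(42)
        a = synth.ar1_series(400, 0.45, 0.4, rng)
        r = np.corrcoef(a[:-1], a[1:])[0, 1]
        assert abs(r - 0.45) < 0.1
        assert a.std() == pytest.approx(0.4, abs=0.1)

    def test_zero_sd_is_flat(self):
        a = synth.ar1_series(50, 0.9, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(a, 0.0)


class TestRecovery:
    def test_noiseless_unpenalised_regression_recovers_truth(self):
        """With zero noise and offset, penalty→0 recovers β to <1% relative."""
        cfg = synth.SyntheticConfig(
            fine_grid_shape=(48, 48),
            coarsen_factor=3,
            n_years=2,
            n_days_per_year=5,
            nonlocal_offset=0.0,
            noise_sd_space=0.0,
            seed=21,
        )
        grid_ref, grid_scen, _, _ = synth.generate_pft_grids(cfg)
        truth = synth.make_truth(cfg)
        ds_ref, ds_scen = synth.generate_climate_fields(cfg, grid_ref, grid_scen, truth)
        cat_ref = tr.aggregate_categories(grid_ref)
        cat_scen = tr.aggregate_categories(grid_scen)
        oriented = tr.orient_by_dominant_direction(
            tr.greedy_net_transitions(cat_ref, cat_scen)
        )
        y = (ds_scen["ts"] - ds_ref["ts"]).mean("year").values.ravel()
        spec = RegressionSpec(penalties=np.array([1e-10]), block_size=4)
        blocks = make_blocks(cfg.coarse_grid_shape, spec.block_size)
        train_idx, test_idx, groups = split_blocks(
            blocks, spec.train_fraction, np.random.default_rng(3)
        )
        fit = fit_once(y, oriented.design_matrix(), spec, train_idx, test_idx, groups, np.random.default_rng(3))
        expected = truth.expected_coefficients(oriented)
        np.testing.assert_allclose(fit.coef, expected, rtol=0.01)
        assert fit.mae < 1e-6  # the noiseless model predicts held-out blocks exactly


class TestAttributionFixture:
    def test_exactly_five_active_types(self):
        fix = synth.make_attribution_fixture(seed=0)
        assert fix.X.shape[1] == 5
        assert len(fix.names) == 5

    def test_greedy_recovers_planted_design(self):
        """The design reconstructs the planted response exactly (noise 0)."""
        fix = synth.make_attribution_fixture(seed=1, noise_sd=0.0, intercept=0.3)
        np.testing.assert_allclose(
            fix.y, fix.X @ fix.true_beta + 0.3, atol=1e-12
        )

    def test_signed_design_has_both_directions(self):
        fix = synth.make_attribution_fixture(seed=2)
        assert np.all(fix.X.min(axis=0) < 0)
        assert np.all(fix.X.max(axis=0) > 0)


class TestSubstreams:
    def test_named_substreams_are_independent_and_stable(self):
        a = synth.substream(1, "alpha").random(3)
        b = synth.substream(1, "beta").random(3)
        assert not np.allclose(a, b)
        np.testing.assert_array_equal(a, synth.substream(1, "alpha").random(3))
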