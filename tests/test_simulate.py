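import numpy as np
import pytest
from shapely.geometry import Point

from foxrange.errors import ConfigurationError, DomainError
from foxrange.homerange import mcp
from foxrange.landscape import mean_elevation_zonal
from foxrange.simulate import (
    GeneratorConfig,
    build_landscape,
    default_zone_design,
    derive_position_sd,
    generate_study,
    place_foxes,
    sample_fox_covariates,
    simulate_trajectory,
)


def single_fox_config(seed, zone="BN", **kw):
    alloc = {"BN": 0, "SB": 0, "NB": 0}
    alloc[zone] = 1
    return GeneratorConfig(
        seed=seed, n_foxes=1, n_males=kw.pop("n_males", 0), zone_allocation=alloc, **kw
    )


class TestConfigValidation:
    def test_allocation_must_sum_to_n_foxes(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(zone_allocation={"BN": 10, "SB": 10, "NB": 10})

    def test_fix_rate_choices(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(fix_rate=4)

    def test_r2_bounds(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(r2_target=0.0)


class TestSampleFoxCovariates:
    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_default_design_counts(self, seed):
        truth = sample_fox_covariates(GeneratorConfig(seed=seed))
        assert len(truth) == 52
        assert (truth["sex"] == "M").sum() == 33
        assert truth["zone"].value_counts().to_dict() == {"BN": 30, "SB": 14, "NB": 8}

    def test_zero_noise_limit_is_exact_linear_predictor(self):
        cfg = GeneratorConfig(seed=2, r2_target=1.0)
        truth = sample_fox_covariates(cfg)
        b = cfg.betas
        xb = (
            b.intercept
            + b.elevation * truth["elevation_m"]
            + b.agriculture * truth["prop_agriculture"]
            + b.sex_male * truth["sex_code"]
        )
        assert np.allclose(truth["true_log_area"], xb)

    def test_bn_elevation_monte_carlo_mean(self):
        # 10,000 draws from the configured truncated Normal(54, 22)
        cfg = GeneratorConfig(
            seed=3,
            n_foxes=10_000,
            n_males=5_000,
            zone_allocation={"BN": 10_000, "SB": 0, "NB": 0},
        )
        truth = sample_fox_covariates(cfg)
        assert truth["elevation_m"].mean() == pytest.approx(54.0, abs=1.0)

    def test_proportions_in_unit_interval(self):
        truth = sample_fox_covariates(GeneratorConfig(seed=9))
        for col in ("prop_agriculture", "prop_settlement"):
            assert truth[col].between(0, 1).all()
        assert (truth["prop_agriculture"] + truth["prop_settlement"] <= 0.95 + 1e-12).all()

    def test_latitude_elevation_correlation_matches_field_pattern(self):
        rs = [
            np.corrcoef(
                t["latitude"], t["elevation_m"]
            )[0, 1]
            for t in (
                sample_fox_covariates(GeneratorConfig(seed=s)) for s in (11, 12, 13)
            )
        ]
        assert np.mean(rs) == pytest.approx(0.89, abs=0.05)


class TestDerivePositionSd:
    def test_closed_form_chi2_quantile(self):
        # chi-square(2) 0.90-quantile is 4.60517: A = pi * 4.60517 km^2 -> 1000 m
        assert derive_position_sd(np.pi * 4.60517, 0.90) == pytest.approx(1000.0, rel=1e-4)

    def test_one_square_km(self):
        assert derive_position_sd(1.0, 0.90) == pytest.approx(263.0, abs=0.5)

    def test_zero_area_limit(self):
        assert derive_position_sd(0.0, 0.90) == 0.0

    def test_negative_area_rejected(self):
        with pytest.raises(DomainError):
            derive_position_sd(-1.0, 0.90)


class TestSimulateTrajectory:
    def test_zero_sd_collapses_to_centre(self):
        cfg = single_fox_config(5)
        truth = place_foxes(sample_fox_covariates(cfg))
        row = truth.iloc[0].copy()
        row["ou_position_sd_m"] = 0.0
        traj = simulate_trajectory(row, cfg)
        assert np.allclose(traj.xy, traj.xy[0])
        assert mcp(traj.xy, 1.0).area_km2 == 0.0

    def test_fix_count_and_schedule(self):
        cfg = single_fox_config(6)
        truth = place_foxes(sample_fox_covariates(cfg))
        row = truth.iloc[0].copy()
        row["duration_days"] = 180
        traj = simulate_trajectory(row, cfg)
        assert traj.n_fixes == 540
        assert traj.fixes["timestamp"].is_monotonic_increasing

    def test_ou_stationary_sd_recovered(self):
        """Over 50 replicate residents the track scatter matches the
        configured OU stationary sd within 10%."""
        cfg = single_fox_config(8)
        truth = place_foxes(sample_fox_covariates(cfg))
        row = truth.iloc[0].copy()
        row["duration_days"] = 180
        sd_target = float(row["ou_position_sd_m"])
        rng = np.random.default_rng(99)
        ratios = []
        for _ in range(50):
            traj = simulate_trajectory(row, cfg, rng=rng)
            xy = traj.xy - [row["centre_x"], row["centre_y"]]
            ratios.append(xy.std(axis=0).mean() / sd_target)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_disperser_nsd_exceeds_threshold(self):
        cfg = single_fox_config(10)
        truth = place_foxes(sample_fox_covariates(cfg))
        row = truth.iloc[0].copy()
        row["movement_class"] = "disperser"
        traj = simulate_trajectory(row, cfg)
        d = traj.xy - traj.xy[0]
        nsd_max = (d**2).sum(axis=1).max()
        assert nsd_max > 25.0 * float(row["ou_position_sd_m"]) ** 2

    def test_duration_under_one_day_rejected(self):
        cfg = single_fox_config(11)
        truth = place_foxes(sample_fox_covariates(cfg))
        row = truth.iloc[0].copy()
        row["duration_days"] = 0
        with pytest.raises(ConfigurationError):
            simulate_trajectory(row, cfg)


@pytest.fixture(scope="module")
def small_study():
    cfg = GeneratorConfig(
        seed=21, n_foxes=6, n_males=3, zone_allocation={"BN": 3, "SB": 2, "NB": 1}
    )
    truth = place_foxes(sample_fox_covariates(cfg))
    return truth, build_landscape(truth)


class TestBuildLandscape:

    def test_zero_agriculture_fox_has_clean_neighbourhood(self):
        cfg = single_fox_config(31, zone="NB")
        truth = place_foxes(sample_fox_covariates(cfg))
        truth.loc[:, "prop_agriculture"] = 0.0
        layers = build_landscape(truth)
        row = truth.iloc[0]
        disc = Point(row["centre_x"], row["centre_y"]).buffer(3 * row["ou_position_sd_m"])
        assert not any(g.intersects(disc) for g in layers.class_polygons["agriculture"])

    def test_local_proportion_matches_draw(self, small_study):
        truth, layers = small_study
        from foxrange.landscape import proportion_in_class

        for row in truth.itertuples():
            disc = Point(row.centre_x, row.centre_y).buffer(2.0 * row.ou_position_sd_m)
            got = proportion_in_class(disc, layers, "agriculture")
            assert got == pytest.approx(row.prop_agriculture, abs=0.06)

    def test_local_elevation_matches_draw(self, small_study):
        truth, layers = small_study
        for row in truth.itertuples():
            disc = Point(row.centre_x, row.centre_y).buffer(2.0 * row.ou_position_sd_m)
            got = mean_elevation_zonal(disc, layers.elevation)
            assert got == pytest.approx(row.elevation_m, abs=6.0)

    def test_zone_bands_tile_and_contain_centres(self, small_study):
        truth, layers = small_study
        from foxrange.landscape import assign_zone

        for row in truth.itertuples():
            got = assign_zone(Point(row.centre_x, row.centre_y), layers.zone_polygons)
            assert got == row.zone

    def test_overlapping_classes_rejected(self):
        cfg = single_fox_config(32)
        truth = place_foxes(sample_fox_covariates(cfg))
        truth.loc[:, "prop_agriculture"] = 0.7
        truth.loc[:, "prop_settlement"] = 0.5
        with pytest.raises(ConfigurationError):
            build_landscape(truth)


class TestDeterminism:
    def test_same_seed_reproduces_study_byte_for_byte(self):
        cfg = GeneratorConfig(
            seed=40, n_foxes=4, n_males=2, zone_allocation={"BN": 2, "SB": 1, "NB": 1}
        )
        s1 = generate_study(cfg, with_landscape=False)
        s2 = generate_study(cfg, with_landscape=False)
        assert s1.truth.to_csv() == s2.truth.to_csv()
        for a, b in zip(s1.trajectories, s2.trajectories):
            assert a.fixes.to_csv() == b.fixes.to_csv()

    def test_different_seeds_differ(self):
        c1 = GeneratorConfig(seed=41)
        c2 = GeneratorConfig(seed=42)
        t1 = sample_fox_covariates(c1)
        t2 = sample_fox_covariates(c2)
        assert not np.allclose(t1["true_log_area"], t2["true_log_area"])

    def test_timestamps_strictly_increasing_everywhere(self):
        study = generate_study(
            GeneratorConfig(
                seed=43, n_foxes=3, n_males=1, zone_allocation={"BN": 1, "SB": 1, "NB": 1}
            ),
            with_landscape=False,
        )
        for traj in study.trajectories:
            dt = traj.fixes["timestamp"].diff().dropna()
            assert (dt > pd_zero()).all()


def pd_zero():
    import pandas as pd

    return pd.Timedelta(0)
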