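"""Tests of the synthetic study generator: determinism, degenerate
parameter limits, calibration of the latent surface, and planted
covariate associations."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy.special import expit

import vapegeo as vg


class TestGeography:
    def test_reference_design_shape(self):
        geo = vg.generate_geography(293, 10, seed=1)
        assert geo["division_id"].nunique() == 293
        assert geo["province_id"].nunique() == 10
        assert np.isfinite(geo[["x", "y"]]).all().all()

    def test_minimal_two_divisions_one_province(self):
        geo = vg.generate_geography(2, 1, seed=7)
        assert len(geo) == 2
        assert set(geo["province_id"]) == {"P01"}

    def test_provinces_are_contiguous_blocks(self):
        geo = vg.generate_geography(100, 5, seed=3)
        # provinces partition the x axis into strips: ranges do not overlap
        bounds = geo.groupby("province_id")["x"].agg(["min", "max"]).sort_values("min")
        assert (bounds["min"].to_numpy()[1:] >= bounds["max"].to_numpy()[:-1]).all()

    def test_determinism(self):
        assert_frame_equal(
            vg.generate_geography(50, 4, seed=9), vg.generate_geography(50, 4, seed=9)
        )

    def test_too_few_divisions_rejected(self):
        with pytest.raises(ValueError):
            vg.generate_geography(1, 1, seed=0)


class TestTruth:
    def test_zero_variance_gives_flat_surface(self):
        cfg = vg.ScenarioConfig(n_divisions=40, n_provinces=2, sigma_u_true=0.0, seed=2)
        geo = vg.generate_geography(40, 2, cfg.seed)
        truth = vg.generate_truth(geo, cfg)
        assert (truth["u_true"] == 0).all()
        assert np.allclose(truth["p_true_ends"], expit(cfg.beta0_ends))

    def test_spatial_field_is_clustered(self):
        """Correlated field: Moran's i of u over 3-NN positive on average."""
        vals = []
        for seed in range(100):
            cfg = vg.ScenarioConfig(
                n_divisions=200, n_provinces=5, sigma_u_true=0.5,
                spatial_range=0.15, seed=seed,
            )
            geo = vg.generate_geography(200, 5, seed)
            truth = vg.generate_truth(geo, cfg)
            w = vg.knn_weights(geo, 3)
            vals.append(vg.morans_i(w.align(truth, "u_true"), w))
        assert np.mean(vals) > 0.2

    def test_iid_field_not_clustered(self):
        """spatial_range=0: permutation test non-significant in >=90% of seeds."""
        hits = 0
        for seed in range(50):
            cfg = vg.ScenarioConfig(
                n_divisions=100, n_provinces=4, spatial_range=0.0, seed=seed
            )
            geo = vg.generate_geography(100, 4, seed)
            truth = vg.generate_truth(geo, cfg)
            w = vg.knn_weights(geo, 3)
            r = vg.mc_permutation_test(
                w.align(truth, "u_true"), w, n_sims=199, seed=seed
            )
            hits += r.p_value > 0.05
        assert hits >= 45

    def test_median_true_prevalence_near_four_percent(self):
        meds = []
        for seed in range(100):
            cfg = vg.ScenarioConfig(n_divisions=100, n_provinces=4, seed=seed)
            geo = vg.generate_geography(100, 4, seed)
            meds.append(vg.generate_truth(geo, cfg)["p_true_ends"].median())
        assert 0.02 < np.median(meds) < 0.08


class TestRespondents:
    def test_full_determinism_under_seed(self):
        cfg = vg.ScenarioConfig(n_divisions=30, n_provinces=3, seed=21)
        assert_frame_equal(
            vg.simulate_scenario(cfg).respondents, vg.simulate_scenario(cfg).respondents
        )

    def test_division_size_median_matches_design(self):
        meds = []
        for seed in range(50):
            cfg = vg.ScenarioConfig(seed=seed)
            geo = vg.generate_geography(cfg.n_divisions, cfg.n_provinces, seed)
            truth = vg.generate_truth(geo, cfg)
            resp = vg.generate_respondents(truth, geo, cfg)
            meds.append(resp.groupby("division_id").size().median())
        assert 250 <= np.median(meds) <= 360

    def test_symmetric_bernoulli_limit(self):
        """All effects zero and beta0=0: pooled outcome proportion ~ 0.5."""
        cfg = vg.ScenarioConfig(
            n_divisions=30, n_provinces=2, median_respondents=300,
            beta0_ends=0.0, beta_age=(0.0, 0.0, 0.0), beta_sex=0.0,
            source_offsets=(0.0,) * 12, sigma_u_true=0.0, seed=4,
        )
        world = vg.simulate_scenario(cfg)
        assert abs(world.respondents["y_ends"].mean() - 0.5) < 0.02

    def test_large_division_recovers_true_prevalence(self):
        """Binomial oracle: empirical rate within 3 MC sd of p_true."""
        cfg = vg.ScenarioConfig(
            n_divisions=2, n_provinces=1, median_respondents=20000,
            size_dispersion=0.0, beta_age=(0.0, 0.0, 0.0), beta_sex=0.0,
            source_offsets=(0.0,) * 12, seed=12,
        )
        world = vg.simulate_scenario(cfg)
        obs = world.respondents.groupby("division_id")["y_ends"].agg(["mean", "size"])
        for div, row in obs.iterrows():
            p = world.truth.set_index("division_id").at[div, "p_true_ends"]
            assert abs(row["mean"] - p) < 3 * np.sqrt(p * (1 - p) / row["size"])

    def test_binomial_variance_bound_at_zero_sigma(self):
        """sigma_u=0: between-division variance is binomial noise only."""
        cfg = vg.ScenarioConfig(
            n_divisions=100, n_provinces=4, median_respondents=300,
            size_dispersion=0.0, sigma_u_true=0.0,
            beta_age=(0.0, 0.0, 0.0), beta_sex=0.0, source_offsets=(0.0,) * 12,
            seed=5,
        )
        world = vg.simulate_scenario(cfg)
        rates = world.respondents.groupby("division_id")["y_ends"].agg(["mean", "size"])
        p = world.respondents["y_ends"].mean()
        binom_var = (p * (1 - p) / rates["size"]).mean()
        assert rates["mean"].var() < 3 * binom_var

    def test_weights_positive_and_mean_one(self):
        cfg = vg.ScenarioConfig(n_divisions=30, n_provinces=2, seed=8)
        w = vg.simulate_scenario(cfg).respondents["weight"]
        assert (w > 0).all()
        assert abs(w.mean() - 1.0) < 0.05


class TestCovariates:
    def test_planted_ice_association_recovered(self):
        hits = 0
        for seed in range(100):
            cfg = vg.ScenarioConfig(seed=seed)  # defaults plant ice > 0
            geo = vg.generate_geography(cfg.n_divisions, cfg.n_provinces, seed)
            truth = vg.generate_truth(geo, cfg)
            cov = vg.generate_covariates(truth, cfg)
            hits += np.corrcoef(cov["ice"], truth["u_true"])[0, 1] > 0
        assert hits >= 95

    def test_null_covariates_uncorrelated(self):
        hits = 0
        for seed in range(100):
            cfg = vg.ScenarioConfig(seed=seed, covariate_effects={})
            geo = vg.generate_geography(cfg.n_divisions, cfg.n_provinces, seed)
            truth = vg.generate_truth(geo, cfg)
            cov = vg.generate_covariates(truth, cfg)
            r = np.corrcoef(cov["ice"], truth["u_true"])[0, 1]
            hits += abs(r) < 0.2
        assert hits >= 90

    def test_ranges_respected(self):
        cfg = vg.ScenarioConfig(
            n_divisions=200, n_provinces=5, seed=3,
            covariate_effects={"ice": 5.0},  # large effect to force clipping
        )
        geo = vg.generate_geography(200, 5, 3)
        truth = vg.generate_truth(geo, cfg)
        cov = vg.generate_covariates(truth, cfg)
        assert cov["ice"].between(-1, 1).all()
        for c in ("pct_visible_minority", "pct_degree", "pct_low_income", "unemployment"):
            assert cov[c].between(0, 100).all()
        assert (cov["median_income"] > 0).all()

    def test_unknown_covariate_rejected(self):
        with pytest.raises(vg.synthetic.InvalidScenarioError):
            vg.ScenarioConfig(covariate_effects={"no_such_covariate": 1.0})


def test_scenario_validation():
    with pytest.raises(vg.synthetic.InvalidScenarioError):
        vg.ScenarioConfig(n_divisions=1)
    with pytest.raises(vg.synthetic.InvalidScenarioError):
        vg.ScenarioConfig(sigma_u_true=-0.1)
    with pytest.raises(vg.synthetic.InvalidScenarioError):
        vg.ScenarioConfig(n_provinces=0)
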