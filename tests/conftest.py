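"""Shared fixtures.

The expensive fixture here is ``reference_batch``: fifty independent
replicates of the reference synthetic scenario (293 divisions, median
~304 respondents, 4% baseline vaping prevalence, sigma_u = 0.3), each
fully fitted, shrunken and standardized.  Several recovery/dominance
checks share it so the multilevel model is fitted once per seed only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import vapegeo as vg


@pytest.fixture(scope="session")
def small_world() -> vg.SyntheticWorld:
    cfg = vg.ScenarioConfig(
        n_divisions=25, n_provinces=3, median_respondents=150, seed=11
    )
    world = vg.simulate_scenario(cfg)
    world.respondents = vg.scale_weights(world.respondents)
    return world


@pytest.fixture(scope="session")
def small_fit(small_world):
    return vg.fit_multilevel_logistic(small_world.respondents, "y_ends")


def full_joint_profile(model) -> pd.DataFrame:
    """Weighted empirical joint distribution over every model term."""
    frame = model._source_frame
    terms = list(model._term_order)
    joint = frame.groupby(terms, observed=True)["__w__"].sum()
    cells = (joint / joint.sum()).reset_index().rename(columns={"__w__": "prob"})
    return cells


def true_cell_prevalence(cells: pd.DataFrame, cfg: vg.ScenarioConfig, u: np.ndarray):
    """True mixed prevalence per division under the given cell profile."""
    lin = np.array(
        [
            cfg.beta0_ends
            + cfg.beta_age[vg.AGE_GROUPS.index(row["age_group"])]
            + cfg.beta_sex * (row["sex"] == "M")
            + cfg.source_offsets[cfg.sources.index(row["source"])]
            for _, row in cells.iterrows()
        ]
    )
    probs = cells["prob"].to_numpy()
    return expit(lin[None, :] + u[:, None]) @ probs


def _one_reference_replicate(seed: int) -> dict:
    cfg = vg.ScenarioConfig(seed=seed)
    world = vg.simulate_scenario(cfg)
    resp = vg.scale_weights(world.respondents)
    res = vg.fit_multilevel_logistic(resp, "y_ends")
    cells = full_joint_profile(res.model)
    est = vg.apply_shrinkage(res)
    est = vg.standardize_prevalence(res, est, profile=cells, n_draws=0)
    est = est.sort_values("division_id", ignore_index=True)
    truth = world.truth.sort_values("division_id", ignore_index=True)
    p_mix = true_cell_prevalence(cells, cfg, truth["u_true"].to_numpy())
    raw = (
        resp.assign(num=resp["scaled_weight"] * resp["y_ends"])
        .groupby("division_id")[["num", "scaled_weight"]]
        .sum()
    )
    raw = (raw["num"] / raw["scaled_weight"]).reindex(est["division_id"]).to_numpy()
    shrunk = est["prevalence"].to_numpy()
    w3 = vg.knn_weights(world.geography, 3)
    corr = vg.correlate_all(
        est, None, world.covariates[["division_id", "ice"]], w3,
        n_perm=19, seed=seed,
    )
    return {
        "seed": seed,
        "beta0_hat": float(res.params["const"]),
        "sigma2_hat": float(res.sigma2_u0),
        "converged": res.converged,
        "rmse_shrunk": float(np.sqrt(np.mean((shrunk - p_mix) ** 2))),
        "rmse_raw": float(np.sqrt(np.mean((raw - p_mix) ** 2))),
        "L_ice": float(corr.loc[corr["y"] == "ice", "L"].iloc[0]),
        "natl_prev": float(np.average(shrunk, weights=est["n_j"])),
        # prevalence standardized to the reference cell, the scale on
        # which the scenario's 4% national anchor is defined
        "natl_prev_ref": float(
            np.average(
                expit(res.params["const"] + est["u_hat"].to_numpy()),
                weights=est["n_j"],
            )
        ),
    }


@pytest.fixture(scope="session")
def reference_batch() -> pd.DataFrame:
    return pd.DataFrame([_one_reference_replicate(seed) for seed in range(50)])
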