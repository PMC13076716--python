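"""Precision-weighted (empirical-Bayes) shrinkage and standardized
division prevalence.

The raw division residual ``r_j`` from the multilevel fit is attenuated
toward the grand mean by the precision weight

.. math::

    \\hat u_{0j} = r_j \\times
        \\frac{\\sigma^2_{u0}}{\\sigma^2_{u0} + \\sigma^2_{e0}/n_j},

so divisions contributing few respondents are pulled hardest toward
zero on the residual (logit) scale.  Shrunken effects are then turned
into age/sex/source-standardized prevalences by averaging inverse-logit
predictions over a reference covariate profile, with percentile
intervals from parametric simulation of the fitted sampling
distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit


def shrinkage_factor(sigma2_u0, sigma2_e0, n_j):
    """Precision weight ``sigma2_u0 / (sigma2_u0 + sigma2_e0 / n_j)``.

    Vectorized over ``n_j``.  ``n_j = 0`` gives 0 (no information);
    ``sigma2_u0 = 0`` gives 0 for any ``n_j``; the factor tends to 1 as
    ``n_j`` grows.  Negative variances are rejected.
    """
    scalar = np.isscalar(n_j) and np.isscalar(sigma2_u0) and np.isscalar(sigma2_e0)
    s2u, s2e, n = np.broadcast_arrays(
        np.asarray(sigma2_u0, dtype=float),
        np.asarray(sigma2_e0, dtype=float),
        np.asarray(n_j, dtype=float),
    )
    if (s2u < 0).any() or (s2e <= 0).any():
        raise ValueError("variance components must be sigma2_u0 >= 0, sigma2_e0 > 0")
    if (n < 0).any():
        raise ValueError("n_j must be >= 0")
    ratio = np.divide(s2e, n, out=np.full(n.shape, np.inf), where=n > 0)
    denom = s2u + ratio
    out = np.divide(s2u, denom, out=np.zeros(n.shape), where=denom > 0)
    out = np.where(s2u == 0, 0.0, out)
    return float(out) if scalar else out


def apply_shrinkage(results) -> pd.DataFrame:
    """Division estimates table with the shrunken effect ``u_hat`` filled.

    ``u_hat = r_j * shrinkage_factor(sigma2_u0, sigma2_e0, n_j)``; by the
    definition of ``r_j`` this equals the empirical-Bayes posterior mean
    of the division random intercept.
    """
    if not results.converged:
        raise ValueError("refusing to shrink residuals from a non-converged fit")
    lam = shrinkage_factor(results.sigma2_u0, results.sigma2_e0, results.n_j)
    re = results.random_effects
    if re["r_j"].isna().any():
        raise ValueError("missing residual r_j for at least one division")
    u_hat = re["r_j"].to_numpy() * lam
    return pd.DataFrame(
        {
            "division_id": re["division_id"].to_numpy(),
            "n_j": re["n_j"].to_numpy(),
            "r_j": re["r_j"].to_numpy(),
            "shrink_lambda": lam,
            "u_hat": u_hat,
            "suppressed": False,
            "merged_into": pd.array([None] * len(re), dtype=object),
        }
    )


def default_reference_profile(
    model, reference_source: str | None = None
) -> pd.DataFrame:
    """Pooled empirical age x sex joint distribution, source fixed.

    The standardization target is the weighted joint distribution of age
    band and sex over all respondents, with the data source held at a
    designated reference survey-year (default: the model's reference
    dummy level, i.e. the first source alphabetically).  Returns a cell
    table with columns for each model term plus ``prob``.
    """
    if model._terms is None:
        raise ValueError("reference profile needs a model built with from_dataframe")
    terms = list(model._term_order)
    demo = [t for t in terms if t != "source"]
    raw = getattr(model, "_source_frame", None)
    if raw is None:
        raise ValueError("model does not carry its source respondent frame")
    joint = raw.groupby(demo, observed=True)["__w__"].sum()
    joint = joint / joint.sum()
    cells = joint.reset_index().rename(columns={"__w__": "prob"})
    if "source" in terms:
        src = reference_source if reference_source is not None else model._terms["source"][0]
        if src not in model._terms["source"]:
            raise KeyError(f"unknown reference source {src!r}")
        cells["source"] = src
    return cells[terms + ["prob"]]


def _cell_design(model, cells: pd.DataFrame) -> np.ndarray:
    return np.vstack(
        [
            model.design_row(**{t: row[t] for t in model._term_order})
            for _, row in cells.iterrows()
        ]
    )


def standardize_prevalence(
    results,
    estimates: pd.DataFrame,
    profile: pd.DataFrame | None = None,
    n_draws: int = 1000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fill standardized prevalence and interval columns of ``estimates``.

    ``prevalence_j = sum_cells prob(cell) * expit(x_cell' beta + u_hat_j)``.
    Intervals come from ``n_draws`` parametric draws of ``beta`` (from
    the fitted covariance) and of ``u_0j`` (from its empirical-Bayes
    posterior), percentile ``alpha/2`` and ``1 - alpha/2``.  Set
    ``n_draws=0`` to skip intervals.
    """
    model = results.model
    if profile is None:
        profile = default_reference_profile(model)
    probs = profile["prob"].to_numpy(dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-8):
        raise ValueError("reference profile probabilities must sum to 1")
    Xc = _cell_design(model, profile)
    beta = results.params.to_numpy()
    out = estimates.copy()
    order = pd.Index(results.random_effects["division_id"]).get_indexer(
        out["division_id"]
    )
    if (order < 0).any():
        raise KeyError("estimates contain divisions unknown to the fit")
    u_hat = out["u_hat"].to_numpy(dtype=float)
    eta_cells = Xc @ beta  # (n_cells,)
    out["prevalence"] = expit(eta_cells[None, :] + u_hat[:, None]) @ probs
    if n_draws > 0:
        rng = np.random.default_rng(seed)
        cov = results.cov_params().to_numpy()
        bdraws = rng.multivariate_normal(beta, cov, size=n_draws, method="svd")
        post_mean = results.u_postmean[order]
        post_sd = np.sqrt(results.u_postvar[order])
        udraws = post_mean[None, :] + post_sd[None, :] * rng.standard_normal(
            (n_draws, len(out))
        )
        eta_draw = bdraws @ Xc.T  # (n_draws, n_cells)
        prev = np.empty((n_draws, len(out)))
        for d in range(n_draws):
            prev[d] = expit(eta_draw[d][None, :] + udraws[d][:, None]) @ probs
        out["ci_low"] = np.quantile(prev, alpha / 2, axis=0)
        out["ci_high"] = np.quantile(prev, 1 - alpha / 2, axis=0)
    else:
        out["ci_low"] = np.nan
        out["ci_high"] = np.nan
    return out


def estimate_divisions(
    results,
    profile: pd.DataFrame | None = None,
    n_draws: int = 1000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Shrink and standardize in one step (the usual entry point)."""
    est = apply_shrinkage(results)
    return standardize_prevalence(
        results, est, profile=profile, n_draws=n_draws, seed=seed
    )
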