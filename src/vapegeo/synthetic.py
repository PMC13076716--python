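"""Synthetic study generator: geography, latent prevalence surface,
pooled-survey respondents, and area covariates with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: ~293 divisions nested in ~10 provinces, a spatially
autocorrelated division-level random effect on the logit scale, pooled
respondents from several survey products and years with survey weights,
and division-level census-style covariates with configurable planted
associations with the latent surface.  Everything is deterministic
given the scenario seed.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit


class InvalidScenarioError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


#: survey products x years pooled in the emulated design, with relative
#: target sample shares loosely proportional to the real survey sizes.
DEFAULT_SOURCES: tuple[str, ...] = (
    "CTADS_2013", "CTADS_2015", "CTADS_2017",
    "CCHS_2015", "CCHS_2016", "CCHS_2017", "CCHS_2018", "CCHS_2019",
    "CTNS_2019", "CTNS_2020", "CTNS_2021", "CADS_2019",
)
DEFAULT_SOURCE_SHARES: tuple[float, ...] = (
    15, 16, 16, 65, 65, 65, 65, 65, 9, 8, 10, 10,
)
#: per-source intercept offsets (logit scale); vaping was rising over the
#: study window so later years sit higher.  Offsets are expressed
#: relative to the alphabetically first source (CADS 2019), which is the
#: reference level of the model's dummy coding, so the true intercept is
#: the log-odds at the model's reference cell.
DEFAULT_SOURCE_OFFSETS: tuple[float, ...] = (
    -0.32, -0.22, -0.12, -0.22, -0.17, -0.12, -0.07, -0.02,
    0.03, 0.06, 0.10, 0.0,
)

AGE_GROUPS: tuple[str, ...] = ("15-24", "25-44", "45+")
SEXES: tuple[str, ...] = ("F", "M")

#: (baseline level, residual noise sd, lower clip, upper clip) per covariate.
COVARIATE_SPECS: dict[str, tuple[float, float, float, float]] = {
    "median_age": (41.0, 3.5, 18.0, 75.0),
    "pct_visible_minority": (9.0, 8.0, 0.0, 100.0),
    "pct_indigenous": (7.0, 7.0, 0.0, 100.0),
    "pct_degree": (17.0, 6.0, 0.0, 100.0),
    "median_income": (62000.0, 9000.0, 15000.0, np.inf),
    "pct_low_income": (14.0, 4.0, 0.0, 100.0),
    "unemployment": (8.0, 3.0, 0.0, 100.0),
    "female_labour_index": (1.0, 0.12, 0.0, np.inf),
    "ice": (0.0, 0.12, -1.0, 1.0),
}


@dataclasses.dataclass
class ScenarioConfig:
    """Full description of a synthetic study scenario.

    Defaults encode the reference study design: 293 divisions across 10
    provinces, a median of 304 respondents per division, a ~4% national
    past-month vaping prevalence at the reference profile, moderate
    between-division heterogeneity (sigma_u = 0.3 on the logit scale)
    with a spatially correlated random-effect surface, and a modest
    positive planted association between the ICE covariate and the
    latent surface.
    """

    n_divisions: int = 293
    n_provinces: int = 10
    median_respondents: float = 304.0
    size_dispersion: float = 0.7  # sd of log division sizes
    min_respondents: int = 1
    beta0_ends: float = float(logit(0.04))
    beta0_smoke: float = float(logit(0.12))
    beta_age: tuple[float, ...] = (0.0, -0.6, -1.4)  # per AGE_GROUPS level
    beta_sex: float = 0.35  # male vs female
    sources: tuple[str, ...] = DEFAULT_SOURCES
    source_shares: tuple[float, ...] = DEFAULT_SOURCE_SHARES
    source_offsets: tuple[float, ...] = DEFAULT_SOURCE_OFFSETS
    age_shares: tuple[float, ...] = (0.15, 0.33, 0.52)
    sex_shares: tuple[float, ...] = (0.51, 0.49)
    sigma_u_true: float = 0.3
    spatial_range: float = 0.15  # correlation length on the unit square
    covariate_effects: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"ice": 0.1}
    )
    weight_dispersion: float = 0.5  # sd of log survey weights
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_divisions < 2:
            raise InvalidScenarioError("n_divisions must be >= 2")
        if self.n_provinces < 1:
            raise InvalidScenarioError("n_provinces must be >= 1")
        if self.n_provinces > self.n_divisions:
            raise InvalidScenarioError("more provinces than divisions")
        if self.sigma_u_true < 0:
            raise InvalidScenarioError("sigma_u_true must be >= 0")
        if self.spatial_range < 0:
            raise InvalidScenarioError("spatial_range must be >= 0")
        if self.median_respondents <= 0 or self.size_dispersion < 0:
            raise InvalidScenarioError("division size parameters must be positive")
        if self.min_respondents < 0:
            raise InvalidScenarioError("min_respondents must be >= 0")
        if self.weight_dispersion < 0:
            raise InvalidScenarioError("weight_dispersion must be >= 0")
        if len(self.beta_age) != len(AGE_GROUPS):
            raise InvalidScenarioError(
                f"beta_age must have {len(AGE_GROUPS)} entries"
            )
        if not (
            len(self.sources) == len(self.source_shares) == len(self.source_offsets)
        ):
            raise InvalidScenarioError(
                "sources, source_shares and source_offsets must be equal length"
            )
        unknown = set(self.covariate_effects) - set(COVARIATE_SPECS)
        if unknown:
            raise InvalidScenarioError(
                f"unknown covariate name(s) in covariate_effects: {sorted(unknown)}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_effects"] = dict(self.covariate_effects)
        return d


@dataclasses.dataclass
class SyntheticWorld:
    """Bundle of a fully generated scenario with its ground truth."""

    config: ScenarioConfig
    geography: pd.DataFrame
    truth: pd.DataFrame
    respondents: pd.DataFrame
    covariates: pd.DataFrame


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


def generate_geography(
    n_divisions: int, n_provinces: int, seed: int
) -> pd.DataFrame:
    """Division centroids on the unit square with contiguous provinces.

    Centroids are uniform on the unit square; provinces are assigned as
    contiguous vertical strips (equal division counts, west to east) so
    that provinces form spatial blocks.  Returns a DataFrame with
    columns ``division_id, province_id, x, y``.
    """
    if n_divisions < 2:
        raise InvalidScenarioError("n_divisions must be >= 2")
    if n_provinces < 1 or n_provinces > n_divisions:
        raise InvalidScenarioError("need 1 <= n_provinces <= n_divisions")
    rng = _rng(seed, 0)
    xy = rng.uniform(size=(n_divisions, 2))
    order = np.argsort(xy[:, 0], kind="stable")  # west-to-east strips
    province = np.empty(n_divisions, dtype=object)
    bounds = np.array_split(order, n_provinces)
    for p, block in enumerate(bounds):
        province[block] = f"P{p + 1:02d}"
    width = len(str(n_divisions))
    ids = [f"D{i + 1:0{width}d}" for i in range(n_divisions)]
    return pd.DataFrame(
        {"division_id": ids, "province_id": province, "x": xy[:, 0], "y": xy[:, 1]}
    )


def generate_truth(geography: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Latent division effects and true prevalences.

    ``u_true`` is a zero-mean Gaussian field over the centroids with
    marginal sd ``sigma_u_true`` and exponential correlation
    ``exp(-d / spatial_range)``; ``spatial_range = 0`` gives i.i.d.
    effects.  True prevalences are the inverse-logit of the outcome
    intercepts plus ``u_true`` (the reference covariate profile).
    """
    rng = _rng(config.seed, 1)
    n = len(geography)
    z = rng.standard_normal(n)
    if config.sigma_u_true == 0:
        u = np.zeros(n)
    elif config.spatial_range == 0:
        u = config.sigma_u_true * z
    else:
        xy = geography[["x", "y"]].to_numpy(dtype=float)
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        corr = np.exp(-d / config.spatial_range)
        corr[np.diag_indices(n)] += 1e-9
        chol = np.linalg.cholesky(corr)
        u = config.sigma_u_true * (chol @ z)
    return pd.DataFrame(
        {
            "division_id": geography["division_id"].to_numpy(),
            "u_true": u,
            "p_true_ends": expit(config.beta0_ends + u),
            "p_true_smoke": expit(config.beta0_smoke + u),
        }
    )


def generate_respondents(
    truth: pd.DataFrame, geography: pd.DataFrame, config: ScenarioConfig
) -> pd.DataFrame:
    """Pooled-survey respondent records with binary nicotine outcomes.

    Division sample sizes are log-normal around ``median_respondents``;
    each respondent carries an age band, sex, source (survey product x
    year), a positive log-normal survey weight independent of the
    outcome, and Bernoulli outcomes with
    ``logit(p) = beta0 + x'beta + u_true_j``.
    """
    if not truth["division_id"].equals(geography["division_id"]):
        raise InvalidScenarioError("truth and geography division ids differ")
    rng = _rng(config.seed, 2)
    n_div = len(truth)
    sizes = np.rint(
        np.exp(
            np.log(config.median_respondents)
            + config.size_dispersion * rng.standard_normal(n_div)
        )
    ).astype(int)
    sizes = np.maximum(sizes, config.min_respondents)
    total = int(sizes.sum())

    division = np.repeat(truth["division_id"].to_numpy(), sizes)
    u = np.repeat(truth["u_true"].to_numpy(), sizes)

    age_idx = rng.choice(len(AGE_GROUPS), size=total, p=np.asarray(config.age_shares))
    sex_idx = rng.choice(len(SEXES), size=total, p=np.asarray(config.sex_shares))
    shares = np.asarray(config.source_shares, dtype=float)
    src_idx = rng.choice(len(config.sources), size=total, p=shares / shares.sum())

    lin = (
        np.asarray(config.beta_age)[age_idx]
        + config.beta_sex * (sex_idx == 1)
        + np.asarray(config.source_offsets)[src_idx]
        + u
    )
    y_ends = rng.uniform(size=total) < expit(config.beta0_ends + lin)
    y_smoke = rng.uniform(size=total) < expit(config.beta0_smoke + lin)
    weight = np.exp(
        -0.5 * config.weight_dispersion**2
        + config.weight_dispersion * rng.standard_normal(total)
    )

    sources = np.asarray(config.sources, dtype=object)
    years = np.array([int(s.rsplit("_", 1)[1]) for s in config.sources])
    out = pd.DataFrame(
        {
            "respondent_id": [f"R{i + 1:07d}" for i in range(total)],
            "division_id": division,
            "age_group": np.asarray(AGE_GROUPS, dtype=object)[age_idx],
            "sex": np.asarray(SEXES, dtype=object)[sex_idx],
            "source": sources[src_idx],
            "year": years[src_idx],
            "weight": weight,
            "y_ends": y_ends.astype(int),
            "y_smoke": y_smoke.astype(int),
        }
    )
    empty = truth["division_id"][sizes == 0]
    if len(empty):
        out.attrs["empty_divisions"] = list(empty)
    return out


def generate_covariates(
    truth: pd.DataFrame, config: ScenarioConfig, seed: int | None = None
) -> pd.DataFrame:
    """Division-level census-style covariates with planted associations.

    Each covariate is ``a_c + b_c * u_true_j + noise`` with ``b_c`` (in
    covariate units per logit of the latent surface) taken from
    ``config.covariate_effects`` (0 when unnamed), then clipped to its
    natural range.
    """
    rng = _rng(config.seed if seed is None else seed, 3)
    u = truth["u_true"].to_numpy(dtype=float)
    out = {"division_id": truth["division_id"].to_numpy()}
    for name, (base, noise_sd, lo, hi) in COVARIATE_SPECS.items():
        b = float(config.covariate_effects.get(name, 0.0))
        vals = base + b * u + noise_sd * rng.standard_normal(len(u))
        out[name] = np.clip(vals, lo, hi)
    return pd.DataFrame(out)


def simulate_scenario(config: ScenarioConfig) -> SyntheticWorld:
    """Generate the complete synthetic study for ``config``."""
    geography = generate_geography(config.n_divisions, config.n_provinces, config.seed)
    truth = generate_truth(geography, config)
    respondents = generate_respondents(truth, geography, config)
    covariates = generate_covariates(truth, config)
    return SyntheticWorld(
        config=config,
        geography=geography,
        truth=truth,
        respondents=respondents,
        covariates=covariates,
    )
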