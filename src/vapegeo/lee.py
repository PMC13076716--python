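"""Lee's L spatially explicit bivariate correlation.

Lee's L blends Pearson correlation with the spatial autocorrelation of
both variables by correlating their spatially lagged deviations:

.. math::

    L_{X,Y} = \\frac{\\sum_i \\bigl(\\sum_j w_{ij}(x_j-\\bar x)\\bigr)
                          \\bigl(\\sum_j w_{ij}(y_j-\\bar y)\\bigr)}
                   {\\sqrt{\\sum_i (x_i-\\bar x)^2}\\,
                    \\sqrt{\\sum_i (y_i-\\bar y)^2}}

with ``w`` a row-standardized spatial weights matrix.  Under identity
weights (each unit its own sole neighbour) L collapses to Pearson's r.

Significance is assessed by jointly permuting the (x_i, y_i) pairs over
locations: the aspatial x–y correlation is preserved under the null, so
the test isolates the spatial component of the association.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .spatial import SpatialWeights, UndefinedStatisticError, _check_variable

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    """A single spatially explicit correlation with its permutation p."""

    x_name: str
    y_name: str
    L: float
    p_value: float
    n_perm: int
    spec: str
    seed: int | None
    n_used: int


def lees_l(x: np.ndarray, y: np.ndarray, weights: SpatialWeights) -> float:
    """Lee's L of two variables aligned to ``weights.ids``.

    Raises
    ------
    UndefinedStatisticError
        If either variable has zero variance.
    """
    x = _check_variable(x, "x")
    y = _check_variable(y, "y")
    if x.size != weights.n or y.size != weights.n:
        raise ValueError("variable length does not match weights")
    zx = x - x.mean()
    zy = y - y.mean()
    num = float((weights.W @ zx) @ (weights.W @ zy))
    den = float(np.sqrt(zx @ zx) * np.sqrt(zy @ zy))
    return num / den


def _lees_l_batch(Zx: np.ndarray, Zy: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    """Lee's L per column pair (columns already centred)."""
    num = ((weights.W @ Zx) * (weights.W @ Zy)).sum(axis=0)
    den = np.sqrt((Zx**2).sum(axis=0)) * np.sqrt((Zy**2).sum(axis=0))
    return num / den


def lees_l_inference(
    x: np.ndarray,
    y: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """Permutation test for Lee's L.

    The null is built by jointly permuting (x_i, y_i) pairs over
    locations; the two-sided pseudo p applies the
    ``(1 + count) / (n_perm + 1)`` rule to ``|L - mean(L_perm)|``.
    Deterministic given ``seed``.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    obs = lees_l(x, y, weights)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(np.arange(x.size), (n_perm, 1)), axis=1).T
    sims = _lees_l_batch(x[perm] - x.mean(), y[perm] - y.mean(), weights)
    centre = sims.mean()
    count = int((np.abs(sims - centre) >= abs(obs - centre)).sum())
    p = (1 + count) / (n_perm + 1)
    return CorrelationResult(
        x_name=x_name,
        y_name=y_name,
        L=float(obs),
        p_value=p,
        n_perm=n_perm,
        spec=weights.spec,
        seed=seed,
        n_used=int(x.size),
    )


def correlate_all(
    estimates: pd.DataFrame,
    smoking_estimates: pd.DataFrame | None,
    covariates: pd.DataFrame | None,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = 0,
    value_col: str = "prevalence",
    covariate_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Correlation sweep of the vaping surface against smoking and covariates.

    One :func:`lees_l_inference` result for vaping~smoking (if smoking
    estimates are supplied) followed by one per covariate column, all
    against the vaping surface.  Suppressed divisions (``suppressed``
    truthy or missing ``value_col``) are excluded; divisions missing a
    covariate are dropped listwise per pair with a logged count.  The
    weights are subset (and re-row-standardized) to the divisions
    actually used for each pair.

    Returns a tidy DataFrame with columns
    ``x, y, L, p, p_adjusted, n_perm, n_used, spec, seed`` where
    ``p_adjusted`` is the Benjamini–Hochberg adjustment across the sweep
    (raw p remains primary).
    """

    def usable_ids(df: pd.DataFrame, col: str) -> set:
        out = df.copy()
        if "suppressed" in out.columns:
            out = out[~out["suppressed"].astype(bool)]
        out = out[np.isfinite(out[col].astype(float))]
        return set(out["division_id"])

    vape_ids = usable_ids(estimates, value_col)
    pairs: list[tuple[str, pd.DataFrame, str, set]] = []
    if smoking_estimates is not None:
        pairs.append(
            (
                "smoking_prevalence",
                smoking_estimates,
                value_col,
                usable_ids(smoking_estimates, value_col),
            )
        )
    if covariates is not None:
        cols = list(covariate_cols) if covariate_cols is not None else [
            c for c in covariates.columns if c != "division_id"
        ]
        for c in cols:
            pairs.append((c, covariates, c, usable_ids(covariates, c)))

    results: list[CorrelationResult] = []
    for idx, (name, table, col, ids_y) in enumerate(pairs):
        keep = sorted(vape_ids & ids_y & set(weights.ids))
        dropped = weights.n - len(keep)
        if dropped:
            logger.info("pair vaping~%s: %d division(s) excluded listwise", name, dropped)
        if len(keep) < 3:
            raise ValueError(f"too few divisions ({len(keep)}) for pair vaping~{name}")
        sub = weights.subset(keep)
        x = sub.align(estimates, value_col)
        y = sub.align(table, col)
        # z-scoring is cosmetic (L is scale-invariant) but stabilizes reporting
        y = (y - y.mean()) / y.std(ddof=0)
        sub_seed = None if seed is None else int(
            np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31)
        )
        results.append(
            lees_l_inference(
                x, y, sub, n_perm=n_perm, seed=sub_seed,
                x_name="ends_prevalence", y_name=name,
            )
        )

    table = pd.DataFrame(
        {
            "x": [r.x_name for r in results],
            "y": [r.y_name for r in results],
            "L": [r.L for r in results],
            "p": [r.p_value for r in results],
            "n_perm": [r.n_perm for r in results],
            "n_used": [r.n_used for r in results],
            "spec": [r.spec for r in results],
            "seed": [r.seed for r in results],
        }
    )
    table["p_adjusted"] = multipletests(table["p"], method="fdr_bh")[1]
    return table[["x", "y", "L", "p", "p_adjusted", "n_perm", "n_used", "spec", "seed"]]


def plot_correlation_sweep(table: pd.DataFrame, path=None, alpha: float = 0.05):
    """Horizontal bar chart of the correlation sweep (significant bars filled)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.4 * len(table) + 1.5))
    sig = table["p"] < alpha
    colors = np.where(sig, "#c0392b", "#95a5a6")
    ax.barh(table["y"], table["L"], color=list(colors))
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Lee's L with past-month vaping prevalence")
    ax.invert_yaxis()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
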