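"""Random-intercepts multilevel logistic regression for pooled surveys.

The model for respondent i in division j is

.. math::

    \\mathrm{logit}\\,P(y_{ij}=1) = \\beta_0 + x_{ij}'\\beta_1 + u_{0j},
    \\qquad u_{0j} \\sim N(0, \\sigma^2_{u0}),

with fixed effects for age band, sex/gender and data source (survey
product x year).  The marginal likelihood integrates the division
random intercept out numerically — a Laplace approximation by default,
adaptive Gauss–Hermite quadrature on request — and survey weights enter
as frequency-style scaled weights in a pseudo-likelihood.

The per-division quantities needed by precision-weighted estimation
(empirical-Bayes posterior modes/means and the raw residual ``r_j``
whose shrinkage reproduces the posterior mean) are carried on the
results object.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

SIGMA2_E0_LOGISTIC = np.pi**2 / 3.0
"""Standard logistic latent-scale level-1 variance (pi^2/3)."""


class DegenerateFitError(ValueError):
    """Raised when the outcome carries no information (constant overall)."""


class ConvergenceWarning(UserWarning):
    """Emitted when the optimizer stops without meeting its tolerance."""


# ---------------------------------------------------------------------------
# survey-weight scaling
# ---------------------------------------------------------------------------

def scale_weights(
    respondents: pd.DataFrame,
    method: str | None = "A",
    weight_col: str = "weight",
    group_col: str = "division_id",
) -> pd.DataFrame:
    """Scale survey weights for pooled multilevel use.

    Method "A" (cluster-size scaling) rescales weights within each
    division so they sum to the division's respondent count:
    ``scaled_w_ij = w_ij * n_j / sum_i w_ij``.  Method "B" rescales to
    the division's effective sample size ``(sum w)^2 / sum w^2``.
    ``method=None`` copies weights unchanged.  The original weight
    column is preserved; the result gains a ``scaled_weight`` column.
    """
    if (respondents[weight_col] <= 0).any():
        raise ValueError("survey weights must be strictly positive")
    out = respondents.copy()
    w = out[weight_col].astype(float)
    if method is None or method == "none":
        out["scaled_weight"] = w.to_numpy()
        return out
    grp = out.groupby(group_col)[weight_col]
    wsum = grp.transform("sum").astype(float)
    if method == "A":
        target = grp.transform("size").astype(float)
    elif method == "B":
        wsq = out[weight_col].astype(float) ** 2
        target = (wsum**2) / wsq.groupby(out[group_col]).transform("sum")
    else:
        raise ValueError(f"unknown weight-scaling method {method!r}")
    out["scaled_weight"] = (w * target / wsum).to_numpy()
    return out


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class MixedLogit:
    """Random-intercept logistic model estimated by approximate ML.

    Parameters
    ----------
    endog : array-like of {0, 1}
    exog : (n, p) design matrix including an intercept column first.
    groups : array-like of division labels, one per row.
    weights : optional positive frequency-style weights (e.g. scaled
        survey weights); default 1.
    exog_names : optional column names for ``exog``.
    sigma2_e0 : level-1 latent-scale variance used for the shrinkage
        factor attached to the results; defaults to pi^2/3.
    """

    def __init__(
        self,
        endog,
        exog,
        groups,
        weights=None,
        exog_names=None,
        sigma2_e0: float = SIGMA2_E0_LOGISTIC,
    ):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("exog must be (n, p) aligned with endog")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        labels, g = np.unique(np.asarray(groups), return_inverse=True)
        if labels.size < 2:
            raise ValueError("at least 2 divisions are required")
        if weights is None:
            w = np.ones_like(y)
        else:
            w = np.asarray(weights, dtype=float).ravel()
            if w.size != y.size or (w <= 0).any():
                raise ValueError("weights must be positive and aligned with endog")
        self.endog = y
        self.exog = X
        self.group_labels = labels
        self.weights = w
        self.sigma2_e0 = float(sigma2_e0)
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else ["const"] + [f"x{i}" for i in range(1, X.shape[1])]
        )
        self._g = g
        self._G = labels.size
        self._nj = np.bincount(g, minlength=self._G).astype(float)
        self._wsum = np.bincount(g, weights=w, minlength=self._G)
        self._ucache = np.zeros(self._G)
        self._terms: dict[str, list] | None = None
        self._term_order: tuple[str, ...] | None = None
        self._source_frame: pd.DataFrame | None = None

    # -- construction from a respondent table ---------------------------

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        group: str = "division_id",
        terms: tuple[str, ...] = ("age_group", "sex", "source"),
        weight_col: str | None = "scaled_weight",
        sigma2_e0: float = SIGMA2_E0_LOGISTIC,
    ) -> "MixedLogit":
        """Build the design matrix from a respondent table.

        Each term is treated as categorical with sorted levels and
        first-level-reference dummy coding; the fitted intercept is the
        logit prevalence at the joint reference level.
        """
        n = len(data)
        cols = [np.ones(n)]
        names = ["const"]
        term_levels: dict[str, list] = {}
        for t in terms:
            levels = sorted(pd.unique(data[t]))
            term_levels[t] = levels
            vals = data[t].to_numpy()
            for lev in levels[1:]:
                cols.append((vals == lev).astype(float))
                names.append(f"{t}[{lev}]")
        X = np.column_stack(cols)
        w = data[weight_col].to_numpy(dtype=float) if weight_col else None
        model = cls(
            data[outcome].to_numpy(),
            X,
            data[group].to_numpy(),
            weights=w,
            exog_names=names,
            sigma2_e0=sigma2_e0,
        )
        model._terms = term_levels
        model._term_order = tuple(terms)
        frame = data[list(terms)].copy()
        frame["__w__"] = w if w is not None else 1.0
        model._source_frame = frame
        return model

    def design_row(self, **levels) -> np.ndarray:
        """Design vector for one covariate cell (requires ``from_dataframe``)."""
        if self._terms is None:
            raise ValueError("design_row needs a model built with from_dataframe")
        row = [1.0]
        for t in self._term_order:
            lvls = self._terms[t]
            val = levels[t]
            if val not in lvls:
                raise KeyError(f"unknown level {val!r} for term {t!r}")
            row.extend(1.0 if val == lev else 0.0 for lev in lvls[1:])
        return np.asarray(row)

    # -- likelihood machinery -------------------------------------------

    def _posterior_modes(
        self, eta0: np.ndarray, sigma: float, u_start: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Newton solve for per-division posterior modes of u.

        Returns the modes and the negative Hessians
        ``H_j = sum_i w_i p_i (1 - p_i) + 1/sigma^2`` at the modes.
        The objective is strictly concave in each u_j, so undamped
        Newton (with a step clip for safety) converges.
        """
        g, w, y, G = self._g, self.weights, self.endog, self._G
        inv_s2 = 1.0 / sigma**2
        u = u_start.copy()
        for _ in range(100):
            p = expit(eta0 + u[g])
            grad = np.bincount(g, weights=w * (y - p), minlength=G) - u * inv_s2
            hess = np.bincount(g, weights=w * p * (1 - p), minlength=G) + inv_s2
            step = np.clip(grad / hess, -10.0, 10.0)
            u += step
            if np.abs(step).max() < 1e-10:
                break
        p = expit(eta0 + u[g])
        hess = np.bincount(g, weights=w * p * (1 - p), minlength=G) + 1.0 / sigma**2
        return u, hess

    def _group_data_loglik(self, eta: np.ndarray) -> np.ndarray:
        """Per-division weighted Bernoulli log-likelihood at linear predictor eta."""
        ll_rows = self.weights * (self.endog * eta - np.logaddexp(0.0, eta))
        return np.bincount(self._g, weights=ll_rows, minlength=self._G)

    def loglike(self, params: np.ndarray, n_quad: int = 1) -> float:
        """Approximate marginal log-likelihood at ``params = [beta, sigma_u]``.

        ``n_quad = 1`` is the Laplace approximation; larger values use
        adaptive Gauss–Hermite quadrature centred on the posterior mode.
        """
        params = np.asarray(params, dtype=float)
        beta, sigma = params[:-1], params[-1]
        if sigma < 0:
            raise ValueError("sigma_u must be >= 0")
        eta0 = self.exog @ beta
        if sigma < 1e-10:
            return float(self._group_data_loglik(eta0).sum())
        u, H = self._posterior_modes(eta0, sigma, self._ucache)
        self._ucache = u
        if n_quad <= 1:
            f = self._group_data_loglik(eta0 + u[self._g]) - 0.5 * u**2 / sigma**2
            ll = f - np.log(sigma) - 0.5 * np.log(H)
            return float(ll.sum())
        t, om = np.polynomial.hermite.hermgauss(n_quad)
        s = np.sqrt(2.0 / H)  # per-group scale
        A = np.empty((self._G, n_quad))
        for k in range(n_quad):
            uk = u + s * t[k]
            fk = self._group_data_loglik(eta0 + uk[self._g]) - 0.5 * uk**2 / sigma**2
            A[:, k] = np.log(om[k]) + t[k] ** 2 + fk
        ll = np.log(s) + logsumexp(A, axis=1) - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        return float(ll.sum())

    def _posterior_moments(
        self, beta: np.ndarray, sigma: float, n_quad: int = 40
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Posterior mode, mean and variance of u_j at fixed parameters."""
        eta0 = self.exog @ beta
        if sigma < 1e-10:
            z = np.zeros(self._G)
            return z, z.copy(), z.copy()
        u, H = self._posterior_modes(eta0, sigma, self._ucache)
        t, om = np.polynomial.hermite.hermgauss(n_quad)
        s = np.sqrt(2.0 / H)
        A = np.empty((self._G, n_quad))
        U = np.empty((self._G, n_quad))
        for k in range(n_quad):
            uk = u + s * t[k]
            fk = self._group_data_loglik(eta0 + uk[self._g]) - 0.5 * uk**2 / sigma**2
            A[:, k] = np.log(om[k]) + t[k] ** 2 + fk
            U[:, k] = uk
        A -= A.max(axis=1, keepdims=True)
        wgt = np.exp(A)
        wgt /= wgt.sum(axis=1, keepdims=True)
        mean = (wgt * U).sum(axis=1)
        var = (wgt * (U - mean[:, None]) ** 2).sum(axis=1)
        return u, mean, var

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        start_params: np.ndarray | None = None,
        method: str = "laplace",
        n_quad: int = 1,
        maxiter: int = 200,
        ftol: float = 1e-9,
        sigma_start: float = 0.3,
    ) -> "MixedLogitResults":
        """Maximize the approximate marginal likelihood.

        Fixed-effect start values come from an ordinary weighted
        logistic GLM; the variance parameter is profiled jointly with
        the betas by L-BFGS-B with ``sigma_u`` bounded in [0, 5].
        Non-convergence is flagged on the results and warned about,
        never silent.
        """
        wy = self.weights @ self.endog
        if wy == 0 or wy == self.weights.sum():
            raise DegenerateFitError("outcome is constant; the fit is degenerate")
        if method == "laplace":
            n_quad = 1
        elif method != "agq":
            raise ValueError(f"unknown method {method!r}")
        if start_params is None:
            beta0 = self._glm_start()
            x0 = np.r_[beta0, sigma_start]
        else:
            x0 = np.asarray(start_params, dtype=float)
        p = self.exog.shape[1]
        bounds = [(None, None)] * p + [(0.0, 5.0)]
        nll = lambda th: -self.loglike(th, n_quad=n_quad)
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": ftol},
        )
        converged = bool(res.success)
        if not converged:
            warnings.warn(
                f"mixed-logit optimizer did not converge: {res.message}",
                ConvergenceWarning,
                stacklevel=2,
            )
        beta = res.x[:-1]
        sigma = float(res.x[-1])
        boundary = sigma < 1e-4
        if boundary:
            sigma = 0.0
        u_mode, u_mean, u_var = self._posterior_moments(beta, sigma)
        return MixedLogitResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            sigma_u=sigma,
            llf=float(-res.fun),
            converged=converged,
            boundary=boundary,
            method="laplace" if n_quad <= 1 else f"agq:{n_quad}",
            n_opt_iter=int(res.nit),
            u_mode=u_mode,
            u_postmean=u_mean,
            u_postvar=u_var,
        )

    def _glm_start(self) -> np.ndarray:
        import statsmodels.api as sm

        try:
            glm = sm.GLM(
                self.endog,
                self.exog,
                family=sm.families.Binomial(),
                freq_weights=self.weights,
            )
            return np.asarray(glm.fit(maxiter=50).params)
        except Exception:  # pragma: no cover - defensive fallback
            beta = np.zeros(self.exog.shape[1])
            pbar = float(self.weights @ self.endog / self.weights.sum())
            beta[0] = np.log(pbar / (1 - pbar))
            return beta


def fit_multilevel_logistic(
    respondents: pd.DataFrame,
    outcome: str = "y_ends",
    terms: tuple[str, ...] = ("age_group", "sex", "source"),
    use_weights: bool = True,
    sigma2_e0: float = SIGMA2_E0_LOGISTIC,
    **fit_kwargs,
) -> "MixedLogitResults":
    """Convenience wrapper: build a :class:`MixedLogit` from a respondent
    table and fit it.

    Expects ``scaled_weight`` (from :func:`scale_weights`) when
    ``use_weights`` is on; terms with a single observed level are
    dropped from the design automatically.
    """
    terms = tuple(t for t in terms if respondents[t].nunique() > 1)
    model = MixedLogit.from_dataframe(
        respondents,
        outcome=outcome,
        terms=terms,
        weight_col="scaled_weight" if use_weights else None,
        sigma2_e0=sigma2_e0,
    )
    return model.fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MixedLogitResults:
    """Estimates, variance components and per-division residuals."""

    model: MixedLogit
    params: pd.Series
    sigma_u: float
    llf: float
    converged: bool
    boundary: bool
    method: str
    n_opt_iter: int
    u_mode: np.ndarray
    u_postmean: np.ndarray
    u_postvar: np.ndarray
    _cov: np.ndarray | None = dataclasses.field(default=None, repr=False)

    # -- scalar summaries ------------------------------------------------

    @property
    def sigma2_u0(self) -> float:
        """Between-division variance component (0 at the boundary)."""
        return self.sigma_u**2

    @property
    def sigma2_e0(self) -> float:
        return self.model.sigma2_e0

    @property
    def n_obs(self) -> int:
        return self.model.endog.size

    @property
    def n_groups(self) -> int:
        return self.model.group_labels.size

    @property
    def n_j(self) -> np.ndarray:
        """Respondent counts per division (model order)."""
        return self.model._nj

    def loglike(self, params: np.ndarray, n_quad: int = 1) -> float:
        return self.model.loglike(params, n_quad=n_quad)

    # -- per-division residual table -------------------------------------

    @property
    def shrinkage_lambda(self) -> np.ndarray:
        from .shrinkage import shrinkage_factor

        return shrinkage_factor(self.sigma2_u0, self.sigma2_e0, self.n_j)

    @property
    def r_j(self) -> np.ndarray:
        """Raw division residual on the logit scale.

        Defined as the empirical-Bayes posterior mean of ``u_0j``
        divided by its own shrinkage factor, so that the precision
        weighting ``u_hat = r_j * lambda_j`` reproduces the posterior
        mean exactly.  Zero where the factor is zero.
        """
        lam = self.shrinkage_lambda
        r = np.zeros_like(lam)
        nz = lam > 0
        r[nz] = self.u_postmean[nz] / lam[nz]
        return r

    @property
    def random_effects(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "division_id": self.model.group_labels,
                "n_j": self.n_j.astype(int),
                "w_sum": self.model._wsum,
                "u_mode": self.u_mode,
                "u_postmean": self.u_postmean,
                "u_postvar": self.u_postvar,
                "shrink_lambda": self.shrinkage_lambda,
                "r_j": self.r_j,
            }
        )

    # -- uncertainty ------------------------------------------------------

    def cov_params(self) -> pd.DataFrame:
        """Covariance of the fixed effects from the numeric observed information.

        Computed lazily by central finite differences of the approximate
        log-likelihood at the optimum (conditioning on ``sigma_u`` when
        the variance sits at the zero boundary).
        """
        if self._cov is None:
            beta = self.params.to_numpy()
            theta = np.r_[beta, self.sigma_u]
            free = len(theta) if not self.boundary else len(beta)
            h = 1e-4 * (1.0 + np.abs(theta))
            n_quad = 1 if self.method == "laplace" else int(self.method.split(":")[1])
            H = np.empty((free, free))
            f = lambda t: self.model.loglike(t, n_quad=n_quad)
            f0 = f(theta)
            for i in range(free):
                for j in range(i, free):
                    ti = theta.copy()
                    if i == j:
                        ti[i] += h[i]
                        fp = f(ti)
                        ti[i] -= 2 * h[i]
                        fm = f(ti)
                        H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
                    else:
                        tpp = theta.copy(); tpp[[i, j]] += [h[i], h[j]]
                        tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                        tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                        tmm = theta.copy(); tmm[[i, j]] -= [h[i], h[j]]
                        H[i, j] = H[j, i] = (
                            f(tpp) - f(tpm) - f(tmp) + f(tmm)
                        ) / (4 * h[i] * h[j])
            cov_full = np.linalg.pinv(-H)
            cov = cov_full[: len(beta), : len(beta)]
            # finite-difference asymmetry can leave tiny negative
            # eigenvalues; project onto the PSD cone
            cov = (cov + cov.T) / 2
            vals, vecs = np.linalg.eigh(cov)
            self._cov = (vecs * np.maximum(vals, 0.0)) @ vecs.T
        return pd.DataFrame(self._cov, index=self.params.index, columns=self.params.index)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params().to_numpy())), index=self.params.index
        )

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        from scipy.stats import norm

        bse = self.bse
        z = self.params / bse
        pv = 2 * norm.sf(np.abs(z))
        lines = [
            "Random-intercepts multilevel logistic regression",
            f"  method: {self.method}   converged: {self.converged}"
            + ("   (variance at boundary)" if self.boundary else ""),
            f"  observations: {self.n_obs}   divisions: {self.n_groups}",
            f"  log-likelihood: {self.llf:.3f}",
            f"  sigma2_u0: {self.sigma2_u0:.5f}   sigma2_e0: {self.sigma2_e0:.5f}",
            "",
            f"  {'term':<24}{'coef':>10}{'se':>10}{'z':>8}{'P>|z|':>9}",
        ]
        for name, b, s, zz, p in zip(self.params.index, self.params, bse, z, pv):
            lines.append(f"  {name:<24}{b:>10.4f}{s:>10.4f}{zz:>8.2f}{p:>9.3g}")
        return "\n".join(lines)

    def to_manifest(self) -> dict:
        """JSON-ready fit record for the run manifest."""
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "sigma2_u0": float(self.sigma2_u0),
            "sigma2_e0": float(self.sigma2_e0),
            "llf": float(self.llf),
            "converged": self.converged,
            "boundary": self.boundary,
            "method": self.method,
            "n_obs": int(self.n_obs),
            "n_groups": int(self.n_groups),
            "n_opt_iter": self.n_opt_iter,
        }
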