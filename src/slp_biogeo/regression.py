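"""Phylogenetic logistic and linear regression, partial R2, AIC comparison.

The logistic model treats the binary trait as thresholded through a
logit link whose linear predictor carries a latent phylogenetic effect:

    logit P(y_i = 1) = x_i' beta + u_i,   u ~ N(0, Sigma(alpha)),
    Sigma_ij(alpha) = exp(-alpha * d_ij) / (2 * alpha),

where d_ij is the patristic distance between tips i and j.  This is the
stationary covariance of a mean-reverting (OU) process with unit
diffusion rate: between-tip correlation decays as exp(-alpha * d_ij),
and a large rate alpha drives the latent variance 1/(2 alpha) to zero,
recovering ordinary logistic regression.  Estimation maximises a
Laplace-approximate likelihood over (beta, u) with alpha profiled on a
log scale; a Firth-type penalty (half log-determinant of the fixed-effect
information) guards the fixed effects against separation, which matters
at the low trait prevalences typical of genus-level binary traits.

The linear model is generalised least squares under a Brownian-motion
covariance, used for continuous responses such as species richness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, log_expit

from .tree import Phylogeny

__all__ = [
    "LogisticFit",
    "PhyloGLMFit",
    "PhyloLMFit",
    "fit_logistic",
    "fit_phyloglm",
    "fit_phylolm",
    "partial_r2lik",
    "lr_test",
    "partial_r2_table",
    "compare_models",
]


# --------------------------------------------------------------------------
# fit containers


@dataclass
class _FitBase:
    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    logLik: float
    n: int
    converged: bool

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "z": self.z, "p": self.p},
            index=self.names,
        )


@dataclass
class LogisticFit(_FitBase):
    method: str = "logistic"

    @property
    def n_params(self) -> int:
        return len(self.beta)


@dataclass
class PhyloGLMFit(_FitBase):
    alpha: float = np.nan
    alpha_bounds: tuple[float, float] = (np.nan, np.nan)
    alpha_at_bound: bool = False
    u: np.ndarray = field(default=None, repr=False)
    method: str = "phyloglm"

    @property
    def n_params(self) -> int:
        return len(self.beta) + 1  # + alpha


@dataclass
class PhyloLMFit(_FitBase):
    sigma2: float = np.nan
    method: str = "phylolm"

    @property
    def n_params(self) -> int:
        return len(self.beta) + 1  # + sigma2


# --------------------------------------------------------------------------
# plain logistic regression (no phylogeny)


def _add_intercept(X) -> tuple[np.ndarray, list[str]]:
    if X is None:
        return np.ones((0, 1)), ["intercept"]
    if hasattr(X, "columns"):
        names = ["intercept"] + [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and X.ndim == 2:
            X = X.T if X.shape[0] == 1 else X
        names = ["intercept"] + [f"x{j}" for j in range(X.shape[1])]
    Xd = np.column_stack([np.ones(X.shape[0]), X])
    return Xd, names


def _bernoulli_loglik(y, eta) -> float:
    # y*eta - log(1 + exp(eta)), stable via log_expit
    return float(np.sum(y * eta + log_expit(-eta)))


def _firth_irls(y, Xd, max_iter=100, tol=1e-10):
    """Firth-penalised logistic regression by adjusted-score IRLS."""
    n, p = Xd.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        XtWX = Xd.T @ (Xd * w[:, None])
        XtWX_inv = np.linalg.inv(XtWX)
        h = np.einsum("ij,jk,ik->i", Xd * w[:, None], XtWX_inv, Xd)
        score = Xd.T @ (y - mu + h * (0.5 - mu))
        step = XtWX_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = Xd @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    cov = np.linalg.inv(Xd.T @ (Xd * w[:, None]))
    return beta, np.sqrt(np.diag(cov)), _bernoulli_loglik(y, eta)


def fit_logistic(y, X=None, names=None, firth: str | bool = "auto") -> LogisticFit:
    """Maximum-likelihood logistic regression (statsmodels backend).

    ``firth='auto'`` falls back to Firth-penalised estimation when the ML
    fit fails to converge (e.g. complete separation); ``firth=True`` forces
    it, ``firth=False`` reports the unpenalised fit with ``converged``
    False on separation.
    """
    y = np.asarray(y, dtype=float)
    if X is None:
        Xd, auto_names = np.ones((len(y), 1)), ["intercept"]
    else:
        Xd, auto_names = _add_intercept(X)
    names = list(names) if names is not None else auto_names
    if len(np.unique(y)) < 2:
        raise ValueError("response must contain both states")
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("design matrix is rank deficient")

    if firth is True:
        beta, se, ll = _firth_irls(y, Xd)
        return LogisticFit(beta, se, names, ll, len(y), True,
                           method="logistic-firth")

    import statsmodels.api as sm

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            beta = np.asarray(res.params)
            se = np.asarray(res.bse)
            ll = float(res.llf)
        except Exception:
            converged = False
            beta = np.full(Xd.shape[1], np.nan)
            se = np.full(Xd.shape[1], np.nan)
            ll = np.nan
    if np.any(~np.isfinite(se)) or np.max(np.abs(beta[np.isfinite(beta)]),
                                          initial=0.0) > 1e2:
        converged = False
    if not converged and firth == "auto":
        beta, se, ll = _firth_irls(y, Xd)
        return LogisticFit(beta, se, names, ll, len(y), True,
                           method="logistic-firth")
    return LogisticFit(beta, se, names, ll, len(y), converged)


# --------------------------------------------------------------------------
# phylogenetic logistic regression


def _latent_cov(D: np.ndarray, alpha: float) -> np.ndarray:
    return np.exp(-alpha * D) / (2.0 * alpha)


def _inner_fit(y, Xd, Sinv, beta0=None, u0=None, penalized=True,
               max_iter=60, tol=1e-8):
    """Joint Newton maximisation over (beta, u) for fixed alpha.

    The Newton direction uses the exact Hessian of the unpenalised joint
    objective; when ``penalized`` the fixed-effect score carries the Firth
    adjustment (hat-value-weighted residual shift), the standard
    adjusted-score fixed point.  Steps are damped by their sup-norm, which
    is enough for this concave objective.  Returns beta, u, the Bernoulli
    weights at the optimum, and a convergence flag.
    """
    n, p = Xd.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    u = np.zeros(n) if u0 is None else u0.copy()
    converged = False
    H = np.empty((p + n, p + n))
    for _ in range(max_iter):
        eta = Xd @ beta + u
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        g_beta = Xd.T @ (y - mu)
        if penalized:
            XtWX_inv = np.linalg.inv(Xd.T @ (Xd * w[:, None]))
            h = np.einsum("ij,jk,ik->i", Xd * w[:, None], XtWX_inv, Xd)
            g_beta = Xd.T @ (y - mu + h * (0.5 - mu))
        g_u = (y - mu) - Sinv @ u
        grad = np.concatenate([g_beta, g_u])
        H[:p, :p] = Xd.T @ (Xd * w[:, None])
        H[:p, p:] = Xd.T * w[None, :]
        H[p:, :p] = H[:p, p:].T
        H[p:, p:] = Sinv
        H[p:, p:][np.diag_indices(n)] += w
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        sup = np.max(np.abs(step))
        if sup > 4.0:  # damp early wild steps
            step *= 4.0 / sup
        beta = beta + step[:p]
        u = u + step[p:]
        if sup < tol:
            converged = True
            break
    eta = Xd @ beta + u
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    return beta, u, w, converged


def _laplace_loglik(y, Xd, beta, u, w, Sinv, Sigma) -> float:
    eta = Xd @ beta + u
    n = len(y)
    ll = _bernoulli_loglik(y, eta) - 0.5 * float(u @ (Sinv @ u))
    sign, ld = np.linalg.slogdet(np.eye(n) + Sigma * w[None, :])
    return ll - 0.5 * ld


def fit_phyloglm(y, X, tree: Phylogeny, names=None, penalized: bool = True,
                 alpha_bounds: tuple[float, float] | None = None,
                 n_grid: int = 7) -> PhyloGLMFit:
    """Phylogenetic logistic regression with profiled signal rate alpha.

    alpha is profiled on a log scale within ``alpha_bounds`` (default
    ``[1e-4 / T, 1e4 / T]`` with T the tree height): a coarse grid
    locates the optimum and a bounded scalar search refines it.  At the
    upper bound the latent variance 1/(2 alpha) is numerically negligible
    and the fit coincides with plain logistic regression.
    """
    y = np.asarray(y, dtype=float)
    if X is None:
        Xd, auto_names = np.ones((len(y), 1)), ["intercept"]
    else:
        Xd, auto_names = _add_intercept(X)
    names = list(names) if names is not None else auto_names
    if len(np.unique(y)) < 2:
        raise ValueError("response must contain both states")
    if Xd.shape[1] > 1 and np.any(np.std(Xd[:, 1:], axis=0) == 0):
        raise ValueError("constant predictor column")
    if y.shape[0] != tree.n_tips:
        raise ValueError("response must align with the tree's tips")

    D = tree.patristic_matrix()
    T = tree.height
    lo, hi = alpha_bounds if alpha_bounds is not None else (1e-4 / T, 1e4 / T)

    state = {}

    def profile(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        Sigma = _latent_cov(D, alpha)
        n_ = Sigma.shape[0]
        jitter = 1e-10 * float(np.mean(np.diag(Sigma)) + 1.0)
        L = cho_factor(Sigma + jitter * np.eye(n_), lower=True,
                       check_finite=False)
        Sinv = cho_solve(L, np.eye(n_), check_finite=False)
        beta0 = state.get("beta")
        u0 = state.get("u")
        beta, u, w, conv = _inner_fit(y, Xd, Sinv, beta0, u0,
                                      penalized=penalized)
        ll = _laplace_loglik(y, Xd, beta, u, w, Sinv, Sigma)
        # alpha is selected on the unpenalised likelihood: the Firth term
        # only stabilises the inner coefficient fit, and including it here
        # would tilt alpha by an amount that depends on the model dimension,
        # breaking full/reduced nesting in likelihood-ratio comparisons
        state.update(beta=beta, u=u, w=w, ll=ll, conv=conv,
                     alpha=alpha, Sigma=Sigma)
        return -ll

    grid = np.linspace(np.log(lo), np.log(hi), n_grid)
    vals = np.array([profile(g) for g in grid])
    best = int(np.argmin(vals))
    g_lo = grid[max(best - 1, 0)]
    g_hi = grid[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(profile, bounds=(g_lo, g_hi),
                                   method="bounded",
                                   options={"xatol": 0.02, "maxiter": 25})
    # refit at the winner (the last profile() call may not be the optimum)
    candidates = [(vals[best], grid[best]), (res.fun, res.x)]
    _, log_alpha_hat = min(candidates)
    profile(float(log_alpha_hat))

    alpha = state["alpha"]
    beta, u, w = state["beta"], state["u"], state["w"]
    Sigma = state["Sigma"]
    # marginal covariance of beta-hat: GLS form on the working scale
    A = np.diag(1.0 / w) + Sigma
    Ainv_X = np.linalg.solve(A, Xd)
    cov = np.linalg.inv(Xd.T @ Ainv_X)
    se = np.sqrt(np.diag(cov))
    at_bound = alpha <= lo * (1 + 1e-3) or alpha >= hi * (1 - 1e-3)
    return PhyloGLMFit(
        beta=beta, se=se, names=names, logLik=float(state["ll"]),
        n=len(y), converged=bool(state["conv"]), alpha=float(alpha),
        alpha_bounds=(lo, hi), alpha_at_bound=bool(at_bound), u=u,
        method="phyloglm-firth" if penalized else "phyloglm",
    )


# --------------------------------------------------------------------------
# phylogenetic linear regression (Brownian GLS)


def fit_phylolm(y, X, tree: Phylogeny, names=None) -> PhyloLMFit:
    """GLS under Brownian covariance V = sigma2 * C, ML estimates."""
    y = np.asarray(y, dtype=float)
    Xd, auto_names = _add_intercept(X)
    names = list(names) if names is not None else auto_names
    if y.shape[0] != tree.n_tips:
        raise ValueError("response must align with the tree's tips")
    n = len(y)
    C = tree.vcv_matrix()
    L = cho_factor(C + 1e-12 * tree.height * np.eye(n), lower=True)
    Ci_X = cho_solve(L, Xd)
    Ci_y = cho_solve(L, y)
    XtCiX = Xd.T @ Ci_X
    try:
        beta = np.linalg.solve(XtCiX, Xd.T @ Ci_y)
    except np.linalg.LinAlgError:
        raise ValueError("singular GLS normal equations") from None
    r = y - Xd @ beta
    sigma2 = float(r @ cho_solve(L, r)) / n
    if sigma2 <= 0:
        raise ValueError("degenerate residual variance")
    logdet_C = 2.0 * np.sum(np.log(np.diag(L[0])))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet_C + n)
    cov = sigma2 * np.linalg.inv(XtCiX)
    se = np.sqrt(np.diag(cov))
    return PhyloLMFit(beta=beta, se=se, names=names, logLik=float(ll),
                      n=n, converged=True, sigma2=sigma2)


# --------------------------------------------------------------------------
# partial likelihood-ratio R2 and model comparison


def partial_r2lik(logLik_full: float, logLik_reduced: float, n: int) -> float:
    """Likelihood-ratio R2 of a full vs reduced model:
    ``1 - exp(-(2/n) * (llf - llr))``."""
    if n <= 0:
        raise ValueError("n must be positive")
    delta = logLik_full - logLik_reduced
    if delta < 0:
        warnings.warn("full model has lower log-likelihood than reduced model")
    return float(1.0 - np.exp(-2.0 * delta / n))


def lr_test(logLik_full: float, logLik_reduced: float, df: int = 1) -> float:
    """p-value of the likelihood-ratio chi-square test."""
    stat = max(0.0, 2.0 * (logLik_full - logLik_reduced))
    return float(stats.chi2.sf(stat, df=df))


def partial_r2_table(y, design: pd.DataFrame, tree: Phylogeny) -> pd.DataFrame:
    """Partial R2lik per model component (each predictor + phylogeny).

    For a covariate, the reduced model is the phylogenetic fit without that
    covariate; for the phylogeny component, the reduced model is ordinary
    logistic regression with the identical predictors.  p-values are from
    likelihood-ratio tests with 1 df per removed component.

    All fits here are unpenalised maximum likelihood: evaluating the
    likelihood at Firth-shrunk estimates would introduce a model-dimension-
    dependent offset that breaks the nesting of full and reduced models.
    """
    cols = list(design.columns)
    full = fit_phyloglm(y, design, tree, penalized=False)
    rows = {}
    for col in cols:
        reduced = fit_phyloglm(y, design.drop(columns=[col]), tree,
                               penalized=False)
        rows[col] = {
            "r2lik": partial_r2lik(full.logLik, reduced.logLik, full.n),
            "p": lr_test(full.logLik, reduced.logLik, df=1),
        }
    nophylo = fit_logistic(y, design)
    rows["phylogeny"] = {
        "r2lik": partial_r2lik(full.logLik, nophylo.logLik, full.n),
        "p": lr_test(full.logLik, nophylo.logLik, df=1),
    }
    table = pd.DataFrame(rows).T
    table.attrs["full_logLik"] = full.logLik
    return table


def compare_models(fits: dict | list) -> pd.DataFrame:
    """AIC, delta-AIC and Akaike weights for fits on identical data."""
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(f"model{i}", f) for i, f in enumerate(fits)]
    if len(items) < 2:
        raise ValueError("need at least 2 fits to compare")
    ns = {f.n for _, f in items}
    if len(ns) != 1:
        raise ValueError("fits were made on different numbers of observations")
    aic = np.array([2.0 * f.n_params - 2.0 * f.logLik for _, f in items])
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    return pd.DataFrame(
        {"k": [f.n_params for _, f in items], "logLik": [f.logLik for _, f in items],
         "aic": aic, "delta_aic": delta, "akaike_weight": w},
        index=[name for name, _ in items],
    )
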