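"""Bayesian linear regression with a shrinkage prior and Savage-Dickey Bayes factors.

All variables are standardized before fitting.  Slope coefficients get
independent Normal(0, prior_sd^2) priors (default SD 0.5) and the
intercept a flat prior (handled by centering).  The residual SD is set by
empirical Bayes — the value maximizing the marginal likelihood of the
centered data — after which the coefficient posterior is the exact
Gaussian conditional.  BF01 is the Savage-Dickey density ratio: posterior
over prior density of the tested coefficient at zero; values below 1
favor the alternative.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "Posterior",
    "BFResult",
    "standardize",
    "conjugate_posterior",
    "fit_bayes_linear",
    "savage_dickey",
    "categorize_bf",
]

PRIOR_SD = 0.5
_Z95 = stats.norm.ppf(0.975)

# BF01 interpretation scale: (upper bound, label) pairs on each side of 1.
_ALTERNATIVE_SCALE = [(0.01, "extreme"), (0.03, "very strong"), (0.1, "strong"), (0.3, "moderate"), (1.0, "anecdotal")]
_NULL_SCALE = [(3.0, "anecdotal"), (10.0, "moderate"), (30.0, "strong"), (100.0, "very strong")]


@dataclasses.dataclass
class Posterior:
    beta_mean: float
    beta_sd: float
    ci95: tuple[float, float]
    sigma_hat: float
    name: str = "predictor"

    def __post_init__(self):
        if self.beta_sd <= 0:
            raise ValueError("beta_sd must be positive")


@dataclasses.dataclass
class BFResult:
    bf01: float
    category: str


def standardize(values: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a constant (or non-finite) vector")
    return (x - x.mean()) / sd


def conjugate_posterior(
    XtX: np.ndarray, Xty: np.ndarray, sigma: float, prior_sd: float = PRIOR_SD
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gaussian posterior of the coefficients for known residual SD.

    Posterior precision = X'X / sigma^2 + I / prior_sd^2.
    Returns (mean vector, covariance matrix).
    """
    XtX = np.atleast_2d(np.asarray(XtX, dtype=float))
    Xty = np.atleast_1d(np.asarray(Xty, dtype=float))
    p = XtX.shape[0]
    precision = XtX / sigma**2 + np.eye(p) / prior_sd**2
    cov = np.linalg.inv(precision)
    mean = cov @ (Xty / sigma**2)
    return mean, cov


def _profile_sigma(X: np.ndarray, y: np.ndarray, prior_sd: float) -> float:
    """Residual SD maximizing the marginal likelihood of y | sigma.

    Marginal model: y ~ N(0, sigma^2 I + prior_sd^2 X X'); evaluated via
    the eigendecomposition of X'X so each candidate sigma costs O(p^3).
    """
    n, p = X.shape
    evals, V = np.linalg.eigh(X.T @ X)
    u = V.T @ (X.T @ y)
    yty = float(y @ y)
    ps2 = prior_sd**2

    def neg_logml(log_sigma: float) -> float:
        s2 = np.exp(2.0 * log_sigma)
        logdet = (n - p) * np.log(s2) + np.sum(np.log(s2 + ps2 * evals))
        quad = (yty - np.sum(u**2 / (evals + s2 / ps2))) / s2
        return 0.5 * (n * np.log(2 * np.pi) + logdet + quad)

    res = minimize_scalar(neg_logml, bounds=(np.log(1e-4), np.log(10.0)), method="bounded")
    return float(np.exp(res.x))


def fit_bayes_linear(
    dependent: np.ndarray,
    predictor: np.ndarray,
    covariates: np.ndarray | None = None,
    prior_sd: float = PRIOR_SD,
    sigma: float | None = None,
    standardize_inputs: bool = True,
    name: str = "predictor",
) -> Posterior:
    """Posterior for the predictor's standardized coefficient.

    ``covariates`` (e.g. age and sex) are entered alongside the predictor
    and share the same shrinkage prior; only the predictor coefficient is
    summarized.  With ``sigma=None`` the residual SD is set by empirical
    Bayes; passing a value fixes it (used by closed-form oracles).
    """
    y = np.asarray(dependent, dtype=float).ravel()
    x = np.asarray(predictor, dtype=float).ravel()
    if covariates is None:
        C = np.empty((y.size, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != y.size:
            C = C.T
    n = y.size
    if x.size != n or C.shape[0] != n:
        raise ValueError("dependent, predictor and covariates disagree on n")
    p = 1 + C.shape[1]
    if n <= p + 2:
        raise ValueError(f"need n > {p + 2} observations, got {n}")

    if standardize_inputs:
        y = standardize(y)
        x = standardize(x)
        C = np.column_stack([standardize(C[:, j]) for j in range(C.shape[1])]) if C.shape[1] else C
    else:
        y = y - y.mean()
        x = x - x.mean()
        C = C - C.mean(axis=0) if C.shape[1] else C

    X = np.column_stack([x, C]) if C.shape[1] else x[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")

    sigma_hat = _profile_sigma(X, y, prior_sd) if sigma is None else float(sigma)
    mean, cov = conjugate_posterior(X.T @ X, X.T @ y, sigma_hat, prior_sd)
    beta_mean = float(mean[0])
    beta_sd = float(np.sqrt(cov[0, 0]))
    return Posterior(
        beta_mean=beta_mean,
        beta_sd=beta_sd,
        ci95=(beta_mean - _Z95 * beta_sd, beta_mean + _Z95 * beta_sd),
        sigma_hat=sigma_hat,
        name=name,
    )


def savage_dickey(posterior: Posterior, prior_sd: float = PRIOR_SD) -> BFResult:
    """BF01 = posterior density of the coefficient at 0 over prior density at 0."""
    if posterior.beta_sd <= 0:
        raise ValueError("posterior SD must be positive")
    log_post0 = stats.norm.logpdf(0.0, loc=posterior.beta_mean, scale=posterior.beta_sd)
    log_prior0 = stats.norm.logpdf(0.0, loc=0.0, scale=prior_sd)
    bf01 = float(np.exp(log_post0 - log_prior0))
    return BFResult(bf01=bf01, category=categorize_bf(bf01))


def categorize_bf(bf01: float) -> str:
    """Evidence label on the two-sided interpretation scale (BF01 orientation)."""
    if not np.isfinite(bf01) or bf01 <= 0:
        raise ValueError(f"bf01 must be a positive finite number, got {bf01}")
    if bf01 == 1.0:
        return "equipoise"
    if bf01 < 1.0:
        for bound, label in _ALTERNATIVE_SCALE:
            if bf01 < bound:
                return f"{label} (alternative)"
        return "anecdotal (alternative)"
    for bound, label in _NULL_SCALE:
        if bf01 <= bound:
            return f"{label} (null)"
    return "extreme (null)"
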