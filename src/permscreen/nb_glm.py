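"""Null negative-binomial / Poisson GLM fitting (log link).

The null model regresses a response count vector on technical factors only.
The fit exposes exactly the quantities the score test consumes: fitted means,
the weight vector w_i = mu_i / (1 + mu_i / theta) and the working residual
Y_i / mu_i - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "NullFit",
    "DegenerateResponseError",
    "fit_null_glm",
    "estimate_theta",
    "nb_loglik",
    "THETA_MIN",
    "THETA_MAX",
]

THETA_MIN = 0.01
THETA_MAX = 1000.0


class DegenerateResponseError(ValueError):
    """Response vector unusable for GLM fitting (e.g. all zeros)."""


@dataclass
class NullFit:
    """Fitted null GLM and the derived score-test ingredients.

    ``theta`` is ``numpy.inf`` for a Poisson fit, in which case ``w`` equals
    ``mu`` exactly.
    """

    beta: np.ndarray
    theta: float
    mu: np.ndarray
    w: np.ndarray
    working_resid: np.ndarray
    family: str  # "nb" | "poisson"
    converged: bool
    loglik: float
    n_iter: int
    theta_at_bound: bool = False
    deviance_trace: list[float] | None = None


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Log-likelihood of NB(mu, size=theta); Poisson when theta is inf."""
    if np.isinf(theta):
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
        if np.isinf(theta):
            dev = term - (y - mu)
        else:
            dev = term - (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * np.sum(dev))


def estimate_theta(
    y: np.ndarray,
    mu: np.ndarray,
    theta_min: float = THETA_MIN,
    theta_max: float = THETA_MAX,
) -> tuple[float, bool]:
    """Maximum-likelihood NB size given fitted means.

    Returns ``(theta, at_upper_bound)``; the flag is set when the data are
    equidispersed (or underdispersed) so the MLE diverges and the estimate is
    clamped to ``theta_max`` (effectively Poisson).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)

    def neg_ll(log_theta: float) -> float:
        return -nb_loglik(y, mu, float(np.exp(log_theta)))

    res = minimize_scalar(
        neg_ll,
        bounds=(np.log(theta_min), np.log(theta_max)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    theta = float(np.exp(res.x))
    at_upper = theta >= theta_max * (1 - 1e-3)
    if at_upper:
        theta = theta_max
    return theta, at_upper


def _irls(
    y: np.ndarray,
    Z: np.ndarray,
    theta: float,
    max_iter: int,
    tol: float,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """IRLS for the log-link NB/Poisson mean model at fixed theta.

    Step-halving keeps the deviance monotone nonincreasing.
    """
    n = len(y)
    if beta0 is None:
        mu = np.full(n, max(y.mean(), 1e-8))
        eta = np.log(mu) * np.ones(n)
        beta = np.zeros(Z.shape[1])
        beta[0] = np.log(mu[0])
        eta = Z @ beta
        mu = np.exp(eta)
    else:
        beta = beta0.copy()
        eta = Z @ beta
        mu = np.exp(np.clip(eta, -30, 30))
    dev = _deviance(y, mu, theta)
    trace = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu if np.isinf(theta) else mu / (1.0 + mu / theta)
        zwork = eta + (y - mu) / mu
        WZ = Z * w[:, None]
        try:
            beta_new = np.linalg.solve(Z.T @ WZ, WZ.T @ zwork)
        except np.linalg.LinAlgError:
            break
        # step-halving on deviance increase
        step = 1.0
        for _ in range(30):
            beta_try = beta + step * (beta_new - beta)
            eta_try = np.clip(Z @ beta_try, -30, 30)
            mu_try = np.exp(eta_try)
            dev_try = _deviance(y, mu_try, theta)
            if np.isfinite(dev_try) and dev_try <= dev + 1e-12:
                break
            step /= 2.0
        else:
            break
        rel = abs(dev - dev_try) / (abs(dev_try) + 0.1)
        beta, eta, mu, dev = beta_try, eta_try, mu_try, dev_try
        trace.append(dev)
        if rel < tol:
            converged = True
            break
    return beta, mu, converged, it, trace


def fit_null_glm(
    y: np.ndarray,
    Z: np.ndarray,
    family: str = "nb",
    theta: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> NullFit:
    """Fit the null GLM of the count vector on the covariate matrix.

    Parameters
    ----------
    family
        ``"nb"`` with ``theta=None`` estimates the size parameter by
        alternating IRLS mean updates with a univariate MLE; ``"nb"`` with a
        fixed ``theta`` skips estimation; ``"poisson"`` sets theta to
        infinity.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if y.ndim != 1 or Z.ndim != 2 or len(y) != Z.shape[0]:
        raise ValueError("y must be 1-D and row-aligned with Z")
    if not np.all(np.isfinite(Z)):
        raise ValueError("covariate matrix has non-finite entries")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must contain nonnegative integers")
    if not np.any(y > 0):
        raise DegenerateResponseError("response is identically zero")

    if family == "poisson":
        theta_val: float = np.inf
        estimate = False
    elif family == "nb":
        if theta is not None:
            if not theta > 0:
                raise ValueError("theta must be positive")
            theta_val = float(theta)
            estimate = False
        else:
            theta_val = np.inf  # start from Poisson means
            estimate = True
    else:
        raise ValueError(f"unknown family {family!r}")

    beta, mu, converged, it, trace = _irls(y, Z, theta_val, max_iter, tol)
    theta_at_bound = False
    if estimate:
        # alternate theta MLE and IRLS refits until theta stabilizes
        theta_val, theta_at_bound = estimate_theta(y, mu)
        for _ in range(10):
            beta, mu, converged, it2, trace = _irls(y, Z, theta_val, max_iter, tol, beta0=beta)
            it += it2
            theta_new, theta_at_bound = estimate_theta(y, mu)
            if abs(np.log(theta_new) - np.log(theta_val)) < 1e-4:
                theta_val = theta_new
                break
            theta_val = theta_new
        if theta_at_bound:
            theta_val = THETA_MAX

    family_tag = "poisson" if np.isinf(theta_val) else "nb"
    if not converged:
        logger.warning("IRLS did not converge; falling back to Poisson fit")
        theta_val = np.inf
        beta, mu, conv2, it2, trace = _irls(y, Z, theta_val, max_iter, tol)
        it += it2
        family_tag = "poisson"
        converged = False

    w = mu if np.isinf(theta_val) else mu / (1.0 + mu / theta_val)
    working_resid = y / mu - 1.0
    return NullFit(
        beta=beta,
        theta=theta_val,
        mu=mu,
        w=w,
        working_resid=working_resid,
        family=family_tag,
        converged=converged,
        loglik=nb_loglik(y, mu, theta_val),
        n_iter=it,
        theta_at_bound=theta_at_bound,
        deviance_trace=trace,
    )
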