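"""Fast weighted logistic regression by Newton-Raphson.

Shared numerical core for unpenalized refits, AIC backward elimination,
imputation sub-models and recalibration.  Kept deliberately small: dense
problems with at most a few dozen parameters, where forming X'WX directly
is cheaper than any iterative solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

# |linear predictor| beyond which a fitted probability is numerically 0/1;
# used as a (quasi-)separation heuristic.
_SEPARATION_BOUND = 30.0


class ConvergenceError(RuntimeError):
    """Raised when an unpenalized logistic fit fails (separation or divergence)."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


@dataclass
class LogisticFit:
    """Result of a weighted logistic regression.

    ``params[0]`` is the intercept; ``cov`` is the inverse observed
    information (used for posterior-style coefficient perturbation).
    """

    params: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.params.size


def _design(X: np.ndarray, add_intercept: bool) -> np.ndarray:
    if not add_intercept:
        return X
    return np.column_stack([np.ones(X.shape[0]), X])


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    add_intercept: bool = True,
    ridge: float = 0.0,
    max_iter: int = 60,
    tol: float = 1e-9,
    check_separation: bool = True,
) -> LogisticFit:
    """Fit logit(P(y=1)) = Z b by Newton-Raphson with step halving.

    Parameters
    ----------
    X : (n, k) covariate matrix (without intercept column).
    y : (n,) binary outcome in {0, 1}.
    weights : optional nonnegative case weights.
    ridge : L2 penalty added to the slopes' diagonal of the information
        matrix; a small value stabilizes separated fits.
    check_separation : raise :class:`ConvergenceError` when the fit did not
        converge or drifted into a (quasi-)separated solution.
    """
    Z = _design(np.asarray(X, dtype=float), add_intercept)
    y = np.asarray(y, dtype=float)
    n, k = Z.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative weights")

    pen = np.zeros(k)
    if ridge > 0:
        pen[:] = ridge
        if add_intercept:
            pen[0] = 0.0

    b = np.zeros(k)
    ybar = float(np.average(y, weights=w)) if w.sum() > 0 else 0.5
    ybar = min(max(ybar, 1e-9), 1 - 1e-9)
    if add_intercept:
        b[0] = np.log(ybar / (1 - ybar))

    def _loglik(beta: np.ndarray) -> float:
        eta = Z @ beta
        # log(1 + e^eta) computed stably
        ll = y * eta - np.logaddexp(0.0, eta)
        return float(np.sum(w * ll)) - 0.5 * float(np.sum(pen * beta**2))

    ll = _loglik(b)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Z @ b
        mu = expit(eta)
        v = w * mu * (1 - mu)
        g = Z.T @ (w * (y - mu)) - pen * b
        H = (Z * v[:, None]).T @ Z + np.diag(pen)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step halving for monotone log-likelihood
        t = 1.0
        for _ in range(25):
            b_new = b + t * step
            ll_new = _loglik(b_new)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        delta = float(np.max(np.abs(b_new - b)))
        b, ll = b_new, ll_new
        if delta < tol:
            converged = True
            break

    eta = Z @ b
    if check_separation and ridge == 0.0:
        if not converged or np.max(np.abs(eta)) > _SEPARATION_BOUND:
            raise ConvergenceError(
                "logistic fit failed to converge (possible separation)"
            )

    mu = expit(eta)
    v = w * mu * (1 - mu)
    H = (Z * v[:, None]).T @ Z + np.diag(pen)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return LogisticFit(params=b, cov=cov, loglik=ll, converged=converged, n_iter=it)


def fit_logistic_stabilized(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    add_intercept: bool = True,
    ridge: float = 1e-3,
) -> LogisticFit:
    """Logistic fit that falls back to a ridge-stabilized fit on separation."""
    try:
        return fit_logistic(X, y, weights, add_intercept=add_intercept)
    except (ConvergenceError, np.linalg.LinAlgError):
        logger.warning("separation in logistic sub-model; ridge-stabilized fit used")
        return fit_logistic(
            X, y, weights, add_intercept=add_intercept, ridge=ridge,
            check_separation=False,
        )
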