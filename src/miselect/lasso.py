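"""L1-penalized logistic regression with cross-validated penalty choice.

The solver minimizes the weighted negative average log-likelihood plus
``lambda * ||beta||_1`` with an unpenalized intercept.  Covariates are
standardized internally to weighted mean 0 and variance 1 and the
coefficients are returned on the original scale.  The penalty grid is
log-spaced from the smallest lambda that zeroes every slope down to
``lambda_min_ratio`` times it, and the path is solved with warm starts.

Penalty selection follows the deviance-based 10-fold cross validation of
glmnet: ``lambda_opt`` minimizes the mean held-out binomial deviance,
``lambda_1se`` is the largest penalty whose mean deviance stays within one
standard error of that minimum.  On stacked multiply imputed data the folds
are assigned per subject, so a subject's m rows are held out together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._cd import cd_path
from .simdata import as_rng

__all__ = [
    "PenaltyPath",
    "CVCurve",
    "PenaltyChoice",
    "fit_path",
    "cv_curve",
    "choose_penalty",
    "cv_lasso",
]

#: convergence tolerance on the maximum coefficient change
TOL = 1e-7
N_LAMBDAS = 100
LAMBDA_MIN_RATIO = 1e-3
_MAX_IRLS = 50
_MAX_CD = 1000


@dataclass
class PenaltyPath:
    """Solutions along a decreasing penalty grid (original covariate scale)."""

    lambdas: np.ndarray
    intercepts: np.ndarray
    coefs: np.ndarray  # (n_lambdas, p)

    def at(self, lam: float) -> tuple[float, np.ndarray]:
        """Intercept and slopes at a grid value."""
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        return float(self.intercepts[i]), self.coefs[i].copy()


@dataclass
class CVCurve:
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    fold_assignment: np.ndarray
    group_ids: np.ndarray | None = None
    fold_deviance: np.ndarray | None = None  # (k, n_lambdas)


@dataclass
class PenaltyChoice:
    lambda_opt: float
    lambda_1se: float

    def __post_init__(self):
        if self.lambda_1se < self.lambda_opt:
            raise ValueError("lambda_1se must be >= lambda_opt")

    def get(self, rule: str) -> float:
        if rule in ("optimal", "opt"):
            return self.lambda_opt
        if rule == "1se":
            return self.lambda_1se
        raise ValueError(f"unknown penalty rule {rule!r}")


def _prepare(X, y, weights):
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary in {0, 1}")
    n = y.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    w = w / w.mean()  # normalize to mean 1
    return X, y, w


def _standardize(X, w):
    n = X.shape[0]
    mu = (w @ X) / n
    Xc = X - mu
    sd = np.sqrt((w @ (Xc**2)) / n)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return np.ascontiguousarray(Xc / sd), mu, sd


def lambda_max(X, y, weights=None) -> float:
    """Smallest penalty at which every slope is zero."""
    X, y, w = _prepare(X, y, weights)
    Xs, _, _ = _standardize(X, w)
    ybar = (w @ y) / y.size
    score = Xs.T @ (w * (y - ybar)) / y.size
    return float(np.max(np.abs(score)))


def _auto_grid(X, y, w) -> np.ndarray:
    Xs, _, _ = _standardize(X, w)
    ybar = (w @ y) / y.size
    lmax = float(np.max(np.abs(Xs.T @ (w * (y - ybar)) / y.size)))
    lmax = max(lmax, 1e-10)
    return np.logspace(np.log10(lmax), np.log10(lmax * LAMBDA_MIN_RATIO), N_LAMBDAS)


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    lambdas: np.ndarray | None = None,
    tol: float = TOL,
) -> PenaltyPath:
    """Solve the weighted lasso-logistic path.

    When ``lambdas`` is omitted an automatic grid of ``N_LAMBDAS`` log-spaced
    values from lambda_max down to ``LAMBDA_MIN_RATIO * lambda_max`` is used.
    """
    X, y, w = _prepare(X, y, weights)
    if lambdas is None:
        lambdas = _auto_grid(X, y, w)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        if lambdas.size > 1 and np.any(np.diff(lambdas) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")
    Xs, mu, sd = _standardize(X, w)
    XT = np.ascontiguousarray(Xs.T)
    b0s, Bs = cd_path(XT, y, w, lambdas, tol, _MAX_IRLS, _MAX_CD)
    coefs = Bs / sd
    intercepts = b0s - coefs @ mu
    return PenaltyPath(lambdas=lambdas, intercepts=intercepts, coefs=coefs)


def assign_folds(
    y: np.ndarray,
    k: int,
    group_ids: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-row fold ids; stratified by outcome at the subject level.

    With ``group_ids`` all rows of a subject share one fold (the subject's
    outcome is constant across its rows by construction).
    """
    n = y.size
    if group_ids is None:
        group_ids = np.arange(n)
    groups, first = np.unique(group_ids, return_index=True)
    gy = y[first]
    gfold = np.empty(groups.size, dtype=np.int64)
    start = rng.integers(0, k)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(gy == cls)
        rng.shuffle(idx)
        # deal round-robin with a random starting fold so fold sizes balance
        gfold[idx] = (np.arange(idx.size) + start) % k
    pos = np.searchsorted(groups, group_ids)
    return gfold[pos]


def _fold_deviance(path: PenaltyPath, X, y, w) -> np.ndarray:
    """Weighted mean binomial deviance of each path solution on (X, y, w)."""
    eta = path.intercepts[None, :] + X @ path.coefs.T  # (n, nl)
    p = np.clip(expit(eta), 1e-15, 1 - 1e-15)
    ll = y[:, None] * np.log(p) + (1 - y[:, None]) * np.log(1 - p)
    return -2.0 * (w @ ll) / w.sum()


def cv_curve(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    k: int = 10,
    group_ids: np.ndarray | None = None,
    rng: int | np.random.Generator | None = None,
    lambdas: np.ndarray | None = None,
) -> CVCurve:
    """Single k-fold cross-validated deviance along the penalty grid."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = as_rng(rng)
    X, y, w = _prepare(X, y, weights)
    if lambdas is None:
        lambdas = _auto_grid(X, y, w)
    folds = assign_folds(y, k, group_ids, rng)
    dev = np.empty((k, lambdas.size))
    for f in range(k):
        test = folds == f
        train = ~test
        path = fit_path(X[train], y[train], w[train], lambdas=lambdas)
        dev[f] = _fold_deviance(path, X[test], y[test], w[test])
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(k)
    return CVCurve(
        lambdas=lambdas,
        mean_deviance=mean,
        se_deviance=se,
        fold_assignment=folds,
        group_ids=None if group_ids is None else np.asarray(group_ids),
        fold_deviance=dev,
    )


def choose_penalty(curve: CVCurve) -> PenaltyChoice:
    """Optimal and 1-se penalties from a CV curve.

    Deviance ties on the grid are broken toward the larger penalty (the grid
    decreases, so the first minimizer wins).
    """
    if curve.lambdas.size == 0:
        raise ValueError("empty CV curve")
    i_opt = int(np.argmin(curve.mean_deviance))
    thresh = curve.mean_deviance[i_opt] + curve.se_deviance[i_opt]
    i_1se = int(np.flatnonzero(curve.mean_deviance <= thresh)[0])
    return PenaltyChoice(
        lambda_opt=float(curve.lambdas[i_opt]),
        lambda_1se=float(curve.lambdas[i_1se]),
    )


@dataclass
class CVLassoFit:
    """Full-data path together with its CV curve and chosen penalties."""

    path: PenaltyPath
    curve: CVCurve
    choice: PenaltyChoice

    def coef(self, rule: str) -> tuple[float, np.ndarray]:
        return self.path.at(self.choice.get(rule))


def cv_lasso(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    k: int = 10,
    group_ids: np.ndarray | None = None,
    rng: int | np.random.Generator | None = None,
) -> CVLassoFit:
    """Fit the full-data path and choose the penalty by k-fold CV."""
    rng = as_rng(rng)
    Xp, yp, wp = _prepare(X, y, weights)
    lambdas = _auto_grid(Xp, yp, wp)
    curve = cv_curve(Xp, yp, wp, k=k, group_ids=group_ids, rng=rng, lambdas=lambdas)
    path = fit_path(Xp, yp, wp, lambdas=lambdas)
    return CVLassoFit(path=path, curve=curve, choice=choose_penalty(curve))
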