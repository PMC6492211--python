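"""Multiple imputation by chained equations.

Continuous variables are imputed by predictive mean matching (PMM) with a
Bayesian-perturbed linear regression; binary variables by logistic-regression
draws with coefficients perturbed from a normal approximation to their
posterior.  Every imputation model regresses the incomplete variable on all
other covariates plus the (fully observed) binary outcome.  Incomplete
variables are visited in order of increasing missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._glm import fit_logistic_stabilized
from .simdata import CompleteDataset, IncompleteDataset, as_rng

logger = logging.getLogger(__name__)

__all__ = ["ImputationSet", "impute", "pmm_draw", "logistic_draw"]


@dataclass
class ImputationSet:
    """m completed copies of one incomplete dataset (shared outcome)."""

    completed: list[CompleteDataset]
    m: int
    source: IncompleteDataset

    def __post_init__(self):
        if self.m != len(self.completed):
            raise ValueError("m does not match number of completed datasets")

    @property
    def y(self) -> np.ndarray:
        return self.source.y

    @property
    def p(self) -> int:
        return self.source.p


def _bayes_linear_draw(
    Xo: np.ndarray, yo: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit with a draw from the approximate coefficient
    posterior (normal-inverse-chi-square).  Returns (beta_hat, beta_star).
    Singular designs are ridge-stabilized."""
    n, k = Xo.shape
    XtX = Xo.T @ Xo
    Xty = Xo.T @ yo
    ridge = 0.0
    for _ in range(8):
        try:
            A = XtX + ridge * np.eye(k)
            beta_hat = np.linalg.solve(A, Xty)
            Ainv = np.linalg.inv(A)
            break
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10, 1e-8 * max(np.trace(XtX) / k, 1.0))
    resid = yo - Xo @ beta_hat
    df = max(n - k, 1)
    sigma2_hat = float(resid @ resid) / df
    sigma2_star = sigma2_hat * df / max(rng.chisquare(df), 1e-12)
    L = np.linalg.cholesky((Ainv + Ainv.T) / 2 + 1e-12 * np.eye(k))
    beta_star = beta_hat + np.sqrt(sigma2_star) * (L @ rng.standard_normal(k))
    return beta_hat, beta_star


def pmm_draw(
    target: np.ndarray,
    design: np.ndarray,
    donors: int = 5,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Fill the missing entries of ``target`` by predictive mean matching.

    A Bayesian-perturbed linear regression of ``target`` on ``design`` is
    fitted on the observed cases; predicted means for observed cases use the
    point estimate and for missing cases the perturbed draw (type-1
    matching).  Each missing case copies the observed value of one of the
    ``donors`` nearest cases by predicted mean, chosen uniformly.
    """
    rng = as_rng(rng)
    target = np.asarray(target, dtype=float)
    mis = np.isnan(target)
    if not mis.any():
        return target.copy()
    obs = ~mis
    if obs.sum() < donors:
        raise ValueError("fewer observed cases than donors")
    Z = np.column_stack([np.ones(design.shape[0]), design])
    beta_hat, beta_star = _bayes_linear_draw(Z[obs], target[obs], rng)
    pred_obs = Z[obs] @ beta_hat
    pred_mis = Z[mis] @ beta_star
    # nearest observed predictions per missing case
    d = np.abs(pred_mis[:, None] - pred_obs[None, :])
    k = min(donors, pred_obs.size)
    near = np.argpartition(d, k - 1, axis=1)[:, :k]
    pick = near[np.arange(near.shape[0]), rng.integers(0, k, near.shape[0])]
    out = target.copy()
    out[mis] = target[obs][pick]
    return out


def logistic_draw(
    target: np.ndarray,
    design: np.ndarray,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Fill the missing entries of a binary ``target`` by logistic draws.

    Coefficients are drawn from a normal approximation to their posterior,
    N(beta_hat, Cov_hat); missing entries are Bernoulli draws from the
    implied probabilities.  If only one class is observed the constant class
    is imputed.
    """
    rng = as_rng(rng)
    target = np.asarray(target, dtype=float)
    mis = np.isnan(target)
    if not mis.any():
        return target.copy()
    obs = ~mis
    yo = target[obs]
    out = target.copy()
    classes = np.unique(yo)
    if classes.size < 2:
        logger.warning("one-class binary target; constant imputation used")
        out[mis] = classes[0]
        return out
    fit = fit_logistic_stabilized(design[obs], yo)
    L = np.linalg.cholesky(
        (fit.cov + fit.cov.T) / 2 + 1e-10 * np.eye(fit.cov.shape[0])
    )
    beta_star = fit.params + L @ rng.standard_normal(fit.params.size)
    Zm = np.column_stack([np.ones(mis.sum()), design[mis]])
    p = expit(Zm @ beta_star)
    out[mis] = (rng.random(mis.sum()) < p).astype(float)
    return out


def _is_binary(values: np.ndarray) -> bool:
    v = values[~np.isnan(values)]
    return bool(np.isin(v, (0.0, 1.0)).all())


def impute(
    data: IncompleteDataset,
    m: int = 10,
    cycles: int = 5,
    donors: int = 5,
    rng: int | np.random.Generator | None = None,
) -> ImputationSet:
    """Chained-equations multiple imputation.

    Returns ``m`` completed datasets.  Missing entries are initialized by
    random draws from the observed values of their column; each of
    ``cycles`` sweeps then re-imputes every incomplete variable (ascending
    missingness order) from a model on all other covariates plus y.
    """
    rng = as_rng(rng)
    X0, y = data.X, data.y
    if np.isnan(y).any():
        raise ValueError("outcome must be fully observed")
    n, p = X0.shape
    mis_count = np.isnan(X0).sum(axis=0)
    if np.any(mis_count == n):
        raise ValueError("a variable has no observed values and cannot be imputed")
    incomplete = np.flatnonzero(mis_count > 0)
    incomplete = incomplete[np.argsort(mis_count[incomplete], kind="stable")]
    binary = {j: _is_binary(X0[:, j]) for j in incomplete}

    completed: list[CompleteDataset] = []
    for _ in range(m):
        X = X0.copy()
        for j in incomplete:
            mis = np.isnan(X0[:, j])
            obs_vals = X0[~mis, j]
            X[mis, j] = rng.choice(obs_vals, size=mis.sum(), replace=True)
        for _cycle in range(cycles):
            for j in incomplete:
                mis = np.isnan(X0[:, j])
                others = [k for k in range(p) if k != j]
                design = np.column_stack([X[:, others], y])
                col = X0[:, j].copy()  # NaN at missing entries
                col[~mis] = X0[~mis, j]
                if binary[j]:
                    X[:, j] = logistic_draw(col, design, rng)
                else:
                    X[:, j] = pmm_draw(col, design, donors=donors, rng=rng)
        completed.append(CompleteDataset(X=X, y=y.copy()))
    return ImputationSet(completed=completed, m=m, source=data)
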