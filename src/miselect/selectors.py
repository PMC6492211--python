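"""The eight model-building strategies on multiply imputed data.

Reference models:
  FULL   - all covariates, unpenalized fit on the stacked data.
  TrueC  - the true covariates only (simulation benchmark), same fit.

Selection on bootstrap data (inclusion-frequency methods):
  BBeF - backward elimination by AIC on bootstrap resamples of each
         completed dataset; keep variables selected in >= 50% of the m*B
         fits; refit per completion and average.
  BLaF - as BBeF but with lasso selection, the penalty re-chosen by CV per
         bootstrap sample (1-se or optimal rule).

Lasso on the original MI data:
  SepAv  - lasso per completion; average the m coefficient vectors; a
           variable is kept when active in any completion.
  SepAvF - as SepAv but kept only when active in >= 50% of completions.
  Stack  - lasso on the stacked data (uniform 1/m row weights), penalty by
           subject-grouped CV.
  StackW - as Stack with per-observation weights proportional to the
           subject's fraction of observed covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._cd import newton_logistic
from ._glm import _SEPARATION_BOUND, ConvergenceError, fit_logistic
from .lasso import cv_lasso
from .mice import ImputationSet
from .simdata import as_rng

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "PooledModel",
    "InclusionFrequencies",
    "StackedData",
    "backward_eliminate_aic",
    "bootstrap_inclusion",
    "select_by_frequency",
    "select_sepav",
    "make_stack",
    "select_stacked",
    "fit_reference",
]

METHODS = ("FULL", "TrueC", "BBeF", "BLaF", "SepAv", "SepAvF", "Stack", "StackW")


@dataclass
class PooledModel:
    """A pooled prognostic model: one intercept and one slope vector.

    Pooling happens before prediction; ``slopes`` carries zeros for
    unselected covariates so predictions depend only on (intercept, slopes).
    """

    intercept: float
    slopes: np.ndarray
    method: str
    penalty_rule: str = "none"  # {"optimal", "1se", "none"}
    recalibration: str = "none"  # {"none", "score", "refit"}
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.slopes != 0.0)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.slopes

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(X))


@dataclass
class InclusionFrequencies:
    """Fraction of the m*B bootstrap fits in which each covariate appears."""

    freqs: np.ndarray
    B: int
    m: int
    n_fits: int
    n_failures: int = 0
    selections: list[np.ndarray] | None = None  # per-fit active sets

    def __post_init__(self):
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("frequencies must lie in [0, 1]")


@dataclass
class StackedData:
    """The m completions concatenated, with subject ids and row weights."""

    X: np.ndarray
    y: np.ndarray
    subject_id: np.ndarray
    row_weight: np.ndarray


# ---------------------------------------------------------------------------
# backward elimination

def _aic_fit(Z: np.ndarray, y: np.ndarray, w: np.ndarray, step: int) -> float:
    """AIC of an unpenalized logistic fit (numba Newton); raises on
    non-convergence or (quasi-)separation."""
    beta, ll, converged, maxeta = newton_logistic(Z, y, w, 60, 1e-9)
    if not converged or maxeta > _SEPARATION_BOUND:
        raise ConvergenceError(
            "logistic fit failed to converge (possible separation)", step=step
        )
    return -2.0 * ll + 2.0 * Z.shape[1]


def backward_eliminate_aic(
    X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Greedy backward elimination with AIC as the stopping rule.

    Starting from all covariates, repeatedly removes the single covariate
    whose removal most decreases the AIC; stops when no removal decreases
    it.  The intercept is always retained.  Raises
    :class:`ConvergenceError` (carrying the step index) when any required
    fit fails, e.g. under separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    current = list(range(X.shape[1]))
    Z = np.column_stack([np.ones(n), X])
    best_aic = _aic_fit(Z, y, w, step=0)
    step = 0
    while current:
        step += 1
        cand_aic, cand_j = np.inf, None
        for j in current:
            cols = [0] + [c + 1 for c in current if c != j]
            aic = _aic_fit(np.ascontiguousarray(Z[:, cols]), y, w, step)
            if aic < cand_aic:
                cand_aic, cand_j = aic, j
        if cand_aic < best_aic:
            best_aic = cand_aic
            current.remove(cand_j)
        else:
            break
    return np.asarray(current, dtype=int)


# ---------------------------------------------------------------------------
# bootstrap inclusion frequencies

_LASSO_BASES = {"lasso_1se": "1se", "lasso_opt": "optimal"}


def _bootstrap_selections(
    imps: ImputationSet,
    B: int,
    base: str,
    rng: np.random.Generator,
    k: int = 10,
) -> tuple[dict[str, list[np.ndarray]], int]:
    """Per-fit active sets over the m*B bootstrap fits.

    For lasso bases both penalty rules are read off the same CV run, so one
    pass serves BLaF and BLaFo.  Returns ({rule: selections}, n_failures).
    """
    n = imps.source.n
    lasso = base in _LASSO_BASES or base == "lasso"
    rules = ("1se", "optimal") if lasso else ("aic",)
    out: dict[str, list[np.ndarray]] = {r: [] for r in rules}
    failures = 0
    for comp in imps.completed:
        for _b in range(B):
            idx = rng.integers(0, n, n)
            Xb, yb = comp.X[idx], comp.y[idx]
            if yb.min() == yb.max():
                failures += 1
                continue
            if lasso:
                fit = cv_lasso(Xb, yb, k=k, rng=rng)
                for r in rules:
                    _, coef = fit.coef(r)
                    out[r].append(np.flatnonzero(coef))
            else:
                try:
                    out["aic"].append(backward_eliminate_aic(Xb, yb))
                except ConvergenceError:
                    failures += 1
    return out, failures


def bootstrap_inclusion(
    imps: ImputationSet,
    B: int,
    base: str = "lasso_1se",
    rng: int | np.random.Generator | None = None,
    k: int = 10,
) -> InclusionFrequencies:
    """Covariate inclusion frequencies over m*B bootstrap fits.

    ``base`` is one of ``lasso_1se``, ``lasso_opt`` (penalty re-chosen by CV
    per bootstrap sample) or ``aic_backward``.  Failed fits are logged and
    excluded from the denominator.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if base not in (*_LASSO_BASES, "aic_backward"):
        raise ValueError(f"unknown base selector {base!r}")
    rng = as_rng(rng)
    sels, failures = _bootstrap_selections(imps, B, base, rng, k=k)
    rule = _LASSO_BASES.get(base, "aic")
    selections = sels[rule]
    if failures:
        logger.warning("%d of %d bootstrap fits failed and were excluded",
                       failures, imps.m * B)
    return _tally(selections, imps, B, failures)


def _tally(
    selections: list[np.ndarray], imps: ImputationSet, B: int, failures: int
) -> InclusionFrequencies:
    counts = np.zeros(imps.p)
    for sel in selections:
        counts[sel] += 1
    n_fits = len(selections)
    if n_fits == 0:
        raise ConvergenceError("all bootstrap fits failed")
    return InclusionFrequencies(
        freqs=counts / n_fits, B=B, m=imps.m, n_fits=n_fits,
        n_failures=failures, selections=selections,
    )


def select_by_frequency(
    freqs: InclusionFrequencies,
    imps: ImputationSet,
    threshold: float = 0.5,
    method: str = "BLaF",
    penalty_rule: str = "none",
) -> PooledModel:
    """Final model from inclusion frequencies.

    Keeps covariates with frequency >= threshold (inclusive), refits the
    selected set unpenalized on each completion and averages intercept and
    slopes across the m fits.
    """
    selected = np.flatnonzero(freqs.freqs >= threshold)
    if selected.size == 0:
        logger.warning("empty selection at threshold %.2f; intercept-only model",
                       threshold)
    model = _refit_averaged(imps, selected, method=method)
    model.penalty_rule = penalty_rule
    model.info["frequencies"] = freqs.freqs
    model.info["threshold"] = threshold
    return model


def _refit_averaged(
    imps: ImputationSet, selected: np.ndarray, method: str
) -> PooledModel:
    """Unpenalized fit of ``selected`` on each completion, Rubin-pooled."""
    p = imps.p
    icepts, slopes = [], []
    for comp in imps.completed:
        if selected.size:
            fit = fit_logistic(comp.X[:, selected], comp.y)
            icepts.append(fit.params[0])
            s = np.zeros(p)
            s[selected] = fit.params[1:]
        else:
            ybar = comp.y.mean()
            icepts.append(np.log(ybar / (1 - ybar)))
            s = np.zeros(p)
        slopes.append(s)
    return PooledModel(
        intercept=float(np.mean(icepts)),
        slopes=np.mean(slopes, axis=0),
        method=method,
    )


# ---------------------------------------------------------------------------
# lasso on the original MI data

def _per_completion_lasso(
    imps: ImputationSet, rng: np.random.Generator, k: int = 10
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """CV lasso per completion; returns {rule: (intercepts, coef matrix)}."""
    out = {}
    fits = [cv_lasso(c.X, c.y, k=k, rng=rng) for c in imps.completed]
    for rule in ("1se", "optimal"):
        icepts = np.array([f.coef(rule)[0] for f in fits])
        coefs = np.vstack([f.coef(rule)[1] for f in fits])
        out[rule] = (icepts, coefs)
    return out


def _pool_separate(
    icepts: np.ndarray,
    coefs: np.ndarray,
    require_majority: bool,
    method: str,
    penalty_rule: str,
) -> PooledModel:
    active = coefs != 0.0
    freq = active.mean(axis=0)
    if require_majority:
        selected = freq >= 0.5
    else:
        selected = freq > 0.0
    slopes = coefs.mean(axis=0)  # zeros from inactive completions included
    slopes[~selected] = 0.0
    return PooledModel(
        intercept=float(icepts.mean()),
        slopes=slopes,
        method=method,
        penalty_rule=penalty_rule,
        info={"frequencies": freq},
    )


def select_sepav(
    imps: ImputationSet,
    penalty_rule: str = "1se",
    require_majority: bool = False,
    rng: int | np.random.Generator | None = None,
    k: int = 10,
) -> PooledModel:
    """Separate-MI lasso pooling (SepAv / SepAvF).

    Lasso with its own CV per completion; coefficients averaged over all m
    completions (zeros included).  SepAv keeps the union of active sets,
    SepAvF keeps variables active in at least half of the completions.
    """
    rng = as_rng(rng)
    fits = _per_completion_lasso(imps, rng, k=k)
    icepts, coefs = fits[penalty_rule]
    method = "SepAvF" if require_majority else "SepAv"
    return _pool_separate(icepts, coefs, require_majority, method, penalty_rule)


def make_stack(imps: ImputationSet, weighting: str = "uniform") -> StackedData:
    """Concatenate the m completions.

    ``uniform``: every row weighs 1/m.  ``missingness``: row weight
    (1/m) * (number of observed covariates of the subject in the source
    data) / p, constant across the subject's m rows.
    """
    m, p = imps.m, imps.p
    n = imps.source.n
    X = np.vstack([c.X for c in imps.completed])
    y = np.tile(imps.source.y, m)
    subject = np.tile(np.arange(n), m)
    if weighting == "uniform":
        w_subj = np.full(n, 1.0 / m)
    elif weighting == "missingness":
        w_subj = (1.0 / m) * imps.source.n_observed_covariates() / p
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return StackedData(X=X, y=y, subject_id=subject, row_weight=w_subj[subject])


def _stacked_cv(
    imps: ImputationSet, weighting: str, rng: np.random.Generator, k: int = 10
):
    """Stack the completions and run one subject-grouped CV lasso."""
    stack = make_stack(imps, weighting)
    fit = cv_lasso(
        stack.X, stack.y, weights=stack.row_weight,
        group_ids=stack.subject_id, k=k, rng=rng,
    )
    return stack, fit


def _stacked_model(stack, fit, weighting: str, penalty_rule: str) -> PooledModel:
    b0, coef = fit.coef(penalty_rule)
    method = "StackW" if weighting == "missingness" else "Stack"
    return PooledModel(
        intercept=b0, slopes=coef, method=method, penalty_rule=penalty_rule
    )


def select_stacked(
    imps: ImputationSet,
    weighting: str = "uniform",
    penalty_rule: str = "1se",
    rng: int | np.random.Generator | None = None,
    k: int = 10,
) -> PooledModel:
    """Lasso on the stacked MI data (Stack / StackW).

    The CV folds are assigned per subject, so each subject's m rows are
    held out together.
    """
    rng = as_rng(rng)
    stack, fit = _stacked_cv(imps, weighting, rng, k=k)
    return _stacked_model(stack, fit, weighting, penalty_rule)


def fit_reference(
    imps: ImputationSet,
    which: str = "FULL",
    true_idx: np.ndarray | None = None,
) -> PooledModel:
    """FULL / TrueC reference models: unpenalized logistic fit on the
    stacked data with uniform 1/m weights, over the named covariate set."""
    if which == "FULL":
        selected = np.arange(imps.p)
    elif which == "TrueC":
        if true_idx is None:
            raise ValueError("TrueC requires the true covariate indices")
        selected = np.asarray(true_idx, dtype=int)
    else:
        raise ValueError(f"unknown reference model {which!r}")
    stack = make_stack(imps, "uniform")
    fit = fit_logistic(stack.X[:, selected], stack.y, stack.row_weight)
    slopes = np.zeros(imps.p)
    slopes[selected] = fit.params[1:]
    return PooledModel(intercept=float(fit.params[0]), slopes=slopes, method=which)
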