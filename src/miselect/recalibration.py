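"""Recalibration of over-shrunk 1-se lasso models on the derivation data.

Recalibration by score refits the outcome on the model's linear predictor
Z, logit(y) = gamma0 + gamma1 * Z, and rescales every slope by gamma1 — the
relative effects are preserved, so the discrimination (AUC) of the model is
unchanged.  Recalibration by selected variables refits the selected set by
unpenalized maximum likelihood.  For separate-MI methods the refit is done
per completion and the coefficients averaged; for stacked methods once on
the weighted stacked data.  Models with the optimal penalty are considered
optimally shrunk and must not be recalibrated.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from ._glm import fit_logistic
from .mice import ImputationSet
from .selectors import PooledModel, StackedData, _refit_averaged, make_stack

logger = logging.getLogger(__name__)

__all__ = ["recalibrate_by_score", "recalibrate_by_refit"]

_STACKED_METHODS = ("Stack", "StackW", "FULL", "TrueC")


def _check_rule(model: PooledModel) -> None:
    if model.penalty_rule == "optimal":
        raise ValueError(
            "recalibration is not offered for optimal-penalty models; the "
            "optimal penalty is considered optimally shrunk"
        )


def _as_stack(model: PooledModel, data: ImputationSet | StackedData) -> StackedData:
    if isinstance(data, StackedData):
        return data
    weighting = "missingness" if model.method == "StackW" else "uniform"
    return make_stack(data, weighting)


def recalibrate_by_score(
    model: PooledModel, data: ImputationSet | StackedData
) -> PooledModel:
    """Rescale all coefficients by the slope of logit(y) ~ score.

    New slopes are gamma1 * beta_j; the new intercept gamma0 + gamma1 * b0,
    so the recalibrated linear predictor is exactly gamma0 + gamma1 * Z.
    """
    _check_rule(model)
    if model.selected.size == 0:
        logger.warning("intercept-only model; score recalibration is a no-op")
        return replace(model, recalibration="score")

    if model.method in _STACKED_METHODS or isinstance(data, StackedData):
        stack = _as_stack(model, data)
        z = model.linear_predictor(stack.X)
        if np.ptp(z) < 1e-12:
            logger.warning("degenerate (constant) score; recalibration skipped")
            return replace(model, recalibration="score")
        fit = fit_logistic(z[:, None], stack.y, stack.row_weight)
        g0, g1 = float(fit.params[0]), float(fit.params[1])
    else:
        g0s, g1s = [], []
        for comp in data.completed:
            z = model.linear_predictor(comp.X)
            if np.ptp(z) < 1e-12:
                logger.warning("degenerate (constant) score; recalibration skipped")
                return replace(model, recalibration="score")
            fit = fit_logistic(z[:, None], comp.y)
            g0s.append(fit.params[0])
            g1s.append(fit.params[1])
        g0, g1 = float(np.mean(g0s)), float(np.mean(g1s))

    return PooledModel(
        intercept=g0 + g1 * model.intercept,
        slopes=g1 * model.slopes,
        method=model.method,
        penalty_rule=model.penalty_rule,
        recalibration="score",
        info={**model.info, "gamma0": g0, "gamma1": g1},
    )


def recalibrate_by_refit(
    model: PooledModel, data: ImputationSet | StackedData
) -> PooledModel:
    """Unpenalized refit of the selected variables (selection unchanged)."""
    _check_rule(model)
    selected = model.selected
    if selected.size == 0:
        raise ValueError("cannot refit an empty selected set")
    if model.method in _STACKED_METHODS or isinstance(data, StackedData):
        stack = _as_stack(model, data)
        fit = fit_logistic(stack.X[:, selected], stack.y, stack.row_weight)
        slopes = np.zeros(model.slopes.size)
        slopes[selected] = fit.params[1:]
        out = PooledModel(
            intercept=float(fit.params[0]), slopes=slopes,
            method=model.method, penalty_rule=model.penalty_rule,
        )
    else:
        out = _refit_averaged(data, selected, method=model.method)
        out.penalty_rule = model.penalty_rule
    out.recalibration = "refit"
    out.info = dict(model.info)
    return out
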