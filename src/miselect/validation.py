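"""Enhanced-bootstrap optimism correction for MI model-building pipelines.

The whole modelling process — imputation included — is repeated inside each
bootstrap resample of the incomplete data.  Each bootstrap model is scored
on its own bootstrap imputations (apparent_b) and on the original
imputations (test_b); the mean of apparent_b - test_b over bootstrap
samples and imputations estimates the optimism, which is subtracted from
the apparent performance of the model built on the original data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._glm import ConvergenceError
from .evaluation import auc, brier
from .mice import ImputationSet, impute
from .selectors import PooledModel
from .simdata import IncompleteDataset, as_rng

logger = logging.getLogger(__name__)

__all__ = ["OptimismEstimate", "optimism_correct"]

_METRICS: dict[str, Callable] = {"auc": auc, "brier": brier}

#: a pipeline builds a pooled model from an imputation set
Pipeline = Callable[[ImputationSet, np.random.Generator], PooledModel]


@dataclass
class OptimismEstimate:
    metric: str
    apparent: float
    optimism: float
    B: int
    effective_B: int
    per_bootstrap: list[tuple[float, float]] = field(default_factory=list)

    @property
    def corrected(self) -> float:
        return self.apparent - self.optimism


def _mean_metric(model: PooledModel, imps: ImputationSet, metric: Callable) -> float:
    vals = [metric(model.predict(c.X), c.y) for c in imps.completed]
    return float(np.mean(vals))


def _resample(data: IncompleteDataset, rng: np.random.Generator) -> IncompleteDataset:
    idx = rng.integers(0, data.n, data.n)
    return IncompleteDataset(X=data.X[idx], y=data.y[idx], R=data.R[idx])


def optimism_correct(
    data: IncompleteDataset,
    pipeline: Pipeline,
    B: int = 100,
    m: int = 10,
    metrics: tuple[str, ...] = ("auc", "brier"),
    cycles: int = 5,
    rng=None,
) -> dict[str, OptimismEstimate]:
    """Optimism-corrected apparent performance of a modelling pipeline.

    ``pipeline(imps, rng)`` must run the full selection procedure on an
    imputation set and return the pooled model.  Bootstrap resampling is at
    subject level on the incomplete data, before imputation; the original
    imputations are reused as the test bed for every bootstrap model.
    Failed bootstrap replicates are logged and skipped (``effective_B``
    reports the number retained).
    """
    rng = as_rng(rng)
    seeds = np.random.SeedSequence(rng.integers(0, 2**31 - 1)).spawn(2 * B + 2)
    imps0 = impute(data, m=m, cycles=cycles, rng=np.random.default_rng(seeds[0]))
    model0 = pipeline(imps0, np.random.default_rng(seeds[1]))

    apparent = {
        name: _mean_metric(model0, imps0, _METRICS[name]) for name in metrics
    }
    diffs: dict[str, list[float]] = {name: [] for name in metrics}
    per_b: dict[str, list[tuple[float, float]]] = {name: [] for name in metrics}
    effective = 0
    for b in range(B):
        try:
            boot = _resample(data, rng)
            imps_b = impute(
                boot, m=m, cycles=cycles, rng=np.random.default_rng(seeds[2 + 2 * b])
            )
            model_b = pipeline(imps_b, np.random.default_rng(seeds[3 + 2 * b]))
            for name in metrics:
                fn = _METRICS[name]
                app_b = _mean_metric(model_b, imps_b, fn)
                test_b = _mean_metric(model_b, imps0, fn)
                diffs[name].append(app_b - test_b)
                per_b[name].append((app_b, test_b))
            effective += 1
        except (ConvergenceError, ValueError) as exc:
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
    if effective == 0:
        raise ConvergenceError("every bootstrap replicate failed")
    return {
        name: OptimismEstimate(
            metric=name,
            apparent=apparent[name],
            optimism=float(np.mean(diffs[name])),
            B=B,
            effective_B=effective,
            per_bootstrap=per_b[name],
        )
        for name in metrics
    }
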