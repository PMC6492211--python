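"""Scenario runner: replicate the simulation comparison at configurable scale.

One replicate = generate a dataset under the chosen mechanism, impose MAR
missingness, impute m times, build every requested method variant, and
score each pooled model on a fresh fully observed validation set.  CV runs
are shared across variants of the same family (the two penalty rules are
read off one CV curve; recalibrated variants reuse the base model), which
keeps the per-replicate cost near the minimum the design admits.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from ._glm import ConvergenceError
from .evaluation import PerformanceRecord, evaluate_external
from .mice import ImputationSet, impute
from .recalibration import recalibrate_by_refit, recalibrate_by_score
from .selectors import (
    PooledModel,
    _bootstrap_selections,
    _per_completion_lasso,
    _pool_separate,
    _stacked_cv,
    _stacked_model,
    _tally,
    fit_reference,
    select_by_frequency,
)
from .simdata import MechanismSpec, build_mechanism, generate_complete, impose_mar

logger = logging.getLogger(__name__)

__all__ = ["build_models", "run_replicate", "run_scenario", "write_results"]

#: method variants: (method, penalty_rule, recalibration)
DEFAULT_VARIANTS: tuple[tuple[str, str, str], ...] = (
    ("FULL", "none", "none"),
    ("TrueC", "none", "none"),
    ("BBeF", "none", "none"),
    ("BLaF", "1se", "none"),
    ("BLaF", "optimal", "none"),
    *[
        (meth, rule, recal)
        for meth in ("SepAv", "SepAvF", "Stack", "StackW")
        for rule, recal in (
            ("1se", "none"), ("1se", "score"), ("1se", "refit"),
            ("optimal", "none"),
        )
    ],
)


def build_models(
    imps: ImputationSet,
    variants: Iterable[tuple[str, str, str]] = DEFAULT_VARIANTS,
    true_idx: np.ndarray | None = None,
    B: int = 100,
    threshold: float = 0.5,
    rng=None,
) -> dict[tuple[str, str, str], PooledModel | Exception]:
    """Build every requested (method, penalty, recalibration) variant.

    Expensive intermediates (bootstrap selections, per-completion lasso
    fits, stacked fits) are computed once per family.  A variant whose fit
    fails (separation in a refit, all bootstrap fits failing) maps to the
    raised :class:`ConvergenceError` instead of a model.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    variants = list(variants)
    out: dict[tuple[str, str, str], PooledModel | Exception] = {}

    def wants(method, rule=None):
        return [v for v in variants if v[0] == method and (rule is None or v[1] == rule)]

    def attempt(key, fn):
        try:
            out[key] = fn()
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            logger.warning("variant %s failed: %s", key, exc)
            out[key] = exc if isinstance(exc, ConvergenceError) else ConvergenceError(str(exc))

    for which in ("FULL", "TrueC"):
        for key in wants(which):
            attempt(key, lambda w=which: fit_reference(imps, w, true_idx))

    if wants("BBeF"):
        def _bbef():
            sels, failures = _bootstrap_selections(imps, B, "aic_backward", rng)
            freqs = _tally(sels["aic"], imps, B, failures)
            return select_by_frequency(freqs, imps, threshold, method="BBeF")
        attempt(("BBeF", "none", "none"), _bbef)

    blaf = wants("BLaF")
    if blaf:
        sels, failures = _bootstrap_selections(imps, B, "lasso", rng)
        for key in blaf:
            rule = key[1]
            def _blaf(rule=rule):
                freqs = _tally(sels[rule], imps, B, failures)
                return select_by_frequency(
                    freqs, imps, threshold, method="BLaF", penalty_rule=rule
                )
            attempt(key, _blaf)

    sep_variants = wants("SepAv") + wants("SepAvF")
    if sep_variants:
        fits = _per_completion_lasso(imps, rng)
        base: dict[tuple[str, str], PooledModel] = {}
        for meth, majority in (("SepAv", False), ("SepAvF", True)):
            for rule in {v[1] for v in wants(meth)}:
                icepts, coefs = fits[rule]
                base[(meth, rule)] = _pool_separate(
                    icepts, coefs.copy(), majority, meth, rule
                )
        for key in sep_variants:
            meth, rule, recal = key
            attempt(key, lambda m=base[(key[0], key[1])], r=recal: _recal(m, imps, r))

    for meth, weighting in (("Stack", "uniform"), ("StackW", "missingness")):
        rules = {v[1] for v in wants(meth)}
        if not rules:
            continue
        stack, fit = _stacked_cv(imps, weighting, rng)
        for rule in rules:
            model = _stacked_model(stack, fit, weighting, rule)
            for key in wants(meth, rule):
                attempt(key, lambda m=model, r=key[2], s=stack: _recal(m, s, r))
    return out


def _recal(model: PooledModel, data, recalibration: str) -> PooledModel:
    if recalibration == "none":
        return model
    if recalibration == "score":
        return recalibrate_by_score(model, data)
    if recalibration == "refit":
        return recalibrate_by_refit(model, data)
    raise ValueError(f"unknown recalibration {recalibration!r}")


def run_replicate(
    mech: MechanismSpec,
    n: int,
    miss: float,
    m: int = 10,
    variants=DEFAULT_VARIANTS,
    B: int = 100,
    threshold: float = 0.5,
    n_val: int = 5000,
    cycles: int = 5,
    replicate: int = 0,
    rng=None,
) -> list[PerformanceRecord]:
    """One full replicate: generate, delete, impute, select, validate."""
    seeds = np.random.SeedSequence(rng).spawn(4) if isinstance(rng, int) else None
    if seeds is not None:
        rngs = [np.random.default_rng(s) for s in seeds]
    else:
        g = np.random.default_rng() if rng is None else rng
        rngs = [g] * 4
    full = generate_complete(mech, n, rngs[0])
    incomplete = impose_mar(full, mech, miss, rngs[0])
    imps = impute(incomplete, m=m, cycles=cycles, rng=rngs[1])
    models = build_models(
        imps, variants, true_idx=mech.true_idx, B=B, threshold=threshold,
        rng=rngs[2],
    )
    records = []
    for (meth, rule, recal), model in models.items():
        if isinstance(model, Exception):
            records.append(PerformanceRecord(
                method=meth, penalty_rule=rule, recalibration=recal,
                replicate=replicate, auc=np.nan, brier=np.nan,
                n_true_selected=0, n_noise_selected=0, n_selected=0,
                failed=True,
            ))
        else:
            records.append(evaluate_external(
                model, mech, n_val=n_val, rng=rngs[3], replicate=replicate
            ))
    return records


def run_scenario(config) -> pd.DataFrame:
    """Run ``config.reps`` replicates and return the tidy results frame.

    Per-replicate seeds are derived from the master seed with a spawn-key
    scheme, so results do not depend on execution order.
    """
    mech = build_mechanism(config.mechanism)
    variants = config.variant_tuples()
    rows = []
    for rep in range(config.reps):
        # deterministic per-replicate children independent of loop order
        child = np.random.SeedSequence(entropy=config.seed, spawn_key=(rep,))
        recs = run_replicate(
            mech, config.n, config.miss, m=config.m, variants=variants,
            B=config.B, threshold=config.threshold, n_val=config.n_val,
            cycles=config.cycles, replicate=rep,
            rng=np.random.default_rng(child),
        )
        rows.extend(r.to_dict() for r in recs)
    return pd.DataFrame(rows)


_RESULT_COLUMNS = [
    "replicate", "method", "penalty_rule", "recalibration",
    "auc", "brier", "n_true_selected", "n_noise_selected", "n_selected",
    "failed",
]


def write_results(records: pd.DataFrame | list, path) -> None:
    """Write the tidy one-row-per-replicate-and-variant CSV."""
    if isinstance(records, list):
        records = pd.DataFrame([r.to_dict() for r in records])
    if records.empty:
        records = pd.DataFrame(columns=_RESULT_COLUMNS)
    records = records[_RESULT_COLUMNS]
    records.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
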