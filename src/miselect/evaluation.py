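"""External predictive evaluation and scenario-level aggregation.

Predictive performance is assessed on fully observed validation data drawn
fresh from the same generating mechanism: AUC (Mann-Whitney, ties count
1/2) for discrimination and the Brier score (mean squared error of the
predicted probability) for overall accuracy.  Selection performance is the
number of selected true and noise covariates.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .selectors import PooledModel
from .simdata import MechanismSpec, generate_complete

__all__ = [
    "auc",
    "brier",
    "PerformanceRecord",
    "evaluate_external",
    "evaluate_on",
    "summarize_scenario",
]


def auc(pred: np.ndarray, y: np.ndarray) -> float:
    """Probability that a random event outranks a random non-event."""
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("AUC requires both outcome classes")
    return float(roc_auc_score(y, np.asarray(pred, dtype=float)))


def brier(pred: np.ndarray, y: np.ndarray) -> float:
    """Mean squared difference between predicted probability and outcome."""
    pred = np.asarray(pred, dtype=float)
    if np.any((pred < 0) | (pred > 1)):
        raise ValueError("predictions must be probabilities in [0, 1]")
    return float(np.mean((pred - np.asarray(y, dtype=float)) ** 2))


@dataclass
class PerformanceRecord:
    method: str
    penalty_rule: str
    recalibration: str
    replicate: int
    auc: float
    brier: float
    n_true_selected: int
    n_noise_selected: int
    n_selected: int
    failed: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def selection_counts(
    model: PooledModel, true_idx: np.ndarray, p: int
) -> tuple[int, int]:
    sel = set(model.selected.tolist())
    true = set(np.asarray(true_idx).tolist())
    return len(sel & true), len(sel - true)


def evaluate_on(
    model: PooledModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """(AUC, Brier) of a pooled model on a fixed dataset."""
    pred = model.predict(X)
    return auc(pred, y), brier(pred, y)


def evaluate_external(
    model: PooledModel,
    mech: MechanismSpec,
    n_val: int = 5000,
    rng=None,
    replicate: int = 0,
) -> PerformanceRecord:
    """Generate a fully observed validation set under ``mech`` and score
    the model on it, together with true/noise selection counts."""
    val = generate_complete(mech, n_val, rng)
    a, b = evaluate_on(model, val.X, val.y)
    nt, nn = selection_counts(model, mech.true_idx, mech.p)
    return PerformanceRecord(
        method=model.method,
        penalty_rule=model.penalty_rule,
        recalibration=model.recalibration,
        replicate=replicate,
        auc=a,
        brier=b,
        n_true_selected=nt,
        n_noise_selected=nn,
        n_selected=nt + nn,
    )


def summarize_scenario(records: pd.DataFrame) -> pd.DataFrame:
    """Per-method-variant means, empirical SDs and normal-approximation CI
    half-widths (1.96 * SD / sqrt(reps)) of AUC/Brier and selection counts.

    ``records`` is the tidy frame written by the scenario runner (one row
    per replicate x method variant).
    """
    if isinstance(records, list):
        records = pd.DataFrame([r.to_dict() for r in records])
    ok = records[~records["failed"]]
    keys = ["method", "penalty_rule", "recalibration"]
    fail_counts = records[records["failed"]].groupby(keys).size()
    rows = []
    for key, g in ok.groupby(keys, sort=False):
        reps = len(g)
        row = dict(zip(keys, key))
        row["replicates"] = reps
        row["failures"] = int(fail_counts.get(key, 0))
        for metric in ("auc", "brier", "n_true_selected", "n_noise_selected"):
            x = g[metric].to_numpy(dtype=float)
            row[f"{metric}_mean"] = x.mean()
            row[f"{metric}_sd"] = x.std(ddof=1) if reps > 1 else 0.0
            row[f"{metric}_ci_halfwidth"] = (
                1.96 * row[f"{metric}_sd"] / np.sqrt(reps) if reps > 1 else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def empirical_epv(y: np.ndarray, n_parameters: int) -> float:
    """Events per estimated parameter; events = the smaller class count."""
    y = np.asarray(y, dtype=float)
    events = min(float((y == 1).sum()), float((y == 0).sum()))
    return events / n_parameters
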