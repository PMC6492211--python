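"""Model/Results facade over the selection toolkit.

:class:`MISelectLogit` wraps an incomplete tabular dataset with a binary
outcome; :meth:`MISelectLogit.fit` runs imputation (unless a precomputed
imputation set is supplied), the requested selection strategy, and optional
recalibration, returning a :class:`MISelectResults` with the pooled
coefficients, inclusion frequencies where applicable, and a summary table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import auc as _auc
from .evaluation import brier as _brier
from .mice import ImputationSet, impute
from .scenario import build_models
from .selectors import PooledModel
from .simdata import IncompleteDataset

__all__ = ["MISelectLogit", "MISelectResults"]


class MISelectLogit:
    """Variable selection for a logistic prognostic model on incomplete data.

    Parameters
    ----------
    endog : (n,) binary outcome, fully observed.
    exog : (n, p) covariates; missing entries as NaN.
    exog_names : optional covariate names (default x1..xp).
    m, cycles, donors : chained-equations imputation settings.

    Examples
    --------
    >>> model = MISelectLogit.from_dataframe(df, outcome="y")
    >>> res = model.fit(method="Stack", penalty="1se", recalibrate="refit",
    ...                 seed=7)
    >>> print(res.summary())
    """

    def __init__(self, endog, exog, exog_names=None, m: int = 10,
                 cycles: int = 5, donors: int = 5):
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("endog/exog have incompatible shapes")
        if np.isnan(y).any():
            raise ValueError("the outcome must be fully observed")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("the outcome must be binary in {0, 1}")
        self.data = IncompleteDataset(X=X, y=y, R=np.isnan(X))
        self.exog_names = (
            list(exog_names) if exog_names is not None
            else [f"x{j + 1}" for j in range(X.shape[1])]
        )
        if len(self.exog_names) != X.shape[1]:
            raise ValueError("exog_names length mismatch")
        self.m, self.cycles, self.donors = m, cycles, donors

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str = "y", **kwargs
                       ) -> "MISelectLogit":
        if outcome not in df.columns:
            raise ValueError(f"outcome column {outcome!r} not found")
        y = df[outcome].to_numpy(dtype=float)
        X = df.drop(columns=[outcome])
        return cls(y, X.to_numpy(dtype=float), exog_names=list(X.columns), **kwargs)

    def impute(self, seed=None) -> ImputationSet:
        return impute(self.data, m=self.m, cycles=self.cycles,
                      donors=self.donors, rng=seed)

    def fit(
        self,
        method: str = "Stack",
        penalty: str = "1se",
        recalibrate: str = "none",
        B: int = 100,
        threshold: float = 0.5,
        true_idx=None,
        imputations: ImputationSet | None = None,
        seed=None,
    ) -> "MISelectResults":
        """Impute (if needed), select, recalibrate, and pool."""
        rng = np.random.default_rng(seed)
        imps = imputations if imputations is not None else impute(
            self.data, m=self.m, cycles=self.cycles, donors=self.donors, rng=rng
        )
        rule = "none" if method in ("FULL", "TrueC", "BBeF") else penalty
        variant = (method, rule, recalibrate if rule == "1se" else "none")
        models = build_models(
            imps, [variant], true_idx=true_idx, B=B, threshold=threshold, rng=rng
        )
        model = models[variant]
        if isinstance(model, Exception):
            raise model
        return MISelectResults(model, self.exog_names, imps)


class MISelectResults:
    """Pooled selection results: coefficients, selected set, diagnostics."""

    def __init__(self, model: PooledModel, exog_names: list[str],
                 imputations: ImputationSet | None = None):
        self._model = model
        self.exog_names = list(exog_names)
        self.imputations = imputations

    @property
    def method(self) -> str:
        return self._model.method

    @property
    def penalty_rule(self) -> str:
        return self._model.penalty_rule

    @property
    def recalibration(self) -> str:
        return self._model.recalibration

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            np.concatenate([[self._model.intercept], self._model.slopes]),
            index=["const"] + self.exog_names,
            name="coef",
        )

    @property
    def selected_names(self) -> list[str]:
        return [self.exog_names[j] for j in self._model.selected]

    @property
    def inclusion_frequencies(self) -> pd.Series | None:
        freqs = self._model.info.get("frequencies")
        if freqs is None:
            return None
        return pd.Series(freqs, index=self.exog_names, name="inclusion_frequency")

    @property
    def pooled_model(self) -> PooledModel:
        return self._model

    def predict(self, exog) -> np.ndarray:
        return self._model.predict(np.asarray(exog, dtype=float))

    def evaluate(self, exog, endog) -> dict[str, float]:
        pred = self.predict(exog)
        return {"auc": _auc(pred, endog), "brier": _brier(pred, endog)}

    def summary(self) -> str:
        m = self._model
        lines = [
            "MI variable selection results",
            "=" * 46,
            f"method:           {m.method}",
            f"penalty rule:     {m.penalty_rule}",
            f"recalibration:    {m.recalibration}",
            f"selected:         {len(m.selected)} of {len(self.exog_names)} covariates",
        ]
        if self.imputations is not None:
            lines.append(f"imputations (m):  {self.imputations.m}")
        if "gamma1" in m.info:
            lines.append(
                f"score slope:      gamma0={m.info['gamma0']:+.4f}, "
                f"gamma1={m.info['gamma1']:.4f}"
            )
        lines.append("-" * 46)
        freqs = m.info.get("frequencies")
        header = f"{'variable':<14}{'coef':>10}"
        if freqs is not None:
            header += f"  {'freq':>6}"
        lines.append(header)
        lines.append(f"{'const':<14}{m.intercept:>10.4f}")
        for j, name in enumerate(self.exog_names):
            if m.slopes[j] == 0.0 and (freqs is None or freqs[j] == 0):
                continue
            row = f"{name:<14}{m.slopes[j]:>10.4f}"
            if freqs is not None:
                row += f"  {freqs[j]:>6.2f}"
            lines.append(row)
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        m = self._model
        payload = {
            "method": m.method,
            "penalty_rule": m.penalty_rule,
            "recalibration": m.recalibration,
            "intercept": m.intercept,
            "slopes": m.slopes.tolist(),
            "exog_names": self.exog_names,
            "selected": self.selected_names,
        }
        if "frequencies" in m.info:
            payload["inclusion_frequencies"] = np.asarray(
                m.info["frequencies"]
            ).tolist()
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "MISelectResults":
        data = json.loads(Path(path).read_text())
        model = PooledModel(
            intercept=float(data["intercept"]),
            slopes=np.asarray(data["slopes"], dtype=float),
            method=data["method"],
            penalty_rule=data["penalty_rule"],
            recalibration=data["recalibration"],
        )
        if "inclusion_frequencies" in data:
            model.info["frequencies"] = np.asarray(data["inclusion_frequencies"])
        return cls(model, data["exog_names"])
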