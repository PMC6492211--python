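"""Synthetic data generation for the two simulation mechanisms.

Both mechanisms draw latent multivariate-normal covariates (mean 0, unit
variance), dichotomize a fixed subset at 0 into {0, 1} indicators, and
generate a binary outcome from a sparse logistic model.  Missingness is
missing-at-random (MAR): for every variable in the incomplete set J, the
per-subject missingness probability follows a logistic model on the fully
observed covariates and the outcome, with the intercept solved numerically
so that the mean missingness probability equals the requested fraction.

Mechanism "one": p = 15 covariates with a sparse hand-specified correlation
structure; mechanism "two": p = 25 with AR(1) correlation (rho = 0.5) and
ten extra pure-noise continuous covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "MechanismSpec",
    "CompleteDataset",
    "IncompleteDataset",
    "build_mechanism",
    "generate_complete",
    "solve_alpha0",
    "impose_mar",
    "write_incomplete",
    "read_incomplete",
]


def as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class MechanismSpec:
    """Full description of a data-generating mechanism.

    All index sets are 0-based.  ``beta`` applies to the transformed
    covariates (binary columns in {0, 1}).
    """

    name: str
    p: int
    corr: np.ndarray
    binary_idx: tuple[int, ...]
    beta: np.ndarray
    intercept: float
    miss_idx: tuple[int, ...]
    miss_slope: float = 0.5
    _chol: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        C = np.asarray(self.corr, dtype=float)
        if C.shape != (self.p, self.p):
            raise ValueError("correlation matrix has wrong shape")
        if not np.allclose(C, C.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        try:
            chol = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix is not positive definite") from exc
        object.__setattr__(self, "_chol", chol)
        if set(self.miss_idx) & set(self.observed_idx):
            raise ValueError("miss_idx overlaps fully observed covariates")

    @property
    def true_idx(self) -> np.ndarray:
        """Indices of covariates with nonzero outcome coefficients."""
        return np.flatnonzero(self.beta != 0.0)

    @property
    def noise_idx(self) -> np.ndarray:
        return np.flatnonzero(self.beta == 0.0)

    @property
    def observed_idx(self) -> tuple[int, ...]:
        return tuple(j for j in range(self.p) if j not in self.miss_idx)

    @property
    def colnames(self) -> list[str]:
        return [f"x{j + 1}" for j in range(self.p)]


@dataclass
class CompleteDataset:
    """Fully observed covariates and binary outcome."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        if np.isnan(self.X).any():
            raise ValueError("complete dataset contains missing entries")

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class IncompleteDataset:
    """Covariate matrix with NaN markers, fully observed outcome, and the
    missingness-indicator matrix R (R[i, j] = True when X[i, j] is missing)."""

    X: np.ndarray
    y: np.ndarray
    R: np.ndarray

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def n_observed_covariates(self) -> np.ndarray:
        """Per-subject count of non-missing covariates."""
        return self.p - self.R.sum(axis=1)

    def complete_case_fraction(self) -> float:
        return float((~self.R.any(axis=1)).mean())


def _mechanism_one_corr() -> np.ndarray:
    C = np.eye(15)
    # 1-based pairs from the sparse correlation structure
    for a, b, r in [(1, 10, 0.5), (2, 6, 0.5), (7, 14, 0.5), (9, 13, 0.5),
                    (4, 8, -0.7), (7, 8, 0.3), (11, 12, 0.7)]:
        C[a - 1, b - 1] = C[b - 1, a - 1] = r
    return C


# binary (dichotomized) covariates x2,x4,x5,x9,x10,x11,x12 -> 0-based
_BINARY_1BASED = (2, 4, 5, 9, 10, 11, 12)
# nonzero coefficients on x4..x10
_TRUE_BETA_1BASED = {4: -0.5, 5: 0.5, 6: 0.5, 7: 0.5, 8: 1.0, 9: 1.0, 10: 1.5}


def build_mechanism(which: str) -> MechanismSpec:
    """Return the specification of mechanism ``"one"`` or ``"two"``."""
    if which == "one":
        p = 15
        corr = _mechanism_one_corr()
        miss_1based = (2, 5, 7, 8, 12, 14)
    elif which == "two":
        p = 25
        idx = np.arange(p)
        corr = 0.5 ** np.abs(idx[:, None] - idx[None, :])
        miss_1based = (2, 5, 7, 8, 12, 14, 16, 17, 19, 23)
    else:
        raise ValueError(f"unknown mechanism {which!r}; expected 'one' or 'two'")
    beta = np.zeros(p)
    for j, b in _TRUE_BETA_1BASED.items():
        beta[j - 1] = b
    return MechanismSpec(
        name=which,
        p=p,
        corr=corr,
        binary_idx=tuple(j - 1 for j in _BINARY_1BASED),
        beta=beta,
        intercept=-0.25,
        miss_idx=tuple(j - 1 for j in miss_1based),
    )


def generate_complete(
    mech: MechanismSpec, n: int, rng: int | np.random.Generator | None = None
) -> CompleteDataset:
    """Draw a fully observed dataset of size ``n`` under ``mech``.

    Latent covariates are multivariate normal with ``mech.corr``; columns in
    ``mech.binary_idx`` are replaced by 1(latent > 0); the outcome is
    Bernoulli with logit equal to ``mech.intercept + X beta`` on the
    transformed covariates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(rng)
    Z = rng.standard_normal((n, mech.p)) @ mech._chol.T
    X = Z
    for j in mech.binary_idx:
        X[:, j] = (Z[:, j] > 0).astype(float)
    lp = mech.intercept + X @ mech.beta
    y = (rng.random(n) < expit(lp)).astype(float)
    return CompleteDataset(X=X, y=y)


def solve_alpha0(miss: float, offsets: np.ndarray, tol: float = 1e-10) -> float:
    """Solve for the missingness-model intercept.

    Returns alpha0 such that mean_i expit(alpha0 + offsets_i) == miss, by a
    bracketing root finder.  ``offsets`` is the per-subject linear predictor
    of the missingness model without its intercept.
    """
    if not 0.0 < miss < 1.0:
        raise ValueError("miss must lie strictly between 0 and 1")
    offsets = np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")

    def f(a: float) -> float:
        return float(np.mean(expit(a + offsets))) - miss

    # mean expit is increasing in a; the root lies in this bracket (padded
    # so constant offsets do not collapse it)
    lo = logit(miss) - np.max(offsets) - 1e-6
    hi = logit(miss) - np.min(offsets) + 1e-6
    return float(brentq(f, lo, hi, xtol=tol))


def mar_offsets(data: CompleteDataset, mech: MechanismSpec) -> np.ndarray:
    """Linear predictor (without intercept) of the MAR missingness model:
    slope ``mech.miss_slope`` on every fully observed covariate and on y."""
    obs = list(mech.observed_idx)
    return mech.miss_slope * (data.X[:, obs].sum(axis=1) + data.y)


def impose_mar(
    data: CompleteDataset,
    mech: MechanismSpec,
    miss: float,
    rng: int | np.random.Generator | None = None,
) -> IncompleteDataset:
    """Delete entries of the variables in J under the MAR model.

    The per-subject probability p_i = expit(alpha0 + offsets_i) is shared by
    all variables in J; the indicators R[i, j] are drawn independently
    across j given p_i.
    """
    rng = as_rng(rng)
    offsets = mar_offsets(data, mech)
    alpha0 = solve_alpha0(miss, offsets)
    p_i = expit(alpha0 + offsets)
    R = np.zeros(data.X.shape, dtype=bool)
    for j in mech.miss_idx:
        R[:, j] = rng.random(data.n) < p_i
    X_obs = data.X.copy()
    X_obs[R] = np.nan
    return IncompleteDataset(X=X_obs, y=data.y.copy(), R=R)


# ---------------------------------------------------------------------------
# CSV serialization: header row, empty fields for missing entries, sidecar
# JSON with provenance.

def write_incomplete(
    data: IncompleteDataset,
    path: str | Path,
    meta: dict | None = None,
    colnames: list[str] | None = None,
) -> None:
    path = Path(path)
    p = data.X.shape[1]
    cols = colnames or [f"x{j + 1}" for j in range(p)]
    df = pd.DataFrame(data.X, columns=cols)
    df["y"] = data.y
    df.to_csv(path, index=False, na_rep="")
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_incomplete(path: str | Path) -> IncompleteDataset:
    df = pd.read_csv(path)
    if "y" not in df.columns:
        raise ValueError("dataset CSV must contain a 'y' column")
    y = df.pop("y").to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome column contains missing values")
    X = df.to_numpy(dtype=float)
    return IncompleteDataset(X=X, y=y, R=np.isnan(X))
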