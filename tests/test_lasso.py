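import subprocess
import sys

import numpy as np
import pytest
from scipy.special import expit

from miselect.lasso import (
    CVCurve,
    PenaltyChoice,
    _prepare,
    _standardize,
    assign_folds,
    choose_penalty,
    cv_curve,
    cv_lasso,
    fit_path,
    lambda_max,
)
from .conftest import make_logit_data


def kkt_violation(path, X, y, weights=None):
    """Worst subgradient violation over the whole path (standardized scale)."""
    Xp, yp, w = _prepare(X, y, weights)
    Xs, mu, sd = _standardize(Xp, w)
    n = yp.size
    worst = 0.0
    for i, lam in enumerate(path.lambdas):
        bs = path.coefs[i] * sd
        b0s = path.intercepts[i] + path.coefs[i] @ mu
        pr = expit(b0s + Xs @ bs)
        score = Xs.T @ (w * (yp - pr)) / n
        viol = np.where(
            bs == 0.0,
            np.maximum(np.abs(score) - lam, 0.0),
            np.abs(score - lam * np.sign(bs)),
        )
        worst = max(worst, float(viol.max()))
    return worst


class TestFitPath:
    def test_null_model_at_lambda_max(self, logit_data):
        X, y, _ = logit_data
        path = fit_path(X, y)
        assert np.all(path.coefs[0] == 0.0)
        ybar = y.mean()
        assert path.intercepts[0] == pytest.approx(np.log(ybar / (1 - ybar)))
        assert lambda_max(X, y) == pytest.approx(path.lambdas[0])

    def test_lambda_zero_matches_mle(self, logit_data):
        import statsmodels.api as sm

        X, y, _ = logit_data
        lmax = lambda_max(X, y)
        grid = np.concatenate([np.logspace(np.log10(lmax), -4, 40), [0.0]])
        path = fit_path(X, y, lambdas=grid)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0).params
        ours = np.concatenate([[path.intercepts[-1]], path.coefs[-1]])
        assert np.abs(ours - mle).max() < 1e-4

    def test_kkt_conditions(self, logit_data):
        X, y, _ = logit_data
        assert kkt_violation(fit_path(X, y), X, y) < 1e-5

    def test_unit_weights_equal_unweighted(self, logit_data):
        X, y, _ = logit_data
        a = fit_path(X, y)
        b = fit_path(X, y, weights=np.ones(y.size))
        assert np.array_equal(a.coefs, b.coefs)

    def test_row_duplication_half_weight_equivalence(self, logit_data):
        X, y, _ = logit_data
        a = fit_path(X, y)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        b = fit_path(X2, y2, weights=np.full(2 * y.size, 0.5), lambdas=a.lambdas)
        assert np.abs(a.coefs - b.coefs).max() < 1e-6
        assert np.abs(a.intercepts - b.intercepts).max() < 1e-6

    def test_input_validation(self, logit_data):
        X, y, _ = logit_data
        with pytest.raises(ValueError):
            fit_path(X, y + 0.5)
        with pytest.raises(ValueError):
            fit_path(X, y, weights=-np.ones(y.size))


class TestCVCurve:
    def test_grouped_folds_keep_subjects_together(self, logit_data):
        X, y, _ = logit_data
        m = 4
        Xs = np.vstack([X] * m)
        ys = np.tile(y, m)
        sid = np.tile(np.arange(y.size), m)
        curve = cv_curve(Xs, ys, group_ids=sid, rng=0)
        for s in np.unique(sid):
            assert np.unique(curve.fold_assignment[sid == s]).size == 1

    def test_fold_stratification(self, logit_data):
        X, y, _ = logit_data
        folds = assign_folds(y, 10, None, np.random.default_rng(0))
        for f in range(10):
            assert np.unique(y[folds == f]).size == 2

    def test_mean_matches_fold_recomputation(self, logit_data):
        X, y, _ = logit_data
        curve = cv_curve(X, y, rng=1)
        assert np.allclose(curve.mean_deviance, curve.fold_deviance.mean(axis=0))
        assert np.allclose(
            curve.se_deviance,
            curve.fold_deviance.std(axis=0, ddof=1) / np.sqrt(10),
        )
        assert np.all(curve.se_deviance >= 0)


class TestChoosePenalty:
    def test_flat_curve_takes_largest_lambda(self):
        lam = np.logspace(0, -2, 20)
        curve = CVCurve(lam, np.ones(20), np.full(20, 0.1), np.zeros(1))
        choice = choose_penalty(curve)
        assert choice.lambda_1se == lam[0] == choice.lambda_opt

    def test_one_se_geq_opt(self, logit_data):
        X, y, _ = logit_data
        for seed in range(5):
            fit = cv_lasso(X, y, rng=seed)
            assert fit.choice.lambda_1se >= fit.choice.lambda_opt

    def test_tiny_se_convex_curve(self):
        lam = np.logspace(0, -2, 50)
        dev = (np.log(lam) + 2.0) ** 2 + 1.0
        curve = CVCurve(lam, dev, np.full(50, 1e-12), np.zeros(1))
        choice = choose_penalty(curve)
        assert choice.lambda_1se == pytest.approx(choice.lambda_opt, rel=0.06)

    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            PenaltyChoice(lambda_opt=1.0, lambda_1se=0.5)


@pytest.mark.parametrize("seed", range(6))
def test_kkt_random_problems(seed):
    """KKT subgradient conditions hold along random weighted problems."""
    rng = np.random.default_rng(seed)
    n, p = rng.integers(60, 200), rng.integers(3, 20)
    X, y, _ = make_logit_data(n=int(n), p=int(p), n_signal=min(3, int(p)),
                              seed=seed + 100)
    w = rng.uniform(0.2, 2.0, size=int(n))
    path = fit_path(X, y, weights=w)
    assert kkt_violation(path, X, y, weights=w) < 1e-5


def test_against_r_glmnet(tmp_path, logit_data):
    """cv.glmnet with the same folds, grid and weights is an independent
    oracle for the whole CV curve and both penalty rules."""
    X, y, _ = logit_data
    rng = np.random.default_rng(0)
    folds = assign_folds(y, 10, None, rng)
    lambdas = fit_path(X, y).lambdas
    # reuse the python fold assignment in R
    curve = CVCurve(lambdas, *_cv_with_folds(X, y, lambdas, folds))
    np.savetxt(tmp_path / "X.csv", X, delimiter=",")
    np.savetxt(tmp_path / "y.csv", y, delimiter=",")
    np.savetxt(tmp_path / "lam.csv", lambdas, delimiter=",")
    np.savetxt(tmp_path / "folds.csv", folds + 1, delimiter=",", fmt="%d")
    rcode = f"""
    suppressMessages(library(glmnet))
    X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
    y <- as.numeric(read.csv("{tmp_path}/y.csv", header=FALSE)[[1]])
    lam <- as.numeric(read.csv("{tmp_path}/lam.csv", header=FALSE)[[1]])
    fid <- as.integer(read.csv("{tmp_path}/folds.csv", header=FALSE)[[1]])
    cv <- cv.glmnet(X, y, family="binomial", lambda=lam, foldid=fid,
                    type.measure="deviance")
    write.csv(data.frame(lambda=cv$lambda, cvm=cv$cvm),
              "{tmp_path}/out.csv", row.names=FALSE)
    cat(cv$lambda.min, cv$lambda.1se)
    """
    (tmp_path / "cv.R").write_text(rcode)
    res = subprocess.run(
        ["Rscript", str(tmp_path / "cv.R")], capture_output=True, text=True
    )
    assert res.returncode == 0, res.stderr
    r_min, r_1se = map(float, res.stdout.split()[-2:])
    import pandas as pd

    out = pd.read_csv(tmp_path / "out.csv")
    # glmnet may drop trailing path values; compare on the common prefix
    k = len(out)
    ours = curve.mean_deviance[:k]
    assert np.allclose(ours, out["cvm"].to_numpy(), rtol=5e-3, atol=5e-3)
    choice = choose_penalty(curve)
    grid = curve.lambdas
    # identical grid: chosen penalties agree to within one grid point
    assert abs(np.log(choice.lambda_opt) - np.log(r_min)) < np.log(grid[0] / grid[1]) * 1.5
    assert abs(np.log(choice.lambda_1se) - np.log(r_1se)) < np.log(grid[0] / grid[1]) * 1.5


def _cv_with_folds(X, y, lambdas, folds):
    """Deviance curve for a fixed fold assignment (mirrors cv_curve)."""
    from miselect.lasso import _fold_deviance

    Xp, yp, w = _prepare(X, y, None)
    k = folds.max() + 1
    dev = np.empty((k, lambdas.size))
    for f in range(k):
        test = folds == f
        path = fit_path(Xp[~test], yp[~test], w[~test], lambdas=lambdas)
        dev[f] = _fold_deviance(path, Xp[test], yp[test], w[test])
    return dev.mean(axis=0), dev.std(axis=0, ddof=1) / np.sqrt(k), folds
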