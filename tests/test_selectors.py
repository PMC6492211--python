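import numpy as np
import pytest
from scipy.special import expit

import miselect as ms
from miselect._glm import ConvergenceError, fit_logistic
from miselect.selectors import (
    InclusionFrequencies,
    backward_eliminate_aic,
    bootstrap_inclusion,
    fit_reference,
    make_stack,
    select_by_frequency,
    select_sepav,
    select_stacked,
)


class TestBackwardEliminateAic:
    def test_strong_signal_retained(self):
        # one covariate with OR e^2 among pure noise: retained nearly always
        kept = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((2000, 5))
            y = (rng.random(2000) < expit(2.0 * X[:, 0])).astype(float)
            sel = backward_eliminate_aic(X, y)
            kept += 0 in sel
        assert kept >= 24  # > 95 % of runs

    def test_greedy_step_matches_exhaustive_comparison(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 6))
        y = (rng.random(300) < expit(X[:, 0] - X[:, 1])).astype(float)
        sel = set(backward_eliminate_aic(X, y).tolist())
        # replay the greedy path with an independent statsmodels oracle
        import statsmodels.api as sm

        current = list(range(6))
        def aic(cols):
            Z = sm.add_constant(X[:, cols])
            return sm.Logit(y, Z).fit(disp=0).aic
        best = aic(current)
        while current:
            cands = [(aic([c for c in current if c != j]), j) for j in current]
            a, j = min(cands)
            if a < best:
                best = a
                current.remove(j)
            else:
                break
        assert sel == set(current)

    def test_noise_retention_near_aic_alpha(self):
        # empty signal: each variable is kept at roughly the AIC implicit
        # rate P(chi2_1 > 2) ~ 0.157
        rates = []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((3000, 6))
            y = (rng.random(3000) < 0.5).astype(float)
            rates.append(len(backward_eliminate_aic(X, y)) / 6)
        assert np.mean(rates) == pytest.approx(0.157, abs=0.06)

    def test_immediate_stop_keeps_all(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((4000, 3))
        y = (rng.random(4000) < expit(X @ [1.0, 1.0, -1.0])).astype(float)
        assert backward_eliminate_aic(X, y).tolist() == [0, 1, 2]

    def test_separation_raises(self):
        X = np.linspace(-1, 1, 40)[:, None]
        y = (X[:, 0] > 0).astype(float)
        with pytest.raises(ConvergenceError):
            backward_eliminate_aic(X, y)


class TestBootstrapInclusion:
    def test_recount_oracle(self, small_imps):
        freqs = bootstrap_inclusion(small_imps, B=2, base="lasso_1se", rng=0)
        counts = np.zeros(small_imps.p)
        for sel in freqs.selections:
            counts[sel] += 1
        assert np.allclose(freqs.freqs, counts / freqs.n_fits)
        assert freqs.n_fits == small_imps.m * 2 - freqs.n_failures

    def test_b1_frequencies_quantized(self, complete_imps):
        freqs = bootstrap_inclusion(complete_imps, B=1, base="lasso_1se", rng=1)
        assert set(np.round(freqs.freqs * complete_imps.m).astype(int)) <= set(
            range(complete_imps.m + 1)
        )

    def test_unknown_base(self, small_imps):
        with pytest.raises(ValueError):
            bootstrap_inclusion(small_imps, B=1, base="ridge")

    def test_frequency_bounds_enforced(self):
        with pytest.raises(ValueError):
            InclusionFrequencies(freqs=np.array([1.2]), B=1, m=2, n_fits=2)


class TestSelectByFrequency:
    def test_all_selected_equals_full_refit(self, small_imps):
        freqs = InclusionFrequencies(
            freqs=np.ones(small_imps.p), B=1, m=small_imps.m, n_fits=5
        )
        model = select_by_frequency(freqs, small_imps)
        full = fit_reference(small_imps, "FULL")
        # both average unpenalized full-model fits (stack fit == mean of
        # per-completion fits only approximately; check per-completion pooling)
        fits = [fit_logistic(c.X, c.y) for c in small_imps.completed]
        pooled = np.mean([f.params for f in fits], axis=0)
        assert model.intercept == pytest.approx(pooled[0], abs=1e-8)
        assert np.allclose(model.slopes, pooled[1:], atol=1e-8)
        assert model.selected.size == full.selected.size == small_imps.p

    def test_threshold_is_inclusive(self, small_imps):
        freqs = InclusionFrequencies(
            freqs=np.full(small_imps.p, 0.5), B=2, m=small_imps.m, n_fits=10
        )
        model = select_by_frequency(freqs, small_imps, threshold=0.5)
        assert model.selected.size == small_imps.p

    def test_empty_selection_intercept_only(self, small_imps):
        freqs = InclusionFrequencies(
            freqs=np.zeros(small_imps.p), B=2, m=small_imps.m, n_fits=10
        )
        model = select_by_frequency(freqs, small_imps)
        assert model.selected.size == 0
        ybar = small_imps.y.mean()
        assert model.intercept == pytest.approx(np.log(ybar / (1 - ybar)))


class TestSepAv:
    def test_identical_completions_degenerate(self, complete_imps):
        a = select_sepav(complete_imps, "1se", require_majority=False, rng=3)
        b = select_sepav(complete_imps, "1se", require_majority=True, rng=3)
        assert np.array_equal(a.selected, b.selected)

    def test_hand_pooling(self, small_imps):
        from miselect.selectors import _pool_separate

        m, p = 10, 4
        coefs = np.zeros((m, p))
        coefs[0, 0] = 1.0          # active in 1 of 10
        coefs[:6, 1] = 0.5         # active in 6 of 10
        icepts = np.full(m, -0.2)
        sepav = _pool_separate(icepts, coefs.copy(), False, "SepAv", "1se")
        sepavf = _pool_separate(icepts, coefs.copy(), True, "SepAvF", "1se")
        assert sepav.slopes[0] == pytest.approx(0.1)   # c / m
        assert sepav.slopes[1] == pytest.approx(0.3)   # 0.5 * 6/10
        assert sepavf.slopes[0] == 0.0
        assert 0 not in sepavf.selected and 1 in sepavf.selected

    def test_majority_nested_in_union(self, small_imps):
        a = select_sepav(small_imps, "1se", require_majority=False, rng=4)
        b = select_sepav(small_imps, "1se", require_majority=True, rng=4)
        assert set(b.selected) <= set(a.selected)


class TestStack:
    def test_weights_formula(self, small_imps):
        stack = make_stack(small_imps, "missingness")
        m, p = small_imps.m, small_imps.p
        n_obs = small_imps.source.n_observed_covariates()
        i = int(np.argmax(n_obs == p))  # a fully observed subject
        assert stack.row_weight[stack.subject_id == i][0] == pytest.approx(1 / m)
        assert np.all(stack.row_weight > 0)
        assert np.all(stack.row_weight <= 1 / m + 1e-15)
        # constant within subject, equal to the formula
        for s in range(0, small_imps.source.n, 50):
            ws = stack.row_weight[stack.subject_id == s]
            assert np.allclose(ws, (1 / m) * n_obs[s] / p)

    def test_partial_observation_weight(self):
        # 12 of 15 observed with m=10 -> weight 0.08
        assert (1 / 10) * 12 / 15 == pytest.approx(0.08)

    def test_no_missing_stack_equals_stackw(self, complete_imps):
        a = select_stacked(complete_imps, "uniform", "1se", rng=5)
        b = select_stacked(complete_imps, "missingness", "1se", rng=5)
        assert np.allclose(a.slopes, b.slopes, atol=1e-9)

    def test_stacked_identical_copies_equals_single_fit(self, complete_imps):
        # m identical copies with weight 1/m: same path as the single copy
        from miselect.lasso import fit_path

        stack = make_stack(complete_imps, "uniform")
        single = complete_imps.completed[0]
        a = fit_path(single.X, single.y)
        b = fit_path(stack.X, stack.y, weights=stack.row_weight, lambdas=a.lambdas)
        assert np.abs(a.coefs - b.coefs).max() < 1e-6

    def test_active_set_definition(self, small_imps):
        model = select_stacked(small_imps, "uniform", "1se", rng=6)
        assert np.array_equal(model.selected, np.flatnonzero(model.slopes))


class TestReference:
    def test_truec_counts(self, small_imps, mech_one):
        model = fit_reference(small_imps, "TrueC", mech_one.true_idx)
        rec = ms.evaluate_external(model, mech_one, n_val=500, rng=0)
        assert (rec.n_true_selected, rec.n_noise_selected) == (7, 0)

    def test_full_active_set(self, small_imps):
        model = fit_reference(small_imps, "FULL")
        assert model.selected.size == small_imps.p

    def test_full_single_copy_equals_mle(self, complete_imps):
        import statsmodels.api as sm

        model = fit_reference(complete_imps, "FULL")
        d = complete_imps.completed[0]
        mle = sm.Logit(d.y, sm.add_constant(d.X)).fit(disp=0).params
        assert model.intercept == pytest.approx(mle[0], abs=1e-6)
        assert np.allclose(model.slopes, mle[1:], atol=1e-6)

    def test_truec_requires_indices(self, small_imps):
        with pytest.raises(ValueError):
            fit_reference(small_imps, "TrueC")
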