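"""Linear Cox tests: partial likelihood against brute force, penalized path
behaviour, one-SE rule, Breslow baseline, Schoenfeld diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hfrisk.cohort import CohortTable
from hfrisk.evaluate import harrell_cindex
from hfrisk.linear_cox import (breslow_baseline, cox_partial_loglik,
                               cv_select_lambda, fit_cox, fit_elastic_net_cox,
                               fit_penalized_cox, one_se_lambda,
                               partial_loglik_scores, scaled_schoenfeld)
from hfrisk.synthetic_cohort import EffectSpec, generate_cohort

from conftest import LINEAR_BETAS, gaussian_config, make_cohort


def brute_force_pll(beta, X, time, event):
    """Independent risk-set enumeration of the Breslow partial likelihood."""
    s = X @ np.asarray(beta)
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = time >= time[i]
            ll += s[i] - np.log(np.sum(np.exp(s[risk])))
    return ll


class TestPartialLoglik:
    def test_two_subjects_at_beta_zero(self):
        cohort = make_cohort([1.0, 2.0], [1, 1], {"x": [0.3, -0.3]})
        assert cox_partial_loglik(np.zeros(1), cohort) == pytest.approx(
            np.log(0.5), abs=1e-12)

    def test_single_subject_single_event(self):
        cohort = make_cohort([5.0], [1], {"x": [1.7]})
        assert cox_partial_loglik(np.array([2.0]), cohort) == 0.0

    def test_tied_toy_matches_brute_force(self):
        time = np.array([2.0, 2.0, 3.0, 5.0])
        event = np.array([1, 1, 0, 1])
        X = np.array([[0.5], [-1.0], [2.0], [0.0]])
        cohort = make_cohort(time, event, {"x": X.ravel()})
        got = cox_partial_loglik(np.array([0.5]), cohort)
        want = brute_force_pll([0.5], X, time, event)
        assert got == pytest.approx(want, abs=1e-10)

    def test_no_events_is_an_error(self):
        cohort = make_cohort([1.0, 2.0], [0, 0], {"x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="event"):
            cox_partial_loglik(np.zeros(1), cohort)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 1000), st.floats(-5.0, 5.0))
    def test_score_shift_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        n = 12
        t = rng.uniform(1, 10, n).round(1)  # rounded: exercises ties
        e = rng.integers(0, 2, n)
        if e.sum() == 0:
            e[0] = 1
        s = rng.standard_normal(n)
        a = partial_loglik_scores(s, t, e)
        b = partial_loglik_scores(s + shift, t, e)
        assert a == pytest.approx(b, abs=1e-8)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        n = 40
        t = rng.uniform(1, 20, n).round(0)
        e = rng.integers(0, 2, n)
        e[0] = 1
        s = rng.standard_normal(n)
        _, g = partial_loglik_scores(s, t, e, return_grad=True)
        eps = 1e-6
        for j in (0, 5, 17):
            d = np.zeros(n)
            d[j] = eps
            num = (partial_loglik_scores(s + d, t, e)
                   - partial_loglik_scores(s - d, t, e)) / (2 * eps)
            assert g[j] == pytest.approx(num, abs=1e-6)


class TestFitCox:
    def test_recovers_strong_coefficient(self):
        eff = [EffectSpec("x0", "linear", {"beta": 0.8})]
        cohort, _ = generate_cohort(gaussian_config(2000, 31, eff, n_covariates=1))
        fit = fit_cox(cohort)
        assert abs(fit.beta["x0"] - 0.8) < 3 * fit.se["x0"]

    def test_matches_lifelines_on_tie_free_data(self):
        import lifelines
        rng = np.random.default_rng(7)
        n = 300
        X = rng.standard_normal((n, 2))
        T = 30 * (-np.log(rng.uniform(size=n)) / np.exp(0.6 * X[:, 0]))
        C = rng.uniform(5, 60, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        cohort = make_cohort(t, e, {"a": X[:, 0], "b": X[:, 1]})
        fit = fit_cox(cohort)
        df = pd.DataFrame(X, columns=["a", "b"]).assign(T=t, E=e)
        ll = lifelines.CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.beta, ll.params_, atol=1e-4)
        np.testing.assert_allclose(fit.se, ll.standard_errors_, atol=1e-4)

    def test_ridge_makes_duplicated_covariates_symmetric(self):
        rng = np.random.default_rng(4)
        n = 400
        x = rng.standard_normal(n)
        T = 40 * (-np.log(rng.uniform(size=n)) / np.exp(0.6 * x))
        C = rng.uniform(5, 80, n)
        cohort = make_cohort(np.minimum(T, C), (T <= C).astype(int),
                             {"a": x, "b": x})
        fit = fit_cox(cohort, ridge=1.0)
        assert abs(fit.beta["a"] - fit.beta["b"]) < 1e-6

    def test_optimum_is_locally_optimal(self, linear_cohort, linear_models):
        train = linear_cohort["train"]
        beta_hat = linear_models["cox"].beta.to_numpy()
        best = cox_partial_loglik(beta_hat, train)
        rng = np.random.default_rng(0)
        for _ in range(10):
            delta = 0.05 * rng.standard_normal(len(beta_hat))
            assert cox_partial_loglik(beta_hat + delta, train) <= best + 1e-9


class TestPenalizedPath:
    def test_huge_lambda_shrinks_everything_to_zero(self, linear_cohort):
        with pytest.warns(UserWarning, match="all coefficients are zero"):
            path = fit_penalized_cox(linear_cohort["train"],
                                     alphas=np.array([1e5]))
        assert (path.coefs == 0.0).all()

    def test_sparsity_grows_with_lambda(self, linear_cohort):
        path = fit_penalized_cox(linear_cohort["train"])
        nnz = (np.abs(path.coefs) > 0).sum(axis=1)
        # alphas decrease along the path: support can only grow (loosely)
        assert nnz[0] <= nnz[len(nnz) // 2] <= nnz[-1] + 1


class TestOneSERule:
    def test_zero_se_collapses_to_minimum(self):
        assert one_se_lambda([3, 2, 1], [10, 9, 9.5], [0, 0, 0]) == 2.0

    def test_flat_curve_takes_largest_lambda(self):
        assert one_se_lambda([3, 2, 1], [5, 5, 5], [1, 1, 1]) == 3.0

    def test_hand_constructed_curve(self):
        assert one_se_lambda([3, 2, 1], [10, 9, 9.5], [1, 1, 1]) == 3.0

    def test_cv_selection_is_deterministic_and_above_minimum(self, linear_cohort):
        train = linear_cohort["train"].subset(np.arange(600))
        path = fit_penalized_cox(train)
        lam_a, curve = cv_select_lambda(path, train, k=5, seed=3)
        lam_b, _ = cv_select_lambda(path, train, k=5, seed=3)
        assert lam_a == lam_b
        lam_min = float(curve.lam[curve["mean"].idxmin()])
        assert lam_a >= lam_min


class TestBreslowBaseline:
    def test_nelson_aalen_arithmetic(self):
        h0 = breslow_baseline(np.zeros(4), np.array([1.0, 2.0, 3.0, 4.0]),
                              np.ones(4, dtype=int))
        assert h0(4.0) == pytest.approx(1 / 4 + 1 / 3 + 1 / 2 + 1, abs=1e-12)
        assert h0(0.0) == 0.0

    def test_survival_one_at_time_zero_and_rank_preserving(self, linear_cohort):
        model = fit_elastic_net_cox(linear_cohort["train"], k=5, seed=0)
        test = linear_cohort["test"]
        s0 = model.predict_survival(test.covariates, 0.0)
        np.testing.assert_allclose(s0, 1.0)
        scores = model.predict_log_hazard(test.covariates)
        for t in (12.0, 36.0, 72.0):
            surv = model.predict_survival(test.covariates, t)
            hi, lo = np.argmax(scores), np.argmin(scores)
            assert surv[hi] <= surv[lo]

    def test_calibration_in_the_large(self, linear_cohort):
        model = fit_elastic_net_cox(linear_cohort["train"], k=5, seed=0)
        test = linear_cohort["test"]
        h = 24.0
        pred = np.atleast_1d(model.predict_risk(test.covariates, h))
        observed = ((test.time <= h) & (test.event == 1)).mean()
        # administrative censoring at >= 60 months: status at 24m is known
        se = np.sqrt(observed * (1 - observed) / test.n)
        assert abs(pred.mean() - observed) < 2 * se + 0.01


class TestScaledSchoenfeld:
    def test_two_event_toy_matches_hand_computation(self):
        # events at t=1 (x=1, risk set {1,0,2}) and t=2 (x=0, risk set {0,2})
        cohort = make_cohort([1.0, 2.0, 3.0], [1, 1, 0], {"x": [1.0, 0.0, 2.0]})
        fit = fit_cox(cohort)
        res = scaled_schoenfeld(fit, cohort)
        b = fit.beta["x"]
        w = np.exp(b * np.array([1.0, 0.0, 2.0]))
        r1 = 1.0 - (w[0] * 1 + w[1] * 0 + w[2] * 2) / w.sum()
        r2 = 0.0 - (w[1] * 0 + w[2] * 2) / (w[1] + w[2])
        # undo the Grambsch-Therneau scaling to recover the raw residuals
        from hfrisk.linear_cox import _neg_loglik_grad_hess
        X = cohort.covariates.to_numpy(dtype=float)
        _, _, info = _neg_loglik_grad_hess(fit.beta.to_numpy(), X,
                                           cohort.time, cohort.event, hess=True)
        raw = (res["x"].to_numpy() - b) * info[0, 0] / 2.0
        np.testing.assert_allclose(raw, [r1, r2], atol=1e-8)

    def test_no_trend_under_proportional_hazards(self):
        flagged = 0
        for rep in range(20):
            eff = [EffectSpec("x0", "linear", {"beta": 0.6}),
                   EffectSpec("x1", "linear", {"beta": -0.4})]
            cohort, _ = generate_cohort(
                gaussian_config(2000, 100 + rep, eff, n_covariates=2))
            fit = fit_cox(cohort)
            res = scaled_schoenfeld(fit, cohort)
            rho = max(abs(np.corrcoef(res.event_time, res[c])[0, 1])
                      for c in ("x0", "x1"))
            flagged += rho >= 0.1
        assert flagged <= 2  # no covariate flagged in >= 90% of replicates

    def test_detects_time_varying_effect(self):
        positive = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            n = 2000
            x = rng.standard_normal(n)
            # effect switches on after t=15: a clear PH violation
            lam0 = 1.0 / 40.0
            t_first = rng.exponential(1.0 / lam0, n)
            t = np.where(t_first <= 15.0, t_first,
                         15.0 + rng.exponential(1.0 / (lam0 * np.exp(x)), n))
            c = rng.uniform(10, 80, n)
            cohort = make_cohort(np.minimum(t, c), (t <= c).astype(int), {"x": x})
            fit = fit_cox(cohort)
            res = scaled_schoenfeld(fit, cohort)
            positive += np.corrcoef(res.event_time, res["x"])[0, 1] > 0
        assert positive >= 18  # positive trend in >= 90% of replicates
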