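"""Validation-suite tests: concordance against brute force and an
independent library, IPCW AUC against a hand-computed worked example,
calibration (deciles, ICI), product-limit estimators and Youden metrics."""

import numpy as np
import pytest

from hfrisk.evaluate import (calibration_deciles, compare_auc,
                             cumulative_incidence, cv_cindex, harrell_cindex,
                             ici, kaplan_meier, threshold_metrics,
                             time_dependent_auc)

from conftest import gaussian_config
from hfrisk.synthetic_cohort import EffectSpec, generate_cohort


class TestHarrellCindex:
    def test_perfectly_reversed_risks(self):
        assert harrell_cindex([1, 2, 3], [1, 1, 1], [3.0, 2.0, 1.0]) == 1.0

    def test_all_tied_risks(self):
        assert harrell_cindex([1, 2, 3], [1, 1, 1], [5.0, 5.0, 5.0]) == 0.5

    def test_censored_toy_matches_pair_enumeration(self):
        times = np.array([2.0, 4.0, 3.0, 5.0, 1.0, 6.0])
        events = np.array([1, 0, 1, 1, 0, 1])
        risk = np.array([0.9, 0.3, 0.9, 0.2, 0.8, 0.1])
        conc = pairs = 0.0
        for i in range(6):
            for j in range(6):
                if events[i] == 1 and times[i] < times[j]:
                    pairs += 1
                    conc += 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
        assert harrell_cindex(times, events, risk) == conc / pairs

    def test_agrees_with_sksurv(self):
        # tie-free times: with tied times the comparable-pair conventions
        # of the two implementations differ
        from sksurv.metrics import concordance_index_censored
        rng = np.random.default_rng(3)
        n = 500
        t = rng.uniform(1, 100, n)
        e = rng.integers(0, 2, n)
        s = rng.standard_normal(n)
        assert harrell_cindex(t, e, s) == pytest.approx(
            concordance_index_censored(e.astype(bool), t, s)[0], abs=1e-12)

    def test_no_comparable_pairs(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_cindex([5.0, 1.0], [0, 0], [0.1, 0.2])


class _OracleFactory:
    """Risk factory scoring with the generator's true log-hazard."""

    def __init__(self, truth):
        self.truth = truth

    def __call__(self, train, seed):
        return self

    def predict_log_hazard(self, covariates):
        return self.truth.f_star(covariates)


class _NoiseFactory:
    def __call__(self, train, seed):
        return self

    def predict_log_hazard(self, covariates):
        return np.random.default_rng(0).standard_normal(len(covariates))


class TestCvCindex:
    def test_oracle_cv_matches_full_sample(self, calibration_cohort):
        cohort = calibration_cohort["cohort"].subset(np.arange(3000))
        truth = calibration_cohort["truth"]
        factory = _OracleFactory(truth)
        mean, se, folds = cv_cindex(factory, cohort, k=10, seed=4)
        full = harrell_cindex(cohort.time, cohort.event,
                              truth.f_star(cohort.covariates))
        assert abs(mean - full) < 0.02
        assert len(folds) == 10 and se > 0

    def test_deterministic_given_seed(self, calibration_cohort):
        cohort = calibration_cohort["cohort"].subset(np.arange(1000))
        factory = _OracleFactory(calibration_cohort["truth"])
        a = cv_cindex(factory, cohort, k=5, seed=7)
        b = cv_cindex(factory, cohort, k=5, seed=7)
        assert a[0] == b[0] and a[1] == b[1]

    def test_noise_scores_near_half(self, calibration_cohort):
        cohort = calibration_cohort["cohort"].subset(np.arange(2000))
        mean, se, _ = cv_cindex(_NoiseFactory(), cohort, k=10, seed=1)
        assert abs(mean - 0.5) < 2 * se + 0.02


class TestTimeDependentAuc:
    def test_no_censoring_equals_binary_auc(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(0)
        t = rng.exponential(50, 2000) + 0.1
        e = np.ones(2000, dtype=int)
        s = rng.standard_normal(2000) + 0.8 * (t <= 30)
        auc, _ = time_dependent_auc(t, e, s, 30.0, n_boot=0)
        assert auc == pytest.approx(roc_auc_score(t <= 30, s), abs=1e-12)

    def test_perfect_separation(self):
        t = np.array([5.0, 8.0, 40.0, 50.0, 60.0])
        e = np.array([1, 1, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.1, 0.2, 0.3])
        auc, _ = time_dependent_auc(t, e, s, 20.0, n_boot=0)
        assert auc == 1.0

    def test_worked_example_with_censoring_matches_hand_ipcw(self):
        # 8 subjects, horizon 10; subjects 4 and 5 censored before it
        t = np.array([3.0, 7.0, 4.0, 9.0, 2.0, 6.0, 12.0, 15.0])
        e = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        s = np.array([0.8, 0.6, 0.7, 0.4, 0.5, 0.3, 0.2, 0.1])
        horizon = 10.0
        # censoring KM G: censorings at 9, 6, 2, 12 among risk sets
        # G(2)=7/8, G(6)=7/8*4/5, G(9)=7/8*4/5*2/3
        G2, G6, G9 = 7 / 8, 7 / 8 * 4 / 5, 7 / 8 * 4 / 5 * 2 / 3
        # cases: events at 3, 7, 4 with G(t-) = G(2), G(6), G(2)
        w = np.array([1 / G2, 1 / G6, 1 / G2])
        # controls: t > 10 -> subjects 6 (s=0.2) and 7 (s=0.1)
        # each case outranks both controls
        expected = (w * 2).sum() / (w.sum() * 2)
        auc, _ = time_dependent_auc(t, e, s, horizon, n_boot=0)
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_horizon_beyond_followup_rejected(self):
        with pytest.raises(ValueError, match="follow-up"):
            time_dependent_auc([1.0, 2.0], [1, 1], [0.1, 0.2], 5.0)

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(40, 500) + 0.1
        e = (rng.uniform(size=500) < 0.7).astype(int)
        s = -t / 40 + rng.standard_normal(500)
        auc, (lo, hi) = time_dependent_auc(t, e, s, 30.0, n_boot=200, seed=2)
        assert lo <= auc <= hi


@pytest.fixture(scope="module")
def sample():
    rng = np.random.default_rng(10)
    n = 2000
    x = rng.standard_normal(n)
    T = 50 * (-np.log(rng.uniform(size=n)) / np.exp(0.9 * x))
    C = rng.uniform(10, 120, n)
    return np.minimum(T, C), (T <= C).astype(int), x, rng.standard_normal(n)


class TestCompareAuc:
    def test_identical_models_give_p_near_one(self, sample):
        t, e, s, _ = sample
        assert compare_auc(s, s, t, e, 24.0, n_boot=200, seed=1) == 1.0

    def test_strong_vs_noise_is_significant(self, sample):
        t, e, s, noise = sample
        significant = 0
        for rep in range(10):
            p = compare_auc(s, noise, t, e, 24.0, n_boot=300, seed=rep)
            significant += p < 0.01
        assert significant >= 9

    def test_symmetric_in_model_order(self, sample):
        t, e, s, noise = sample
        p_ab = compare_auc(s, noise, t, e, 24.0, n_boot=300, seed=3)
        p_ba = compare_auc(noise, s, t, e, 24.0, n_boot=300, seed=3)
        assert p_ab == p_ba

    def test_small_bootstrap_rejected(self, sample):
        t, e, s, noise = sample
        with pytest.raises(ValueError, match="n_boot"):
            compare_auc(s, noise, t, e, 24.0, n_boot=50)


class TestCalibrationDeciles:
    def test_oracle_predictions_calibrate(self, calibration_cohort):
        cohort = calibration_cohort["cohort"]
        truth = calibration_cohort["truth"]
        h = 24.0
        p = truth.risk_at(cohort.covariates, h)
        dec = calibration_deciles(p, cohort.time, cohort.event, h)
        assert (dec.observed - dec.mean_predicted).abs().max() < 0.03

    def test_group_sizes_partition_the_sample(self, calibration_cohort):
        cohort = calibration_cohort["cohort"].subset(np.arange(1005))
        p = np.linspace(0.01, 0.99, 1005)
        dec = calibration_deciles(p, cohort.time, cohort.event, 24.0)
        assert dec.n.sum() == 1005
        assert dec.n.max() - dec.n.min() <= 1

    def test_zero_predictions_no_events(self):
        t = np.full(50, 100.0)
        e = np.zeros(50, dtype=int)
        dec = calibration_deciles(np.zeros(50), t, e, 24.0)
        assert (dec.observed == 0).all()


class TestICI:
    def test_oracle_risks_are_well_calibrated(self, calibration_cohort):
        cohort = calibration_cohort["cohort"]
        p = calibration_cohort["truth"].risk_at(cohort.covariates, 24.0)
        assert ici(p, cohort.time, cohort.event, 24.0) < 0.01

    def test_systematic_shift_is_detected(self, calibration_cohort):
        cohort = calibration_cohort["cohort"]
        p = calibration_cohort["truth"].risk_at(cohort.covariates, 24.0)
        shifted = np.clip(p + 0.10, 0.0, 1.0)
        v = ici(shifted, cohort.time, cohort.event, 24.0)
        assert 0.07 <= v <= 0.12

    def test_monotone_in_miscalibration(self, calibration_cohort):
        cohort = calibration_cohort["cohort"]
        p = calibration_cohort["truth"].risk_at(cohort.covariates, 24.0)
        vals = [ici(np.clip(p + d, 0, 1), cohort.time, cohort.event, 24.0)
                for d in (0.0, 0.05, 0.10)]
        assert vals[0] < vals[1] < vals[2]

    def test_constant_prediction_calibrated_in_the_large(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(50, 5000) + 0.01
        e = np.ones(5000, dtype=int)
        frac = (t <= 30).mean()
        assert ici(np.full(5000, frac), t, e, 30.0) < 0.01


class TestProductLimit:
    def test_uncensored_staircase(self):
        km = kaplan_meier([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        np.testing.assert_allclose(km([1.0, 2.0, 3.0, 4.0]),
                                   [0.75, 0.5, 0.25, 0.0])

    def test_all_censored(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert km(99.0) == 1.0

    def test_classic_interleaved_example(self):
        # events at 1, 3, 5; censored at 2, 4, 6
        km = kaplan_meier([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 0])
        s1 = 5 / 6
        s3 = s1 * 3 / 4
        s5 = s3 * 1 / 2
        assert km(1.0) == pytest.approx(s1, abs=1e-10)
        assert km(3.5) == pytest.approx(s3, abs=1e-10)
        assert km(5.0) == pytest.approx(s5, abs=1e-10)

    def test_agrees_with_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(8)
        t = rng.uniform(1, 50, 300).round(0) + 1
        e = rng.integers(0, 2, 300)
        km = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for q in (5.0, 15.0, 30.0, 45.0):
            assert km(q) == pytest.approx(
                float(kmf.survival_function_at_times(q).iloc[0]), abs=1e-10)

    def test_cif_equals_complement_of_km_without_competing(self):
        rng = np.random.default_rng(9)
        t = rng.uniform(1, 50, 200).round(0) + 1
        e = rng.integers(0, 2, 200)
        km = kaplan_meier(t, e)
        cif = cumulative_incidence(t, e)
        for q in (5.0, 20.0, 40.0):
            assert cif(q) == pytest.approx(1.0 - km(q), abs=1e-12)

    def test_competing_events_reduce_incidence(self):
        rng = np.random.default_rng(10)
        t = rng.uniform(1, 50, 500).round(0) + 1
        e = (rng.uniform(size=500) < 0.4).astype(int)
        comp = ((rng.uniform(size=500) < 0.5) & (e == 0)).astype(int)
        cif = cumulative_incidence(t, e, comp)
        plain = cumulative_incidence(t, e)
        assert cif(50.0) <= plain(50.0)
        vals = cif(np.array([5.0, 15.0, 30.0, 50.0]))
        assert (np.diff(vals) >= -1e-12).all()

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            kaplan_meier([-1.0, 2.0], [1, 1])


class TestThresholdMetrics:
    def test_perfect_separator(self):
        t = np.array([2.0, 4.0, 50.0, 60.0, 70.0])
        e = np.array([1, 1, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.2, 0.1, 0.15])
        m = threshold_metrics(p, t, e, 10.0)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_constant_predictor_has_zero_youden(self):
        t = np.array([2.0, 4.0, 50.0, 60.0])
        e = np.array([1, 1, 0, 0])
        m = threshold_metrics(np.full(4, 0.3), t, e, 10.0)
        assert m.youden == 0.0

    def test_ten_row_toy_matches_hand_counts(self):
        t = np.concatenate([np.full(4, 5.0), np.full(6, 50.0)])
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.4, 0.3, 0.7, 0.5, 0.2, 0.15, 0.1, 0.05])
        m = threshold_metrics(p, t, e, 10.0)
        # best cutoff 0.8: TP=2 FN=2 FP=0 TN=6 -> J = 0.5; cutoff 0.3 ties
        # J = (4/4 + 4/6 - 1) = 0.667 -> actually better: TP=4 FN=0 FP=2 TN=4
        assert m.cutoff == pytest.approx(0.3)
        assert m.sensitivity == 1.0
        assert m.specificity == pytest.approx(4 / 6)
        assert m.ppv == pytest.approx(4 / 6)
        assert m.npv == 1.0

    def test_censored_before_horizon_are_excluded(self):
        t = np.array([2.0, 3.0, 4.0, 50.0, 60.0])
        e = np.array([1, 0, 1, 0, 0])
        m = threshold_metrics(np.array([0.9, 0.5, 0.8, 0.1, 0.2]), t, e, 10.0)
        assert m.n_excluded == 1
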