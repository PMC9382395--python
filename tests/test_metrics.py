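"""Discrimination, calibration, classification and Net Benefit metrics."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score

from imbcal.metrics import (
    auroc,
    calibration_intercept,
    calibration_slope,
    classification_metrics,
    decision_curve,
    evaluate,
    flexible_calibration_curve,
    net_benefit,
    net_benefit_treat_all,
)


def calibrated_sample(n=50_000, seed=0, spread=1.2, b0=-1.5):
    """Outcomes drawn from their own predicted probabilities."""
    rng = np.random.default_rng(seed)
    lp = rng.normal(b0, spread, size=n)
    probs = expit(lp)
    y = (rng.random(n) < probs).astype(int)
    return probs, y


class TestAuroc:
    def test_perfect_separation_is_one(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        assert auroc(probs, np.array([1, 1, 0, 0])) == 1.0

    def test_constant_predictions_half(self):
        assert auroc(np.full(10, 0.3), np.r_[np.ones(5), np.zeros(5)]) == 0.5

    def test_hand_enumerated_example(self):
        """3 of 4 event/nonevent pairs concordant."""
        assert auroc(np.array([0.9, 0.8, 0.7, 0.6]), np.array([1, 0, 1, 0])) == 0.75

    def test_single_class_undefined(self):
        assert np.isnan(auroc(np.array([0.1, 0.2]), np.array([1, 1])))

    def test_monotone_transform_invariance(self):
        probs, y = calibrated_sample(n=500, seed=1)
        assert auroc(probs, y) == pytest.approx(auroc(probs**3, y), abs=1e-12)

    def test_matches_sklearn(self):
        probs, y = calibrated_sample(n=2000, seed=2)
        probs = np.round(probs, 2)  # force ties to exercise midranks
        assert auroc(probs, y) == pytest.approx(roc_auc_score(y, probs), abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(4, 12),
        seed=st.integers(0, 10_000),
    )
    def test_pair_enumeration_oracle(self, n, seed):
        """Brute force over all event/nonevent pairs, ties counted 1/2."""
        rng = np.random.default_rng(seed)
        probs = np.round(rng.random(n), 1)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            return
        num = tot = 0.0
        for pe in probs[y == 1]:
            for pn in probs[y == 0]:
                num += 1.0 if pe > pn else (0.5 if pe == pn else 0.0)
                tot += 1.0
        assert auroc(probs, y) == pytest.approx(num / tot, abs=1e-12)


class TestCalibrationIntercept:
    def test_well_calibrated_near_zero(self):
        probs, y = calibrated_sample()
        assert calibration_intercept(probs, y) == pytest.approx(0.0, abs=0.05)

    def test_known_shift_recovery(self):
        probs, y = calibrated_sample(seed=3)
        shifted = expit(logit(probs) - np.log(2))
        a = calibration_intercept(shifted, y)
        assert a == pytest.approx(np.log(2), abs=0.05)

    def test_sign_convention_overestimation_negative(self):
        probs, y = calibrated_sample(seed=4)
        over = expit(logit(probs) + 1.0)
        assert calibration_intercept(over, y) < -0.8

    def test_matches_statsmodels_offset_fit(self):
        probs, y = calibrated_sample(n=5000, seed=5)
        distorted = expit(0.4 + 1.3 * logit(probs))
        a = calibration_intercept(distorted, y)
        ref = sm.GLM(
            y,
            np.ones((y.size, 1)),
            family=sm.families.Binomial(),
            offset=logit(distorted),
        ).fit()
        assert a == pytest.approx(float(ref.params[0]), abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            calibration_intercept(np.array([0.2, 0.4]), np.array([1, 1]))


class TestCalibrationSlope:
    def test_well_specified_slope_one(self):
        probs, y = calibrated_sample(seed=6)
        _, b = calibration_slope(probs, y)
        assert b == pytest.approx(1.0, abs=0.05)

    def test_doubled_logits_slope_half(self):
        probs, y = calibrated_sample(seed=7)
        extreme = expit(2.0 * logit(probs))
        _, b = calibration_slope(extreme, y)
        assert b == pytest.approx(0.5, abs=0.03)

    def test_constant_predictions_undefined(self):
        a, b = calibration_slope(np.full(100, 0.3), np.random.default_rng(0).integers(0, 2, 100))
        assert np.isnan(a) and np.isnan(b)

    def test_matches_statsmodels(self):
        probs, y = calibrated_sample(n=5000, seed=8)
        distorted = expit(0.5 + 1.4 * logit(probs))
        a, b = calibration_slope(distorted, y)
        lp = logit(distorted)
        ref = sm.GLM(
            y, sm.add_constant(lp), family=sm.families.Binomial()
        ).fit()
        assert a == pytest.approx(float(ref.params[0]), abs=1e-6)
        assert b == pytest.approx(float(ref.params[1]), abs=1e-6)


class TestFlexibleCalibrationCurve:
    def test_identity_calibration_close_to_diagonal(self):
        probs, y = calibrated_sample(n=50_000, seed=9)
        curve = flexible_calibration_curve(probs, y)
        # judge the smooth where the data live (central 98% of predictions)
        lo, hi = np.quantile(probs, [0.01, 0.99])
        inner = (curve.predicted >= lo) & (curve.predicted <= hi)
        assert np.max(np.abs(curve.observed[inner] - curve.predicted[inner])) < 0.02

    def test_overestimation_lies_below_diagonal(self):
        probs, y = calibrated_sample(n=30_000, seed=10)
        over = expit(logit(probs) + 1.0)
        curve = flexible_calibration_curve(over, y)
        inner = (curve.predicted > 0.1) & (curve.predicted < 0.9)
        assert np.mean(curve.observed[inner] < curve.predicted[inner]) > 0.95

    def test_ordinates_in_unit_interval(self):
        probs, y = calibrated_sample(n=2000, seed=11)
        curve = flexible_calibration_curve(probs, y)
        assert np.all((curve.observed >= 0) & (curve.observed <= 1))
        assert np.all(np.diff(curve.predicted) > 0)

    def test_too_few_points_warns_and_omits(self):
        with pytest.warns(UserWarning):
            out = flexible_calibration_curve(np.linspace(0.1, 0.9, 20), np.zeros(20))
        assert out is None


class TestClassification:
    def test_hand_counted_example(self):
        # TP=3, FN=1, TN=5, FP=1
        probs = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.2, 0.3, 0.4, 0.1])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        m = classification_metrics(probs, y, 0.5)
        assert (m.tp, m.fn, m.tn, m.fp) == (3, 1, 5, 1)
        assert m.accuracy == pytest.approx(0.8)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(5 / 6)

    def test_classify_no_one_accuracy_at_rare_events(self):
        """A useless always-low-risk model is 99% accurate at 1% prevalence."""
        n = 10_000
        y = np.zeros(n, dtype=int)
        y[:100] = 1
        probs = np.full(n, 0.01)
        m = classification_metrics(probs, y, 0.5)
        assert m.accuracy == pytest.approx(0.99)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0

    def test_tiny_threshold_flags_everyone(self):
        probs, y = calibrated_sample(n=1000, seed=12)
        m = classification_metrics(probs, y, 1e-9)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0

    def test_threshold_tie_is_high_risk(self):
        m = classification_metrics(np.array([0.5, 0.49]), np.array([1, 0]), 0.5)
        assert m.tp == 1 and m.tn == 1

    def test_monotone_in_threshold(self):
        probs, y = calibrated_sample(n=2000, seed=13)
        grid = np.linspace(0.05, 0.95, 19)
        ms = [classification_metrics(probs, y, t) for t in grid]
        sens = [m.sensitivity for m in ms]
        spec = [m.specificity for m in ms]
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classification_metrics(np.array([0.5]), np.array([1]), 1.5)


class TestNetBenefit:
    def test_treat_none_is_zero(self):
        probs, y = calibrated_sample(n=500, seed=14)
        assert net_benefit(np.zeros_like(probs) + 1e-9, y, 0.2) == 0.0

    def test_formula_arithmetic(self):
        """TP=50, FP=100, N=1000 at t=0.1 gives (50 - 100/9)/1000."""
        probs = np.r_[np.full(50, 0.9), np.full(100, 0.9), np.full(850, 0.01)]
        y = np.r_[np.ones(50, dtype=int), np.zeros(950, dtype=int)]
        assert net_benefit(probs, y, 0.1) == pytest.approx(
            (50 - (0.1 / 0.9) * 100) / 1000
        )

    def test_treat_all_zero_at_prevalence_threshold(self):
        y = np.r_[np.ones(30, dtype=int), np.zeros(70, dtype=int)]
        assert net_benefit_treat_all(y, 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_predictor_nb_equals_prevalence(self):
        y = np.r_[np.ones(20, dtype=int), np.zeros(80, dtype=int)]
        probs = np.clip(y.astype(float), 0.01, 0.99)
        for t in (0.1, 0.3, 0.5):
            assert net_benefit(probs, y, t) == pytest.approx(0.2)

    def test_never_exceeds_prevalence(self):
        probs, y = calibrated_sample(n=3000, seed=15)
        prev = y.mean()
        for t in np.linspace(0.05, 0.9, 18):
            assert net_benefit(probs, y, t) <= prev + 1e-12

    def test_overestimating_model_negative_at_high_threshold(self):
        probs, y = calibrated_sample(n=30_000, seed=16, b0=-3.0)
        over = expit(logit(probs) + 2.5)
        assert net_benefit(over, y, 0.5) < 0

    def test_decision_curve_table(self):
        probs, y = calibrated_sample(n=1000, seed=17)
        dc = decision_curve(probs, y)
        assert list(dc.columns) == ["threshold", "nb_model", "nb_all", "nb_none"]
        assert len(dc) == 10
        assert (dc.nb_none == 0).all()


def test_evaluate_bundles_all_domains():
    probs, y = calibrated_sample(n=5000, seed=18)
    rec = evaluate(probs, y, thresholds=(0.5, 0.2), meta={"model": "demo"})
    assert 0.5 < rec.auroc < 1.0
    assert abs(rec.cal_intercept) < 0.2
    assert set(rec.thresholds) == {0.5, 0.2}
    assert rec.meta["model"] == "demo"
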