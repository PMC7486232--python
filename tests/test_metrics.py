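"""Metric suite: oracles, closed forms, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import expit, logit

import depval as dv
from depval.errors import DegenerateOutcomeError, UndefinedMetricError, ValidationError
from depval.metrics import (
    flexible_calibration_curve,
    roc_curve_points,
    unreliability_pvalue,
)
from .conftest import simulate_probs


def auc_pairwise_oracle(p, y):
    """Exhaustive O(n^2) concordance count; ties score one half."""
    p, y = np.asarray(p, float), np.asarray(y, float)
    num = den = 0.0
    for pe in p[y == 1]:
        for pn in p[y == 0]:
            den += 1
            num += 1.0 if pe > pn else (0.5 if pe == pn else 0.0)
    return num / den


class TestAuc:
    @pytest.mark.parametrize(
        "p,y,expected",
        [
            ((0.9, 0.8, 0.2, 0.1), (1, 1, 0, 0), 1.0),
            ((0.5, 0.5, 0.5, 0.5), (1, 1, 0, 0), 0.5),
            ((0.2, 0.5, 0.5, 0.8), (0, 1, 0, 1), 0.875),
        ],
    )
    def test_known_values(self, p, y, expected):
        assert dv.auc(np.array(p), np.array(y)) == pytest.approx(expected)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 200))
            p = rng.choice(np.linspace(0, 1, 11), size=n)  # induce ties
            y = rng.integers(0, 2, n).astype(float)
            if y.min() == y.max():
                continue
            assert dv.auc(p, y) == pytest.approx(auc_pairwise_oracle(p, y), abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(40)
        y = rng.integers(0, 2, 40).astype(float)
        if y.min() == y.max():
            return
        base = dv.auc(p, y)
        assert dv.auc(expit(3 * logit(np.clip(p, 1e-9, 1 - 1e-9)) + 2), y) == pytest.approx(base, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            dv.auc(np.array([0.1, 0.2]), np.array([1.0, 1.0]))


class TestBootstrapAucCi:
    def test_seeded_determinism_and_ordering(self, rng):
        p, y = simulate_probs(rng, 126)
        a = dv.bootstrap_auc_ci(p, y, B=400, seed=7)
        b = dv.bootstrap_auc_ci(p, y, B=400, seed=7)
        assert a == b
        assert a[0] <= dv.auc(p, y) <= a[1]

    def test_perfect_separation_degenerate_interval(self):
        p = np.array([0.9] * 10 + [0.1] * 10)
        y = np.array([1.0] * 10 + [0.0] * 10)
        assert dv.bootstrap_auc_ci(p, y, B=200, seed=0) == (1.0, 1.0)

    def test_small_B_rejected(self, rng):
        p, y = simulate_probs(rng, 50)
        with pytest.raises(ValidationError):
            dv.bootstrap_auc_ci(p, y, B=50)


class TestBrier:
    def test_known_values(self):
        y = np.array([1.0, 0.0])
        assert dv.brier(y, y) == 0.0
        assert dv.brier(np.array([0.5, 0.5]), y) == 0.25
        assert dv.brier(np.array([0.8, 0.3]), y) == pytest.approx(0.065)

    def test_prevalence_constant_predictor(self, rng):
        _, y = simulate_probs(rng, 500)
        prev = y.mean()
        assert dv.brier(np.full_like(y, prev), y) == pytest.approx(prev * (1 - prev), abs=1e-12)


class TestCalibrationInTheLarge:
    def test_constant_offset_closed_form(self):
        p = np.full(4, 0.2)
        y = np.array([1.0, 1.0, 0.0, 0.0])
        assert dv.calibration_in_the_large(p, y) == pytest.approx(
            logit(0.5) - logit(0.2), abs=1e-9
        )

    def test_matches_grid_search_oracle(self, rng):
        p, y = simulate_probs(rng, 300)
        p_shift = np.clip(p * 0.55, 1e-9, 1 - 1e-9)
        lp = logit(p_shift)
        # oracle: maximize the offset likelihood by brute-force grid search
        grid = np.linspace(-3, 3, 6001)
        eta = grid[:, None] + lp[None, :]
        ll = eta @ y - np.logaddexp(0.0, eta).sum(axis=1)
        best = grid[np.argmax(ll)]
        assert dv.calibration_in_the_large(p_shift, y) == pytest.approx(best, abs=2e-3)

    def test_under_prediction_is_positive(self, rng):
        p, y = simulate_probs(rng, 2000)
        assert dv.calibration_in_the_large(np.clip(p * 0.3, 1e-9, 1), y) > 0

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            dv.calibration_in_the_large(np.array([0.1, 0.2]), np.array([1.0, 1.0]))


class TestCalibrationSlope:
    def test_own_training_data_slope_one(self, dev_cohort):
        X = dev_cohort[list(dv.DEFAULT_PREDICTOR_FREQS)]
        model = dv.fit_pmle(X, dev_cohort["y"], 0.0)
        p = dv.predict_prob(model, X).p
        assert dv.calibration_slope(p, dev_cohort["y"].to_numpy(float)) == pytest.approx(
            1.0, abs=1e-6
        )

    @pytest.mark.parametrize("factor,expected", [(0.5, 2.0), (2.0, 0.5)])
    def test_attenuation_recovery(self, factor, expected):
        rng = np.random.default_rng(int(10 * factor))
        lp = -1.0 + 1.2 * rng.standard_normal(20_000)
        y = (rng.random(20_000) < expit(lp)).astype(float)
        slope = dv.calibration_slope(expit(factor * lp), y)
        assert slope == pytest.approx(expected, abs=0.1)

    def test_constant_predictions_undefined(self):
        with pytest.raises(UndefinedMetricError):
            dv.calibration_slope(np.full(10, 0.4), np.array([0, 1] * 5, dtype=float))


class TestUnreliability:
    def test_printed_reference_tail(self):
        # 2-df upper tail at statistic 0.2702
        assert round(unreliability_pvalue(0.2702), 3) == 0.874

    def test_null_at_maximum_gives_zero(self, dev_cohort):
        X = dev_cohort[list(dv.DEFAULT_PREDICTOR_FREQS)]
        model = dv.fit_pmle(X, dev_cohort["y"], 0.0)
        p = dv.predict_prob(model, X).p
        stat, pval = dv.unreliability_test(p, dev_cohort["y"].to_numpy(float))
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert pval == pytest.approx(1.0, abs=1e-6)

    def test_statistic_equals_two_fit_oracle(self, rng):
        """LR statistic from the package equals one computed by explicitly
        maximizing the free recalibration with an independent optimizer."""
        p, y = simulate_probs(rng, 400)
        p_bad = np.clip(p * 0.7, 1e-9, 1 - 1e-9)
        stat, _ = dv.unreliability_test(p_bad, y)
        lp = logit(p_bad)

        def nll(theta):
            eta = theta[0] + theta[1] * lp
            return -(y @ eta - np.logaddexp(0, eta).sum())

        free = minimize(nll, np.array([0.0, 1.0]), method="BFGS", tol=1e-12)
        oracle = 2.0 * (nll(np.array([0.0, 1.0])) - free.fun)
        assert stat == pytest.approx(oracle, abs=1e-8)


class TestFlexibleCurve:
    def test_identity_calibration_tracks_diagonal(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.95, 50_000)
        y = (rng.random(50_000) < p).astype(float)
        curve = flexible_calibration_curve(p, y)
        assert np.max(np.abs(curve.estimate - curve.grid)) < 0.02
        assert np.all(curve.low <= curve.estimate + 1e-12)
        assert np.all(curve.estimate <= curve.high + 1e-12)

    def test_band_width_shrinks_with_n(self):
        def mean_width(n, seed):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.1, 0.9, n)
            y = (rng.random(n) < p).astype(float)
            c = flexible_calibration_curve(p, y)
            return float(np.mean(c.high - c.low))

        assert mean_width(50_000, 1) < mean_width(500, 1)

    def test_constant_predictions_flagged_degenerate(self):
        y = np.array([0, 1] * 15, dtype=float)
        curve = flexible_calibration_curve(np.full(30, 0.3), y)
        assert curve.degenerate

    def test_tiny_n_refused(self):
        with pytest.raises(ValidationError, match="grouped"):
            flexible_calibration_curve(np.linspace(0.1, 0.9, 10), np.array([0, 1] * 5, dtype=float))


def test_roc_points_monotone(rng):
    p, y = simulate_probs(rng, 200)
    roc = roc_curve_points(p, y)
    assert (np.diff(roc["fpr"]) >= 0).all() and (np.diff(roc["tpr"]) >= 0).all()
    assert roc.iloc[-1].tolist() == [1.0, 1.0]


def test_performance_report_panel(val_sample):
    model_cols = list(dv.DEFAULT_PREDICTOR_FREQS)
    m = dv.fit_pmle(val_sample[model_cols], val_sample["y"], 1.0)
    p = dv.predict_prob(m, val_sample).p
    rep = dv.performance_report(p, val_sample["y"].to_numpy(float), B=300, seed=0)
    d = rep.to_dict()
    assert 0 <= d["brier"] <= 1 and 0 <= d["auc"] <= 1
    assert d["auc_ci_low"] <= d["auc"] <= d["auc_ci_high"]
    assert 0 <= d["unreliability_p"] <= 1
    assert d["n"] == len(val_sample)
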