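"""Categorical NRI and the score x group interaction test."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import depval as dv
from depval.errors import CollinearityError, DegenerateOutcomeError, ValidationError
from depval.reclassification import classify_risk


def nri_counting_oracle(p_old, p_new, y, thr):
    """Exhaustive per-subject enumeration of category moves."""
    up_e = down_e = up_ne = down_ne = 0
    n_e = n_ne = 0
    for po, pn, yi in zip(p_old, p_new, y):
        old_hi, new_hi = po >= thr, pn >= thr
        if yi == 1:
            n_e += 1
            up_e += (not old_hi) and new_hi
            down_e += old_hi and (not new_hi)
        else:
            n_ne += 1
            up_ne += (not old_hi) and new_hi
            down_ne += old_hi and (not new_hi)
    return (up_e - down_e) / n_e + (down_ne - up_ne) / n_ne


class TestClassifyRisk:
    def test_boundary_is_high(self):
        cats = classify_risk(np.array([0.2, 0.19, 0.21]), 0.2)
        assert cats.high.tolist() == [True, False, True]

    def test_threshold_monotonicity(self, rng):
        p = rng.random(100)
        low_thr = classify_risk(p, 0.2).high
        high_thr = classify_risk(p, 0.4).high
        assert not np.any(high_thr & ~low_thr)

    def test_threshold_validated(self):
        with pytest.raises(ValidationError):
            classify_risk(np.array([0.5]), 1.0)


class TestNri:
    def test_identity_comparison_is_zero(self, rng):
        p = rng.random(60)
        y = rng.integers(0, 2, 60).astype(float)
        res = dv.nri(p, p, y, threshold=0.4, bootstrap_B=2000, seed=0)
        assert res.nri == res.nri_event == res.nri_nonevent == 0.0
        assert np.isfinite(res.se)
        table = res.reclassification_table
        assert table[0, 1].sum() == table[1, 0].sum() == 0  # diagonal only

    def test_nine_subject_worked_example(self):
        # events: 1 up-move of 4; non-events: 2 down, 1 up of 5
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        p_old = np.array([0.1, 0.6, 0.6, 0.1, 0.6, 0.6, 0.1, 0.1, 0.1])
        p_new = np.array([0.6, 0.6, 0.6, 0.1, 0.1, 0.1, 0.6, 0.1, 0.1])
        res = dv.nri(p_old, p_new, y, threshold=0.5, bootstrap_B=2000, seed=1)
        assert res.nri_event == pytest.approx(0.25)
        assert res.nri_nonevent == pytest.approx(0.2)
        assert res.nri == pytest.approx(0.45)
        assert res.to_dict()["paper_convention"]["nri_minus"] == pytest.approx(-0.2)

    def test_matches_counting_oracle_and_table(self, rng):
        n = 500
        p_old = rng.random(n)
        p_new = np.clip(p_old + rng.normal(0, 0.15, n), 0, 1)
        y = rng.integers(0, 2, n).astype(float)
        res = dv.nri(p_old, p_new, y, threshold=0.5, bootstrap_B=2000, seed=2)
        assert res.nri == pytest.approx(nri_counting_oracle(p_old, p_new, y, 0.5), abs=1e-12)
        # overall NRI recomputable from the returned table
        t = res.reclassification_table.astype(float)
        n_e, n_ne = t[..., 1].sum(), t[..., 0].sum()
        recomputed = (t[0, 1, 1] - t[1, 0, 1]) / n_e + (t[1, 0, 0] - t[0, 1, 0]) / n_ne
        assert res.nri == pytest.approx(recomputed, abs=1e-12)
        assert t.sum() == n

    def test_antisymmetry(self, rng):
        n = 200
        p_old, p_new = rng.random(n), rng.random(n)
        y = rng.integers(0, 2, n).astype(float)
        fwd = dv.nri(p_old, p_new, y, threshold=0.3, bootstrap_B=2000, seed=3)
        rev = dv.nri(p_new, p_old, y, threshold=0.3, bootstrap_B=2000, seed=3)
        assert fwd.nri == pytest.approx(-rev.nri)
        assert fwd.nri_event == pytest.approx(-rev.nri_event)
        assert fwd.nri_nonevent == pytest.approx(-rev.nri_nonevent)

    def test_default_threshold_is_prevalence(self, rng):
        p = rng.random(100)
        y = rng.integers(0, 2, 100).astype(float)
        res = dv.nri(p, p, y, bootstrap_B=2000, seed=4)
        assert res.threshold == pytest.approx(y.mean())

    def test_exchangeable_null_centred_on_zero(self):
        """Comparing a model against an independent relabeling of itself
        yields mean NRI within 2 Monte-Carlo SEs of 0."""
        rng = np.random.default_rng(77)
        vals = []
        for _ in range(200):
            n = 120
            y = rng.integers(0, 2, n).astype(float)
            if y.min() == y.max():
                continue
            p_old = rng.random(n)
            p_new = rng.permutation(p_old)
            vals.append(nri_counting_oracle(p_old, p_new, y, 0.5))
        vals = np.array(vals)
        mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) <= 2 * mc_se + 1e-12

    def test_degenerate_outcome_rejected(self, rng):
        p = rng.random(10)
        with pytest.raises(DegenerateOutcomeError):
            dv.nri(p, p, np.ones(10), threshold=0.5)


class TestInteraction:
    def test_constant_group_rejected(self, rng):
        lp = rng.normal(size=50)
        y = rng.integers(0, 2, 50).astype(float)
        with pytest.raises(CollinearityError):
            dv.interaction_test(lp, np.zeros(50), y)

    def test_detects_strong_interaction(self):
        rng = np.random.default_rng(8)
        n = 5000
        lp = -1.0 + rng.standard_normal(n)
        g = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < expit(lp + 1.0 * lp * g)).astype(float)
        table, p = dv.interaction_test(lp, g, y)
        assert p < 0.01
        assert set(table.index) == {"const", "lp", "group", "lp_x_group"}

    def test_null_interaction_large_p_typical(self):
        rng = np.random.default_rng(9)
        n = 5000
        lp = -1.0 + rng.standard_normal(n)
        g = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < expit(lp)).astype(float)
        _, p = dv.interaction_test(lp, g, y)
        assert p > 0.01  # a single null draw should rarely reject


class TestCompareAuc:
    def test_identical_and_monotone_predictions_zero_delta(self, rng):
        p = rng.random(100)
        y = rng.integers(0, 2, 100).astype(float)
        assert dv.compare_models_auc(p, p, y) == 0.0
        assert dv.compare_models_auc(p, p**3, y) == pytest.approx(0.0, abs=1e-12)

    def test_delta_equals_oracle_difference(self, rng):
        from .test_metrics import auc_pairwise_oracle

        p_old, p_new = rng.random(80), rng.random(80)
        y = rng.integers(0, 2, 80).astype(float)
        expected = auc_pairwise_oracle(p_new, y) - auc_pairwise_oracle(p_old, y)
        assert dv.compare_models_auc(p_old, p_new, y) == pytest.approx(expected, abs=1e-12)
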