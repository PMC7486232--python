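"""Discrimination, calibration and overall-performance metrics.

The metric suite mirrors the standard external-validation report for a
clinical risk model:

* AUC / c-statistic — pairwise concordance with ties counted one half,
  with a seeded nonparametric bootstrap percentile interval;
* Brier score — mean squared distance between predicted probability and
  outcome;
* calibration-in-the-large — the intercept of a one-parameter logistic
  recalibration of the outcome on the model's log-odds as a fixed offset
  (log-odds scale; 0 exactly when mean predicted risk equals prevalence);
* calibration slope — the slope of a free two-parameter logistic
  recalibration of the outcome on the predicted log-odds;
* unreliability test — the likelihood-ratio chi-square (2 df) of the free
  recalibration against the fixed null (intercept 0, slope 1), i.e. a test
  of departure from the 45-degree line;
* a flexible (locally weighted) calibration curve with pointwise bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import chi2, rankdata

from .errors import (
    DegenerateOutcomeError,
    UndefinedMetricError,
    ValidationError,
)

P_CLIP = 1e-12
UNRELIABILITY_DF = 2


@dataclass(frozen=True)
class PerformanceReport:
    """One validation stage's metric panel."""

    brier: float
    auc: float
    auc_ci: tuple[float, float]
    citl: float
    slope: float
    unreliability_chi2: float
    unreliability_p: float
    n: int
    prevalence: float

    def to_dict(self) -> dict:
        return {
            "brier": self.brier,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "citl": self.citl,
            "slope": self.slope,
            "unreliability_chi2": self.unreliability_chi2,
            "unreliability_p": self.unreliability_p,
            "n": self.n,
            "prevalence": self.prevalence,
        }


@dataclass(frozen=True)
class CalibrationCurve:
    """Plot-ready flexible calibration curve data."""

    grid: np.ndarray
    estimate: np.ndarray
    low: np.ndarray
    high: np.ndarray
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p": self.grid, "observed": self.estimate, "low": self.low, "high": self.high}
        )


def _check_binary(y: np.ndarray) -> np.ndarray:
    yv = np.asarray(y, dtype=float)
    if not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    return yv


def _check_both_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome is single-class")


def clipped_logit(p: np.ndarray) -> np.ndarray:
    """Log-odds with probabilities clamped to [1e-12, 1 - 1e-12]."""
    return logit(np.clip(np.asarray(p, dtype=float), P_CLIP, 1.0 - P_CLIP))


def auc(p: np.ndarray, y: np.ndarray) -> float:
    """Pairwise concordance probability, ties counted one half.

    Computed via the rank-sum (Mann-Whitney) identity, which equals the
    exhaustive pairwise count exactly, including tie handling.
    """
    yv = _check_binary(y)
    pv = np.asarray(p, dtype=float)
    if pv.shape != yv.shape:
        raise ValidationError("p and y must be aligned")
    n1 = int(yv.sum())
    n0 = len(yv) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC undefined with a single outcome class")
    ranks = rankdata(pv)
    return float((ranks[yv == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _auc_rows(P: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise AUC for resample matrices (rows with both classes only)."""
    n1 = Y.sum(axis=1)
    n0 = Y.shape[1] - n1
    ranks = rankdata(P, axis=1)
    s1 = (ranks * Y).sum(axis=1)
    return (s1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def bootstrap_auc_ci(
    p: np.ndarray,
    y: np.ndarray,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile interval of the AUC over B seeded subject resamples.

    Resamples that land on a single outcome class are redrawn.
    """
    if B < 200:
        raise ValidationError("B must be at least 200")
    yv = _check_binary(y)
    pv = np.asarray(p, dtype=float)
    _check_both_classes(yv)
    rng = np.random.default_rng(seed)
    n = len(yv)
    aucs = np.empty(B)
    filled = 0
    while filled < B:
        m = B - filled
        idx = rng.integers(0, n, size=(m, n))
        Yb = yv[idx]
        ok = (Yb.sum(axis=1) > 0) & (Yb.sum(axis=1) < n)
        k = int(ok.sum())
        if k:
            aucs[filled : filled + k] = _auc_rows(pv[idx[ok]], Yb[ok])
            filled += k
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def brier(p: np.ndarray, y: np.ndarray) -> float:
    """Mean squared difference between predicted probability and outcome."""
    yv = _check_binary(y)
    pv = np.asarray(p, dtype=float)
    if pv.shape != yv.shape:
        raise ValidationError("p and y must be aligned")
    return float(np.mean((pv - yv) ** 2))


def calibration_in_the_large(p: np.ndarray, y: np.ndarray) -> float:
    """Intercept of the one-parameter offset recalibration, on the log-odds scale.

    Solves the score equation ``mean(expit(a + logit(p))) = mean(y)`` exactly
    by bracketed root finding; positive when the model under-predicts.
    """
    yv = _check_binary(y)
    _check_both_classes(yv)
    lp = clipped_logit(p)
    target = yv.mean()

    def gap(a: float) -> float:
        return float(np.mean(expit(a + lp))) - target

    return float(brentq(gap, -60.0, 60.0, xtol=1e-12))


def _free_recalibration(p: np.ndarray, y: np.ndarray):
    """Two-parameter logistic recalibration of y on logit(p)."""
    yv = _check_binary(y)
    _check_both_classes(yv)
    lp = clipped_logit(p)
    if lp.min() == lp.max():
        raise UndefinedMetricError("constant predictions: recalibration slope undefined")
    X = sm.add_constant(lp)
    return sm.GLM(yv, X, family=sm.families.Binomial()).fit()


def calibration_slope(p: np.ndarray, y: np.ndarray) -> float:
    """Slope of the logistic regression of the outcome on predicted log-odds."""
    return float(_free_recalibration(p, y).params[1])


def unreliability_test(p: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Likelihood-ratio test of the calibration line against the diagonal.

    Compares the free intercept-and-slope recalibration with the fixed null
    (intercept 0, slope 1) on ``UNRELIABILITY_DF = 2`` degrees of freedom;
    returns ``(statistic, upper-tail p)``.
    """
    res = _free_recalibration(p, y)
    yv = np.asarray(y, dtype=float)
    lp = clipped_logit(p)
    ll_null = float(yv @ lp - np.logaddexp(0.0, lp).sum())
    stat = max(0.0, 2.0 * (float(res.llf) - ll_null))
    return stat, unreliability_pvalue(stat)


def unreliability_pvalue(statistic: float) -> float:
    """Upper-tail probability of the 2-df chi-square reference."""
    if statistic < 0:
        raise ValidationError("chi-square statistic must be non-negative")
    return float(chi2.sf(statistic, UNRELIABILITY_DF))


def flexible_calibration_curve(
    p: np.ndarray,
    y: np.ndarray,
    grid_size: int = 50,
    span: float = 0.75,
) -> CalibrationCurve:
    """Locally weighted (tricube local-linear) smooth of outcome on prediction.

    Evaluated on an even grid across the observed prediction range, with
    pointwise normal-approximation bands from the local binomial variance.
    Refuses tiny samples, where a grouped calibration table is the honest
    display.
    """
    yv = _check_binary(y)
    pv = np.asarray(p, dtype=float)
    n = len(pv)
    if n < 20:
        raise ValidationError(
            "n < 20: too few subjects for a flexible curve; use grouped calibration"
        )
    if pv.min() == pv.max():
        g = np.array([pv[0]])
        e = np.array([yv.mean()])
        half = 1.96 * np.sqrt(max(e[0] * (1 - e[0]), 1e-12) / n)
        return CalibrationCurve(g, e, e - half, e + half, degenerate=True)

    grid = np.linspace(pv.min(), pv.max(), grid_size)
    k = max(4, int(np.ceil(span * n)))
    est = np.empty(grid_size)
    var = np.empty(grid_size)
    for i, x0 in enumerate(grid):
        d = np.abs(pv - x0)
        h = np.partition(d, k - 1)[k - 1]
        h = max(h, 1e-9)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, 1.0) ** 3
        # Local linear fit: est = l(x0) @ y with hat weights l from the
        # weighted normal equations.
        Xl = np.column_stack([np.ones(n), pv - x0])
        WX = Xl * w[:, None]
        G = Xl.T @ WX
        l_row = np.linalg.solve(G, WX.T)[0]
        est[i] = float(l_row @ yv)
        mu = min(max(est[i], 1e-6), 1.0 - 1e-6)
        var[i] = float((l_row**2).sum() * mu * (1.0 - mu))
    half = 1.96 * np.sqrt(var)
    return CalibrationCurve(grid, np.clip(est, 0.0, 1.0), est - half, est + half)


def roc_curve_points(p: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """FPR/TPR pairs across all thresholds, for ROC plotting."""
    yv = _check_binary(y)
    _check_both_classes(yv)
    order = np.argsort(-np.asarray(p, dtype=float), kind="stable")
    ys = yv[order]
    tpr = np.concatenate([[0.0], np.cumsum(ys) / ys.sum()])
    fpr = np.concatenate([[0.0], np.cumsum(1 - ys) / (len(ys) - ys.sum())])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def performance_report(
    p: np.ndarray,
    y: np.ndarray,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> PerformanceReport:
    """Assemble the full metric panel for one set of predictions."""
    yv = _check_binary(y)
    a = auc(p, yv)
    ci = bootstrap_auc_ci(p, yv, B=B, level=level, seed=seed)
    stat, pval = unreliability_test(p, yv)
    return PerformanceReport(
        brier=brier(p, yv),
        auc=a,
        auc_ci=ci,
        citl=calibration_in_the_large(p, yv),
        slope=calibration_slope(p, yv),
        unreliability_chi2=stat,
        unreliability_p=pval,
        n=len(yv),
        prevalence=float(yv.mean()),
    )
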