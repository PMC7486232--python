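"""Sensitivity analyses: categorical NRI and the LP x group interaction test.

Adding a candidate predictor (here: former-child-soldier status) to a
transferred risk score is judged two ways:

* **Net reclassification improvement** over a two-level risk categorization
  (high iff predicted risk >= threshold). The events component counts the
  net fraction of events moved up; the non-events component the net fraction
  of non-events moved down; both are positive when the new model improves.
  A rendering with the non-events component sign-flipped is also reported,
  since some papers print that component with the opposite sign.
* **Interaction test** — an unpenalized logistic fit of the outcome on the
  transferred linear predictor, the group flag, and their product, with a
  Wald test on the product term: does the score predict differently across
  groups?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    ConvergenceError,
    DegenerateOutcomeError,
    ValidationError,
)
from .metrics import auc, _check_binary


@dataclass(frozen=True)
class RiskCategories:
    threshold: float
    high: np.ndarray  # boolean per subject


@dataclass(frozen=True)
class NRIResult:
    nri: float
    nri_event: float
    nri_nonevent: float
    se: float
    ci: tuple[float, float]
    ci_event: tuple[float, float]
    ci_nonevent: tuple[float, float]
    reclassification_table: np.ndarray  # (old, new, outcome) counts, 2x2x2
    threshold: float

    def to_dict(self) -> dict:
        return {
            "nri": self.nri,
            "nri_event": self.nri_event,
            "nri_nonevent": self.nri_nonevent,
            "se": self.se,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "ci_event": list(self.ci_event),
            "ci_nonevent": list(self.ci_nonevent),
            "threshold": self.threshold,
            "reclassification_table": self.reclassification_table.tolist(),
            # Some reports print the non-events component with the opposite
            # sign (negative when non-events improve); provided for comparison.
            "paper_convention": {
                "nri_plus": self.nri_event,
                "nri_minus": -self.nri_nonevent,
            },
        }


def classify_risk(p: np.ndarray, threshold: float) -> RiskCategories:
    """Two-level risk categorization; the boundary is assigned high."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must lie strictly in (0, 1): {threshold}")
    pv = np.asarray(p, dtype=float)
    return RiskCategories(threshold=float(threshold), high=pv >= threshold)


def _components(
    old_high: np.ndarray, new_high: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    ev = y == 1
    ne = ~ev
    up = ~old_high & new_high
    down = old_high & ~new_high
    comp_e = (up[ev].sum() - down[ev].sum()) / ev.sum()
    comp_ne = (down[ne].sum() - up[ne].sum()) / ne.sum()
    return float(comp_e), float(comp_ne)


def nri(
    p_old: np.ndarray,
    p_new: np.ndarray,
    y: np.ndarray,
    threshold: float | None = None,
    bootstrap_B: int = 2000,
    seed: int = 0,
) -> NRIResult:
    """Categorical net reclassification improvement with bootstrap CI.

    ``threshold=None`` uses the observed outcome prevalence (a
    prevalence-anchored cut-point). The asymptotic SE combines the binomial
    variances of the two components; the CI is a seeded percentile bootstrap
    over subjects (resamples missing a class are redrawn).
    """
    yv = _check_binary(y)
    if yv.min() == yv.max():
        raise DegenerateOutcomeError("NRI needs both outcome classes")
    po = np.asarray(p_old, dtype=float)
    pn = np.asarray(p_new, dtype=float)
    if not (po.shape == pn.shape == yv.shape):
        raise ValidationError("p_old, p_new and y must be aligned")
    thr = float(yv.mean()) if threshold is None else float(threshold)
    old_high = classify_risk(po, thr).high
    new_high = classify_risk(pn, thr).high

    comp_e, comp_ne = _components(old_high, new_high, yv)
    overall = comp_e + comp_ne

    table = np.zeros((2, 2, 2), dtype=int)
    for o in (0, 1):
        for nw in (0, 1):
            for out in (0, 1):
                table[o, nw, out] = int(
                    ((old_high == o) & (new_high == nw) & (yv == out)).sum()
                )

    n_e = int(yv.sum())
    n_ne = len(yv) - n_e
    ev = yv == 1
    up_e = float((~old_high & new_high)[ev].mean())
    down_e = float((old_high & ~new_high)[ev].mean())
    up_ne = float((~old_high & new_high)[~ev].mean())
    down_ne = float((old_high & ~new_high)[~ev].mean())
    var_e = (up_e + down_e - (up_e - down_e) ** 2) / n_e
    var_ne = (up_ne + down_ne - (down_ne - up_ne) ** 2) / n_ne
    se = float(np.sqrt(var_e + var_ne))

    rng = np.random.default_rng(seed)
    n = len(yv)
    boots = np.empty((bootstrap_B, 3))
    filled = 0
    while filled < bootstrap_B:
        idx = rng.integers(0, n, size=n)
        yb = yv[idx]
        if yb.min() == yb.max():
            continue
        ce, cne = _components(old_high[idx], new_high[idx], yb)
        boots[filled] = (ce + cne, ce, cne)
        filled += 1
    qs = np.quantile(boots, [0.025, 0.975], axis=0)
    return NRIResult(
        nri=overall,
        nri_event=comp_e,
        nri_nonevent=comp_ne,
        se=se,
        ci=(float(qs[0, 0]), float(qs[1, 0])),
        ci_event=(float(qs[0, 1]), float(qs[1, 1])),
        ci_nonevent=(float(qs[0, 2]), float(qs[1, 2])),
        reclassification_table=table,
        threshold=thr,
    )


def interaction_test(
    lp: np.ndarray, group: np.ndarray, y: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """Wald test of the linear-predictor x group interaction.

    Fits ``y ~ lp + group + lp:group`` by unpenalized maximum likelihood and
    returns the coefficient table plus the interaction term's p-value.
    """
    yv = _check_binary(y)
    if yv.min() == yv.max():
        raise DegenerateOutcomeError("interaction test needs both outcome classes")
    lpv = np.asarray(lp, dtype=float)
    gv = np.asarray(group, dtype=float)
    if not (lpv.shape == gv.shape == yv.shape):
        raise ValidationError("lp, group and y must be aligned")
    if gv.min() == gv.max():
        raise CollinearityError("group indicator is constant; interaction undefined")

    X = pd.DataFrame({"const": 1.0, "lp": lpv, "group": gv, "lp_x_group": lpv * gv})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yv, X).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, Exception) as exc:  # noqa: BLE001
            raise ConvergenceError(
                "interaction model did not converge (possible separation); "
                "consider a penalized fit or larger sample"
            ) from exc
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 50:
        raise ConvergenceError(
            "interaction model did not converge (possible separation); "
            "consider a penalized fit or larger sample"
        )
    coef_table = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "z": res.tvalues,
            "p": res.pvalues,
        }
    )
    return coef_table, float(res.pvalues["lp_x_group"])


def compare_models_auc(p_old: np.ndarray, p_new: np.ndarray, y: np.ndarray) -> float:
    """AUC(new) - AUC(old) on the same subjects."""
    return auc(p_new, y) - auc(p_old, y)
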