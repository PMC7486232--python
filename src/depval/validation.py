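"""The three-stage external-validation ladder.

A risk model developed in one cohort is carried to another three ways:

1. **standard** — applied unchanged; case-mix and baseline-risk differences
   show up as miscalibration (large calibration-in-the-large when the target
   prevalence differs from development);
2. **adjusted** — the intercept alone is re-estimated by maximum likelihood
   with the transferred linear predictor held as a fixed offset, so average
   predicted risk matches observed prevalence (recalibration-in-the-large);
3. **refitted** — all coefficients are re-estimated in the target cohort by
   penalized maximum likelihood over the same predictor schema.

Discrimination is untouched by the intercept update (the AUC is invariant
under monotone transforms), so stages 1 and 2 share the AUC exactly; the
refit changes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .metrics import PerformanceReport, calibration_in_the_large, performance_report
from .pmle import (
    PredictionSet,
    RiskModel,
    choose_penalty,
    fit_pmle,
    linear_predictor,
    predict_prob,
)

STAGE_LABELS = ("standard", "adjusted", "refitted")
DEFAULT_LAM_GRID = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)

#: Row order of the rendered stage-comparison table.
TABLE_ROWS = (
    "brier",
    "auc",
    "auc_ci_low",
    "auc_ci_high",
    "citl",
    "slope",
    "unreliability_chi2",
    "unreliability_p",
)


@dataclass(frozen=True)
class ValidationStage:
    label: str
    model: RiskModel
    predictions: PredictionSet
    report: PerformanceReport


def _outcome(cohort: pd.DataFrame, outcome_col: str) -> np.ndarray:
    if outcome_col not in cohort.columns:
        raise SchemaError(f"cohort lacks outcome column {outcome_col!r}")
    y = cohort[outcome_col].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("outcome contains missing values; filter the cohort first")
    return y


def standard_validation(
    model: RiskModel,
    cohort: pd.DataFrame,
    outcome_col: str = "y",
    B: int = 2000,
    seed: int = 0,
) -> ValidationStage:
    """Apply the development model unchanged and report its performance."""
    y = _outcome(cohort, outcome_col)
    preds = predict_prob(model, cohort)
    return ValidationStage(
        label="standard",
        model=model,
        predictions=preds,
        report=performance_report(preds.p, y, B=B, seed=seed),
    )


def recalibrate_intercept(
    model: RiskModel, cohort: pd.DataFrame, outcome_col: str = "y"
) -> RiskModel:
    """Re-estimate the intercept with the linear predictor as a fixed offset.

    The one-parameter offset likelihood is maximized exactly (its score
    equation matches mean predicted probability to observed prevalence), so
    the adjusted predictions have calibration-in-the-large 0 by construction.
    Idempotent: recalibrating an already-calibrated model shifts nothing.
    """
    y = _outcome(cohort, outcome_col)
    lp = linear_predictor(model, cohort)
    delta = calibration_in_the_large(1.0 / (1.0 + np.exp(-lp)), y)
    return model.with_intercept(
        model.intercept + delta, provenance="intercept-recalibrated"
    )


def refit_model(
    schema: list[str],
    cohort: pd.DataFrame,
    lam_strategy: str | float = "grid",
    outcome_col: str = "y",
    lam_grid: tuple[float, ...] = DEFAULT_LAM_GRID,
    B: int = 2000,
    seed: int = 0,
) -> ValidationStage:
    """Re-estimate all coefficients in the target cohort.

    ``lam_strategy`` is ``"unpenalized"``, ``"grid"`` (modified-AIC selection
    over ``lam_grid``), or a fixed non-negative penalty value.
    """
    y = _outcome(cohort, outcome_col)
    X = cohort[list(schema)]
    if lam_strategy == "unpenalized":
        lam = 0.0
    elif lam_strategy == "grid":
        lam = choose_penalty(X, y, list(lam_grid))
    elif isinstance(lam_strategy, (int, float)):
        lam = float(lam_strategy)
    else:
        raise ValidationError(f"unknown lam_strategy: {lam_strategy!r}")
    model = fit_pmle(X, y, lam, provenance=f"refitted (lambda={lam:g})")
    preds = predict_prob(model, cohort)
    return ValidationStage(
        label="refitted",
        model=model,
        predictions=preds,
        report=performance_report(preds.p, y, B=B, seed=seed),
    )


def run_validation_suite(
    model: RiskModel,
    cohort: pd.DataFrame,
    outcome_col: str = "y",
    stages: tuple[str, ...] = STAGE_LABELS,
    lam_strategy: str | float = "grid",
    B: int = 2000,
    seed: int = 0,
) -> list[ValidationStage]:
    """Run the ladder standard -> adjusted -> refitted on one target cohort."""
    unknown = set(stages) - set(STAGE_LABELS)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    y = _outcome(cohort, outcome_col)
    out: list[ValidationStage] = []
    if "standard" in stages:
        out.append(standard_validation(model, cohort, outcome_col, B=B, seed=seed))
    if "adjusted" in stages:
        adj = recalibrate_intercept(model, cohort, outcome_col)
        preds = predict_prob(adj, cohort)
        out.append(
            ValidationStage(
                label="adjusted",
                model=adj,
                predictions=preds,
                report=performance_report(preds.p, y, B=B, seed=seed),
            )
        )
    if "refitted" in stages:
        out.append(
            refit_model(
                list(model.predictor_names),
                cohort,
                lam_strategy=lam_strategy,
                outcome_col=outcome_col,
                B=B,
                seed=seed,
            )
        )
    return out


def stage_table(stages: list[ValidationStage], decimals: int | None = 2) -> pd.DataFrame:
    """Stage-comparison table (rows = metrics, columns = stages).

    ``decimals`` rounds half-even for rendering; ``None`` keeps full precision.
    """
    cols = {}
    for st in stages:
        d = st.report.to_dict()
        cols[st.label] = [d[r] for r in TABLE_ROWS]
    table = pd.DataFrame(cols, index=list(TABLE_ROWS))
    if decimals is not None:
        table = table.round(decimals)
    return table
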