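"""Penalized maximum-likelihood (ridge) logistic regression.

The transferable risk model is a logistic regression fitted by maximizing

    l(alpha, beta) - (lambda / 2) * sum_j (s_j * beta_j)**2

where ``l`` is the Bernoulli log-likelihood, the intercept is unpenalized,
and ``s_j`` is the standard deviation of predictor ``j`` in the fitting data
(so the penalty acts on standardized coefficients). The quadratic penalty
keeps coefficients finite under quasi-separation and shrinks them toward
zero, trading a little bias for transportability — the usual remedy for
overfitting in small clinical prediction models.

Penalty strength can be chosen on a grid by a modified AIC: the likelihood
ratio chi-square of the fitted model minus twice its effective degrees of
freedom, the latter computed from the penalized information matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import (
    ConvergenceError,
    DegenerateOutcomeError,
    SchemaError,
    UnidentifiablePredictorError,
    ValidationError,
)

MODEL_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class RiskModel:
    """A fitted (or transferred) logistic risk score.

    ``scaling`` stores the per-predictor standardization constants computed
    on the fitting data, so the penalty and any later refit are reproducible
    after serialization. Serialization round-trips bit-exactly (floats pass
    through JSON's repr round-trip).
    """

    predictor_names: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    lam: float = 0.0
    scaling: dict[str, float] = field(default_factory=dict)
    provenance: str = ""
    standard_errors: dict[str, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))
        if set(self.predictor_names) != set(self.coefficients):
            raise SchemaError("coefficient names do not match predictor_names")
        if self.lam < 0:
            raise ValidationError(f"penalty must be non-negative: {self.lam}")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[n] for n in self.predictor_names])

    def with_intercept(self, intercept: float, provenance: str | None = None) -> "RiskModel":
        return replace(
            self,
            intercept=float(intercept),
            provenance=self.provenance if provenance is None else provenance,
        )

    def to_dict(self) -> dict:
        d = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "predictor_names": list(self.predictor_names),
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "lambda": self.lam,
            "scaling": self.scaling,
            "provenance": self.provenance,
        }
        if self.standard_errors is not None:
            d["standard_errors"] = self.standard_errors
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(
            predictor_names=tuple(d["predictor_names"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            intercept=float(d["intercept"]),
            lam=float(d.get("lambda", 0.0)),
            scaling={k: float(v) for k, v in d.get("scaling", {}).items()},
            provenance=d.get("provenance", ""),
            standard_errors=(
                {k: float(v) for k, v in d["standard_errors"].items()}
                if "standard_errors" in d
                else None
            ),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class PredictionSet:
    """Per-subject linear predictors and probabilities, aligned to a cohort."""

    subject_id: tuple[str, ...]
    lp: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        assert len(self.subject_id) == len(self.lp) == len(self.p)


def _design(X: pd.DataFrame, names: list[str]) -> np.ndarray:
    missing = [n for n in names if n not in X.columns]
    if missing:
        raise SchemaError(f"design lacks predictors: {missing}")
    return X[list(names)].to_numpy(dtype=float)


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably.
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_pmle(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    lam: float = 0.0,
    *,
    predictor_names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    provenance: str = "development fit",
) -> RiskModel:
    """Fit the ridge-penalized logistic model by Newton iteration.

    Newton steps on the penalized log-likelihood with step-halving;
    convergence is declared at penalized-gradient norm below ``tol``.
    Zero-variance predictor columns are unidentifiable at ``lam == 0``
    (error); with a positive penalty they are retained in the schema with
    coefficient 0 and a warning, mirroring how an all-zero predictor (e.g.
    universally denied drug use) is handled in a refit.
    """
    if lam < 0:
        raise ValidationError(f"penalty must be non-negative: {lam}")
    names = list(predictor_names) if predictor_names is not None else list(X.columns)
    A_full = _design(X, names)
    yv = np.asarray(y, dtype=float)
    if yv.ndim != 1 or yv.shape[0] != A_full.shape[0]:
        raise ValidationError("y must be a vector aligned to X rows")
    if np.isnan(A_full).any() or np.isnan(yv).any():
        raise ValidationError("missing values in the design or outcome")
    if not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    if yv.min() == yv.max():
        raise DegenerateOutcomeError("outcome is single-class; nothing to fit")

    s_full = A_full.std(axis=0, ddof=0)
    zero_var = s_full == 0.0
    if zero_var.any():
        culprits = [n for n, z in zip(names, zero_var) if z]
        if lam == 0.0:
            raise UnidentifiablePredictorError(
                f"zero-variance predictors with no penalty: {culprits}"
            )
        warnings.warn(
            f"zero-variance predictors forced to coefficient 0: {culprits}",
            stacklevel=2,
        )
    keep = ~zero_var
    A = np.column_stack([np.ones(A_full.shape[0]), A_full[:, keep]])
    s = s_full[keep]
    k = A.shape[1]
    # Penalty on standardized slopes only; the intercept is free.
    P = np.diag(np.concatenate([[0.0], lam * s**2]))

    prev = float(yv.mean())
    theta = np.zeros(k)
    theta[0] = np.log(prev / (1.0 - prev))

    def objective(th: np.ndarray) -> float:
        return _loglik(A @ th, yv) - 0.5 * th @ P @ th

    obj = objective(theta)
    converged = False
    H = None
    for _ in range(max_iter):
        eta = A @ theta
        p = expit(eta)
        g = A.T @ (yv - p) - P @ theta
        if np.linalg.norm(g) < tol:
            converged = True
            break
        W = p * (1.0 - p)
        H = A.T @ (A * W[:, None]) + P
        step = np.linalg.solve(H, g)
        # Step-halving keeps the iteration inside the concave objective's
        # ascent region even under quasi-separation.
        t = 1.0
        for _ in range(30):
            cand = theta + t * step
            cobj = objective(cand)
            if cobj >= obj - 1e-12:
                theta, obj = cand, cobj
                break
            t *= 0.5
        else:
            raise ConvergenceError("step-halving failed to find an ascent step")
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} Newton iterations")

    if H is None:  # converged at the start
        p = expit(A @ theta)
        W = p * (1.0 - p)
        H = A.T @ (A * W[:, None]) + P
    se_kept = np.sqrt(np.diag(np.linalg.inv(H)))

    coefs = dict.fromkeys(names, 0.0)
    ses = dict.fromkeys(names, float("nan"))
    for j, name in enumerate(np.array(names)[keep]):
        coefs[name] = float(theta[1 + j])
        ses[name] = float(se_kept[1 + j])
    ses["(intercept)"] = float(se_kept[0])
    return RiskModel(
        predictor_names=tuple(names),
        coefficients=coefs,
        intercept=float(theta[0]),
        lam=float(lam),
        scaling={n: float(sv) for n, sv in zip(names, s_full)},
        provenance=provenance,
        standard_errors=ses,
    )


def penalty_profile(
    X: pd.DataFrame, y: np.ndarray | pd.Series, lam_grid: list[float]
) -> pd.DataFrame:
    """Likelihood-ratio statistic, effective df, and modified AIC per lambda.

    Effective degrees of freedom are ``trace(I @ (I + P)^-1)`` with ``I`` the
    unpenalized observed information at the penalized solution and ``P`` the
    penalty Hessian; the intercept contributes one full degree. The modified
    AIC is ``LR - 2 * df_eff`` where ``LR = 2 * (l(theta_hat) - l(null))``
    uses unpenalized log-likelihoods.
    """
    if len(lam_grid) == 0:
        raise ValidationError("empty penalty grid")
    if any(l < 0 for l in lam_grid):
        raise ValidationError("penalty grid must be non-negative")
    yv = np.asarray(y, dtype=float)
    prev = yv.mean()
    ll_null = float(
        yv.sum() * np.log(prev) + (len(yv) - yv.sum()) * np.log(1.0 - prev)
    )
    rows = []
    for lam in sorted(lam_grid):
        try:
            model = fit_pmle(X, yv, lam)
        except UnidentifiablePredictorError:
            if len(lam_grid) == 1:
                raise
            warnings.warn(
                f"skipping lambda={lam:g}: unidentifiable zero-variance predictor",
                stacklevel=2,
            )
            continue
        names = list(model.predictor_names)
        keep = [n for n in names if model.scaling[n] > 0.0]
        A = np.column_stack([np.ones(len(X)), X[keep].to_numpy(dtype=float)])
        theta = np.concatenate([[model.intercept], [model.coefficients[n] for n in keep]])
        p = expit(A @ theta)
        W = p * (1.0 - p)
        info = A.T @ (A * W[:, None])
        P = np.diag(
            np.concatenate([[0.0], lam * np.array([model.scaling[n] for n in keep]) ** 2])
        )
        df_eff = float(np.trace(np.linalg.solve(info + P, info)))
        ll = _loglik(A @ theta, yv)
        lr = 2.0 * (ll - ll_null)
        rows.append(
            {"lam": lam, "loglik": ll, "lr": lr, "df_eff": df_eff, "maic": lr - 2.0 * df_eff}
        )
    return pd.DataFrame(rows)


def choose_penalty(
    X: pd.DataFrame, y: np.ndarray | pd.Series, lam_grid: list[float]
) -> float:
    """Grid value maximizing the modified AIC; ties break toward larger lambda."""
    prof = penalty_profile(X, y, lam_grid)
    best = prof.iloc[0]
    for _, row in prof.iterrows():
        if row["maic"] >= best["maic"] - 1e-10:
            best = row
    return float(best["lam"])


def linear_predictor(model: RiskModel, X: pd.DataFrame) -> np.ndarray:
    """LP_i = intercept + sum_j beta_j x_ij, matching columns by name."""
    A = _design(X, list(model.predictor_names))
    return model.intercept + A @ model.beta


def predict_prob(model: RiskModel, X: pd.DataFrame) -> PredictionSet:
    """Predicted probabilities via the inverse logit, clamped away from {0, 1}."""
    lp = linear_predictor(model, X)
    p = np.clip(expit(lp), 1e-12, 1.0 - 1e-12)
    ids = (
        tuple(str(s) for s in X["subject_id"])
        if "subject_id" in X.columns
        else tuple(str(i) for i in range(len(X)))
    )
    return PredictionSet(subject_id=ids, lp=lp, p=p)
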