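"""Synthetic cohort generation.

Emulates two longitudinal adolescent cohorts — a low-prevalence development
population (Pelotas-like, point prevalence of late-adolescent depression
about 3.1%) and a high-prevalence validation population (Nepal-like, wave-3
prevalence about 19.8%, including former child soldiers) — with seven binary
risk predictors, per-wave ages, and per-wave DSRS symptom totals, so the full
external-validation ladder can be exercised without any real data.

Predictors are drawn independently at configured marginal frequencies; the
binary depression outcome follows a logistic model whose intercept is solved
exactly so the population prevalence hits a configured target; wave-3 DSRS
totals are drawn from truncated discrete distributions on either side of the
clinical cutoff so that scoring the totals reproduces the outcome.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .errors import SchemaError, UnsupportedConfigError, ValidationError

SCHEMA_VERSION = "1.0"

#: The seven binary predictors shared by both cohorts, with the validation
#: cohort's observed marginal frequencies.
DEFAULT_PREDICTOR_FREQS: dict[str, float] = {
    "female": 0.341,
    "low_caste": 0.183,
    "drug_use": 0.0,
    "school_failure": 0.143,
    "social_isolation": 0.056,
    "fights": 0.135,
    "maltreatment": 0.477,
}

#: Data-generating log-odds effects. Modest, plausible effect sizes for
#: adolescent depression risk factors; the magnitudes matter only through the
#: discrimination/calibration structure they induce.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "female": 0.9,
    "low_caste": 0.4,
    "drug_use": 0.7,
    "school_failure": 0.5,
    "social_isolation": 0.6,
    "fights": 0.4,
    "maltreatment": 0.8,
}

COHORT_COLUMNS = (
    ["subject_id"]
    + list(DEFAULT_PREDICTOR_FREQS)
    + ["age_w1", "age_w2", "age_w3", "dsrs_w1", "dsrs_w2", "dsrs_w3", "soldier", "y"]
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic cohort.

    Parameters
    ----------
    n_subjects
        Cohort size at wave 1.
    predictor_freqs
        Marginal Bernoulli frequency per binary predictor.
    coefficients
        Log-odds effect per predictor in the outcome model.
    target_prevalence
        Population outcome probability; the intercept is solved to hit it.
    group_freq
        Frequency of the former-child-soldier flag.
    group_coef
        Log-odds shift for the group flag (0 by default, so the
        linear-predictor x group interaction null holds by construction).
    wave_age_range
        Inclusive integer bounds of age at wave 1; waves are spaced 1 and 4
        years apart (2007 -> 2008 -> 2012).
    dsrs_noise
        Mean distance of wave-3 DSRS totals from the clinical cutoff;
        controls how concentrated symptom scores are near it.
    prior_depression_rate
        Fraction of subjects given an above-cutoff DSRS total at wave 1 or 2
        (prior-depression records, excluded by the eligibility filter).
    dropout_w2, dropout_w3
        Monotone missed-assessment fractions at waves 2 and 3.
    seed
        Seed for all randomness; identical configs yield identical cohorts.
    """

    n_subjects: int = 126
    predictor_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREDICTOR_FREQS)
    )
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    target_prevalence: float = 0.198
    group_freq: float = 0.437
    group_coef: float = 0.0
    wave_age_range: tuple[int, int] = (11, 17)
    dsrs_noise: float = 3.0
    prior_depression_rate: float = 0.0
    dropout_w2: float = 0.0
    dropout_w3: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1 (empty cohort requested)")
        for name, f in self.predictor_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"frequency of {name!r} outside [0, 1]: {f}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValidationError(
                f"target_prevalence must lie strictly in (0, 1): {self.target_prevalence}"
            )
        for attr in ("group_freq", "prior_depression_rate", "dropout_w2", "dropout_w3"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{attr} outside [0, 1]: {v}")
        unknown = set(self.coefficients) - set(self.predictor_freqs)
        if unknown:
            raise SchemaError(f"coefficients for unknown predictors: {sorted(unknown)}")
        lo, hi = self.wave_age_range
        if lo > hi:
            raise ValidationError(f"wave_age_range reversed: {self.wave_age_range}")
        if self.dsrs_noise <= 0:
            raise ValidationError("dsrs_noise must be positive")

    @property
    def predictor_names(self) -> list[str]:
        return list(self.predictor_freqs)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["wave_age_range"] = list(self.wave_age_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "wave_age_range" in d:
            d["wave_age_range"] = tuple(d["wave_age_range"])
        return cls(**d)


def development_config(seed: int = 0, n_subjects: int = 4000) -> GeneratorConfig:
    """Pelotas-like development cohort: ~3.1% prevalence, drug use 62.4%."""
    freqs = dict(DEFAULT_PREDICTOR_FREQS)
    freqs["drug_use"] = 0.624
    return GeneratorConfig(
        n_subjects=n_subjects,
        predictor_freqs=freqs,
        target_prevalence=0.031,
        group_freq=0.0,
        wave_age_range=(15, 15),
        seed=seed,
    )


def validation_config(seed: int = 1, n_subjects: int = 516) -> GeneratorConfig:
    """Nepal-like validation cohort at baseline: ~19.8% wave-3 prevalence,
    43.7% former child soldiers, nobody reporting drug use, 11-17 at wave 1,
    with realistic follow-up loss (wave Ns 516 -> ~456 -> ~290)."""
    return GeneratorConfig(
        n_subjects=n_subjects,
        target_prevalence=0.198,
        group_freq=0.437,
        wave_age_range=(11, 17),
        prior_depression_rate=0.10,
        dropout_w2=0.116,
        dropout_w3=0.438,
        seed=seed,
    )


def solve_intercept_for_prevalence(
    coefficients: dict[str, float],
    predictor_freqs: dict[str, float],
    target_prevalence: float,
) -> float:
    """Intercept making the marginal outcome probability hit a target.

    Under independent Bernoulli predictors and a logistic outcome model the
    marginal prevalence is an exact sum over predictor patterns; only
    predictors with a nonzero coefficient contribute, so the enumeration runs
    over at most ``2**k_active`` patterns. Solved by Brent root finding to
    better than 1e-10 in the prevalence.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValidationError("target_prevalence must lie strictly in (0, 1)")
    for name, f in predictor_freqs.items():
        if not 0.0 <= f <= 1.0:
            raise ValidationError(f"frequency of {name!r} outside [0, 1]: {f}")
    missing = set(coefficients) - set(predictor_freqs)
    if missing:
        raise SchemaError(f"no frequency for predictors: {sorted(missing)}")

    active = [n for n, b in coefficients.items() if b != 0.0 and predictor_freqs[n] > 0.0]
    if len(active) > 20:
        raise UnsupportedConfigError(
            f"{len(active)} active predictors exceed the exact-enumeration limit (20)"
        )
    beta = np.array([coefficients[n] for n in active])
    freqs = np.array([predictor_freqs[n] for n in active])

    if not active:
        return float(np.log(target_prevalence / (1.0 - target_prevalence)))

    patterns = np.array(list(itertools.product((0, 1), repeat=len(active))), dtype=float)
    weights = np.prod(
        np.where(patterns == 1, freqs, 1.0 - freqs), axis=1
    )
    offsets = patterns @ beta

    def gap(alpha: float) -> float:
        return float(weights @ expit(alpha + offsets)) - target_prevalence

    return float(brentq(gap, -60.0, 60.0, xtol=1e-12))


def _truncated_geometric(
    rng: np.random.Generator, size: int, max_offset: int, mean: float
) -> np.ndarray:
    """Draw from a geometric pmf ~ q**k truncated to {0, ..., max_offset}.

    ``q`` is chosen so the untruncated mean equals ``mean``; truncation pulls
    the realized mean slightly below that.
    """
    if size == 0:
        return np.zeros(0, dtype=int)
    q = mean / (1.0 + mean)
    pmf = q ** np.arange(max_offset + 1)
    pmf /= pmf.sum()
    return rng.choice(max_offset + 1, size=size, p=pmf)


def _draw_dsrs(
    rng: np.random.Generator, depressed: np.ndarray, dsrs_noise: float, cutoff: int = 14
) -> np.ndarray:
    """Wave-3 DSRS totals consistent with the outcome under the >= cutoff rule.

    Cases sit on [cutoff, 36] decaying upward from the cutoff; non-cases on
    [0, cutoff-1] decaying downward from just below it (mean distance about
    twice ``dsrs_noise``). With the defaults nearly all mass lies below ~22,
    matching the range typically observed in community adolescent samples.
    """
    n = depressed.size
    totals = np.empty(n, dtype=int)
    idx_case = np.flatnonzero(depressed)
    idx_ctrl = np.flatnonzero(~depressed)
    totals[idx_case] = cutoff + _truncated_geometric(
        rng, idx_case.size, 36 - cutoff, dsrs_noise
    )
    totals[idx_ctrl] = (cutoff - 1) - _truncated_geometric(
        rng, idx_ctrl.size, cutoff - 1, 2.0 * dsrs_noise
    )
    return totals


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one cohort table; fully deterministic given the config seed.

    Column layout: ``subject_id``, one 0/1 column per predictor, ``age_w1`` ..
    ``age_w3`` (waves spaced 1 and 4 years), ``dsrs_w1`` .. ``dsrs_w3``
    (missing assessments as NaN), ``soldier`` and the binary outcome ``y``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    names = config.predictor_names

    X = pd.DataFrame(
        {name: (rng.random(n) < config.predictor_freqs[name]).astype(int) for name in names}
    )
    soldier = (rng.random(n) < config.group_freq).astype(int)

    coefs = dict(config.coefficients)
    freqs = dict(config.predictor_freqs)
    if config.group_coef != 0.0:
        coefs["soldier"] = config.group_coef
        freqs["soldier"] = config.group_freq
    alpha = solve_intercept_for_prevalence(coefs, freqs, config.target_prevalence)

    lp = alpha + sum(
        config.coefficients.get(name, 0.0) * X[name].to_numpy() for name in names
    )
    lp = lp + config.group_coef * soldier
    y = (rng.random(n) < expit(lp)).astype(int)

    dsrs_w3 = _draw_dsrs(rng, y.astype(bool), config.dsrs_noise).astype(float)
    # Earlier waves: sub-threshold by default; an optional fraction carries a
    # prior-depression record at wave 1 or 2 (exercises the eligibility filter).
    dsrs_w1 = (13 - _truncated_geometric(rng, n, 13, 2.0 * config.dsrs_noise)).astype(float)
    dsrs_w2 = (13 - _truncated_geometric(rng, n, 13, 2.0 * config.dsrs_noise)).astype(float)
    if config.prior_depression_rate > 0:
        prior = rng.random(n) < config.prior_depression_rate
        which_wave = rng.random(n) < 0.5
        elevated = 14 + _truncated_geometric(rng, n, 22, config.dsrs_noise)
        dsrs_w1 = np.where(prior & which_wave, elevated, dsrs_w1)
        dsrs_w2 = np.where(prior & ~which_wave, elevated, dsrs_w2)

    lo, hi = config.wave_age_range
    age_w1 = rng.integers(lo, hi + 1, size=n)
    age_w2 = age_w1 + 1
    age_w3 = age_w2 + 4

    # Monotone attrition: anyone missed at wave 2 stays missing at wave 3.
    u = rng.random(n)
    miss3 = u < config.dropout_w3
    miss2 = u < config.dropout_w2
    dsrs_w2 = np.where(miss2, np.nan, dsrs_w2)
    dsrs_w3 = np.where(miss3, np.nan, dsrs_w3)

    table = pd.DataFrame({"subject_id": [f"S{i:06d}" for i in range(n)]})
    for name in names:
        table[name] = X[name]
    table["age_w1"] = age_w1
    table["age_w2"] = age_w2
    table["age_w3"] = age_w3
    table["dsrs_w1"] = dsrs_w1
    table["dsrs_w2"] = dsrs_w2
    table["dsrs_w3"] = dsrs_w3
    table["soldier"] = soldier
    table["y"] = np.where(miss3, np.nan, y.astype(float))
    return table


def generate_miscalibrated_pair(
    dev_config: GeneratorConfig, val_config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A development/validation cohort pair sharing one predictor schema.

    The two configs may differ in prevalence (case-mix shift, the study's
    central miscalibration mechanism) and in coefficients (predictor-strength
    shift); they must agree on predictor names.
    """
    if list(dev_config.predictor_freqs) != list(val_config.predictor_freqs):
        raise SchemaError(
            "development and validation configs must share the predictor schema: "
            f"{list(dev_config.predictor_freqs)} vs {list(val_config.predictor_freqs)}"
        )
    return generate_cohort(dev_config), generate_cohort(val_config)


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """CSV with a JSON sidecar recording the schema version and columns."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = {"schema_version": SCHEMA_VERSION, "columns": list(table.columns)}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=2))


def read_cohort(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "subject_id" not in table.columns:
        raise SchemaError(f"{path}: not a cohort table (no subject_id column)")
    return table
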