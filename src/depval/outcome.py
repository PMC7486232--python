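"""DSRS outcome scoring and the wave-based eligibility filter.

The Depression Self Rating Scale has 18 items scored 0/1/2 (total 0-36); a
total of 14 or above indicates clinically relevant depression in the
validated Nepali version. The analysis sample keeps subjects who were under
the adult age at waves 1-2, at or above it at wave 3, assessed at every
wave, and free of depression at waves 1-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MissingDataError, SchemaError, ValidationError

N_ITEMS = 18
MAX_TOTAL = 2 * N_ITEMS
DEFAULT_CUTOFF = 14
DEFAULT_ADULT_AGE = 18

#: Exclusion reasons, in audit-column order.
REASONS = (
    "lost_to_follow_up",
    "over_age_w12",
    "under_age_w3",
    "prior_depression",
    "missing_outcome",
)


@dataclass(frozen=True)
class EligibilityDecision:
    subject_id: str
    included: bool
    exclusion_reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        assert self.included == (len(self.exclusion_reasons) == 0)


def score_dsrs(item_responses: Sequence[int]) -> int:
    """Sum 18 item responses rated 0 ('Never'), 1 ('Sometimes'), 2 ('Mostly')."""
    items = list(item_responses)
    if len(items) != N_ITEMS:
        raise ValidationError(f"expected {N_ITEMS} item responses, got {len(items)}")
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise MissingDataError(f"item {i + 1} is missing; no imputation is performed")
        if v not in (0, 1, 2):
            raise ValidationError(f"item {i + 1} outside {{0, 1, 2}}: {v!r}")
    return int(sum(items))


def classify_depression(dsrs_total: int, cutoff: int = DEFAULT_CUTOFF) -> bool:
    """True iff the total meets or exceeds the clinical cutoff."""
    if not 0 <= dsrs_total <= MAX_TOTAL:
        raise ValidationError(f"DSRS total outside [0, {MAX_TOTAL}]: {dsrs_total}")
    return dsrs_total >= cutoff


def select_analysis_sample(
    cohort: pd.DataFrame,
    cutoff: int = DEFAULT_CUTOFF,
    adult_age: int = DEFAULT_ADULT_AGE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the wave-based inclusion filter; return (included, audit).

    The audit table has one row per input subject with one boolean column per
    exclusion reason plus ``included``; a subject may carry several reasons.
    Age exactly ``adult_age`` at wave 1 or 2 excludes (the boundary reading
    of "younger than 18"); age ``adult_age`` or older at wave 3 includes.
    Any missed assessment excludes — there is no imputation.
    """
    for col in ("age_w1", "age_w2", "age_w3", "dsrs_w1", "dsrs_w2", "dsrs_w3"):
        if col not in cohort.columns:
            raise SchemaError(f"cohort lacks required column {col!r}")

    age1 = cohort["age_w1"].to_numpy(dtype=float)
    age2 = cohort["age_w2"].to_numpy(dtype=float)
    age3 = cohort["age_w3"].to_numpy(dtype=float)
    d1 = cohort["dsrs_w1"].to_numpy(dtype=float)
    d2 = cohort["dsrs_w2"].to_numpy(dtype=float)
    d3 = cohort["dsrs_w3"].to_numpy(dtype=float)

    lost = np.isnan(age2) | np.isnan(d2) | np.isnan(age3) | np.isnan(d3)
    over_age = (age1 >= adult_age) | (age2 >= adult_age)
    under_age = age3 < adult_age
    prior = (~np.isnan(d1) & (d1 >= cutoff)) | (~np.isnan(d2) & (d2 >= cutoff))
    missing_outcome = np.isnan(d1) | np.isnan(d3)

    audit = pd.DataFrame(
        {
            "subject_id": cohort.get("subject_id", pd.RangeIndex(len(cohort)).astype(str)),
            "lost_to_follow_up": lost,
            "over_age_w12": over_age,
            "under_age_w3": under_age,
            "prior_depression": prior,
            "missing_outcome": missing_outcome,
        }
    )
    audit["included"] = ~audit[list(REASONS)].any(axis=1)

    included = cohort.loc[audit["included"].to_numpy()].reset_index(drop=True)
    return included, audit


def audit_decisions(audit: pd.DataFrame) -> list[EligibilityDecision]:
    """Convert the audit table to per-subject decision records."""
    out = []
    for _, row in audit.iterrows():
        reasons = tuple(r for r in REASONS if bool(row[r]))
        out.append(
            EligibilityDecision(
                subject_id=str(row["subject_id"]),
                included=bool(row["included"]),
                exclusion_reasons=reasons,
            )
        )
    return out


def attach_outcome(
    cohort: pd.DataFrame, cutoff: int = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """(Re)derive the binary outcome from wave-3 DSRS totals via the cutoff."""
    d3 = cohort["dsrs_w3"].to_numpy(dtype=float)
    if np.isnan(d3).any():
        raise MissingDataError("wave-3 DSRS totals contain missing values")
    out = cohort.copy()
    out["y"] = (d3 >= cutoff).astype(int)
    return out
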