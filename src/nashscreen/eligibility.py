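"""Eligibility screen and auditable exclusion tally.

The analysis cohort retains adults aged 20–74 with a gradable hepatic
ultrasound and no competing cause of steatosis: chronic hepatitis B
(HBsAg **and** anti-HBc positive), chronic hepatitis C (antibody **and**
RNA positive), transferrin saturation above 50% (iron-overload
predisposition), excessive alcohol use (average of more than two
drinks/day for men, more than one for women), or prescription medication
known to cause hepatic steatosis.  Subjects missing any required analysis
variable are dropped last (listwise deletion).

Each subject is excluded at most once, at the first matching reason in
:data:`EXCLUSION_ORDER`, so the tally partitions the input and can be
rendered as a study flow diagram.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "EXCLUSION_ORDER",
    "ExclusionTally",
    "daily_alcohol_average",
    "is_excessive_alcohol",
    "chronic_hep_b",
    "chronic_hep_c",
    "apply_exclusions",
]

logger = logging.getLogger(__name__)

EXCLUSION_ORDER: tuple[str, ...] = (
    "age_out_of_range",
    "ultrasound_missing_or_ungradable",
    "chronic_hep_b",
    "chronic_hep_c",
    "transferrin_gt_50",
    "excessive_alcohol",
    "steatogenic_medication",
    "listwise_missing",
)

AGE_MIN, AGE_MAX = 20, 74  # inclusive bounds

#: Default variables required complete for the analysis (listwise deletion).
DEFAULT_REQUIRED_FIELDS: tuple[str, ...] = (
    "age", "sex", "race_ethnicity", "ultrasound_grade",
    "fasting_glucose", "fasting_insulin", "alt", "ast",
    "systolic_bp", "diastolic_bp", "waist_cm", "hip_cm",
    "triglyceride", "hdl", "weight", "stratum", "psu",
)


@dataclass
class ExclusionTally:
    """Ordered per-reason exclusion counts for a flow report."""

    n_input: int
    n_retained: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for reason in EXCLUSION_ORDER:
            self.counts.setdefault(reason, 0)
        if self.n_input != self.n_retained + sum(self.counts.values()):
            raise ValueError("tally does not partition the input cohort")

    def to_json(self) -> str:
        return json.dumps(
            {"n_input": self.n_input, "n_retained": self.n_retained,
             "excluded": {r: self.counts[r] for r in EXCLUSION_ORDER}},
            indent=2,
        )

    def flow_report(self) -> str:
        """Plain-text flow-diagram summary."""
        lines = [f"Input subjects: {self.n_input}"]
        remaining = self.n_input
        for reason in EXCLUSION_ORDER:
            k = self.counts[reason]
            if k:
                remaining -= k
                lines.append(f"  - excluded {k:>6d}  {reason:<34s} -> {remaining} remain")
        lines.append(f"Analysis cohort: {self.n_retained}")
        return "\n".join(lines)


def daily_alcohol_average(days_per_year: float, drinks_per_day: float) -> float:
    """Average daily drinks: (drinking days/year × drinks per drinking day) / 365."""
    if not 0 <= days_per_year <= 365:
        raise ValueError(f"days_per_year must be in [0, 365], got {days_per_year}")
    if drinks_per_day < 0:
        raise ValueError("drinks_per_day must be non-negative")
    return days_per_year * drinks_per_day / 365.0


def is_excessive_alcohol(avg_drinks_per_day: float, sex: str) -> bool:
    """More than 2 drinks/day (men) or more than 1 (women); boundaries are not excessive."""
    if avg_drinks_per_day < 0:
        raise ValueError("average must be non-negative")
    limit = 2.0 if sex == "male" else 1.0
    return avg_drinks_per_day > limit


def _both(a, b) -> bool:
    if pd.isna(a) or pd.isna(b):
        return False
    return bool(a) and bool(b)


def chronic_hep_b(record) -> bool:
    """HBsAg and anti-HBc both positive; missing serology counts as negative."""
    a, b = record["hbsag_positive"], record["anti_hbc_positive"]
    if pd.isna(a) or pd.isna(b):
        logger.warning("missing hepatitis B serology treated as negative")
    return _both(a, b)


def chronic_hep_c(record) -> bool:
    """HCV antibody and RNA both positive; missing serology counts as negative."""
    a, b = record["hcv_ab_positive"], record["hcv_rna_positive"]
    if pd.isna(a) or pd.isna(b):
        logger.warning("missing hepatitis C serology treated as negative")
    return _both(a, b)


def apply_exclusions(
    cohort: pd.DataFrame,
    required_fields: tuple[str, ...] | list[str] = DEFAULT_REQUIRED_FIELDS,
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Apply the eligibility screen and return (analysis cohort, tally).

    Exclusion reasons are evaluated in :data:`EXCLUSION_ORDER`; each
    subject is tallied once under its first matching reason.  Retained
    rows keep the input order.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")

    def fill_false(col):
        return cohort[col].fillna(False).astype(bool)

    age = pd.to_numeric(cohort["age"], errors="coerce")
    grade = cohort["ultrasound_grade"]
    avg = (
        pd.to_numeric(cohort["alcohol_days_per_year"], errors="coerce").fillna(0)
        * pd.to_numeric(cohort["alcohol_drinks_per_day"], errors="coerce").fillna(0)
        / 365.0
    )
    limit = pd.Series(2.0, index=cohort.index).where(cohort["sex"] == "male", 1.0)
    tsat = pd.to_numeric(cohort["transferrin_saturation"], errors="coerce")

    reasons = {
        "age_out_of_range": age.isna() | (age < AGE_MIN) | (age > AGE_MAX),
        "ultrasound_missing_or_ungradable": grade.isna()
        | grade.isin(["ungradable", "missing"]),
        "chronic_hep_b": fill_false("hbsag_positive") & fill_false("anti_hbc_positive"),
        "chronic_hep_c": fill_false("hcv_ab_positive") & fill_false("hcv_rna_positive"),
        "transferrin_gt_50": tsat.fillna(0) > 50.0,
        "excessive_alcohol": avg > limit,
        "steatogenic_medication": fill_false("steatogenic_medication"),
        "listwise_missing": cohort.reindex(columns=list(required_fields))
        .isna()
        .any(axis=1),
    }

    excluded = pd.Series(False, index=cohort.index)
    counts: dict[str, int] = {}
    for reason in EXCLUSION_ORDER:
        hit = reasons[reason] & ~excluded
        counts[reason] = int(hit.sum())
        excluded |= hit

    retained = cohort.loc[~excluded]
    tally = ExclusionTally(
        n_input=len(cohort), n_retained=len(retained), counts=counts
    )
    return retained, tally
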