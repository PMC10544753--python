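"""Subject-level cohort data model and CSV round-trip.

A cohort is carried as a :class:`pandas.DataFrame` whose columns follow
:data:`COHORT_SCHEMA` — one row per survey participant with demographics,
anthropometrics, fasting laboratory values, viral-hepatitis serology,
ultrasound steatosis grade, and the complex-survey design variables
(stratum, primary sampling unit, sampling weight).  Optional fields may be
missing (``NaN`` / ``NA``); missingness is preserved through the CSV
round-trip and is never silently coerced to zero.  Listwise deletion is a
pipeline decision, not a reader decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COHORT_SCHEMA",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "SubjectRecord",
    "CohortFormatError",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "insulin_pmol_to_uU",
    "glucose_mmol_to_mgdl",
]

# Categorical domains.  Ultrasound grades include the two non-gradable
# states so the eligibility stage can tally them explicitly.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "race_ethnicity": ("white", "black", "mexican_american", "other"),
    "education": ("lt_hs", "hs", "gt_hs"),
    "urbanization": ("urban", "rural"),
    "birthplace": ("us", "mexico", "other"),
    "years_in_us": ("entire_life", "lt5", "5to10", "gt10"),
    "smoking": ("never", "former", "current"),
    "activity_level": ("inactive", "below_guidelines", "meets_guidelines"),
    "ultrasound_grade": ("none", "mild", "moderate", "severe", "ungradable", "missing"),
}

BOOLEAN_COLUMNS: tuple[str, ...] = (
    "ever_12_drinks_lifetime",
    "twelve_drinks_past_year",
    "htn_diagnosis",
    "htn_medication",
    "dm_diagnosis",
    "hbsag_positive",
    "anti_hbc_positive",
    "hcv_ab_positive",
    "hcv_rna_positive",
    "steatogenic_medication",
)

NUMERIC_COLUMNS: tuple[str, ...] = (
    "age",
    "poverty_ratio",
    "alcohol_days_per_year",
    "alcohol_drinks_per_day",
    "waist_cm",
    "hip_cm",
    "systolic_bp",
    "diastolic_bp",
    "fasting_glucose",
    "two_hr_glucose",
    "fasting_insulin",
    "c_peptide",
    "alt",
    "ast",
    "total_cholesterol",
    "hdl",
    "triglyceride",
    "crp",
    "hba1c",
    "transferrin_saturation",
    "hei_score",
    "weight",
)

#: Stable column order for the cohort CSV.
COHORT_SCHEMA: tuple[str, ...] = (
    "subject_id",
    "age",
    "sex",
    "race_ethnicity",
    "education",
    "poverty_ratio",
    "urbanization",
    "birthplace",
    "years_in_us",
    "smoking",
    "alcohol_days_per_year",
    "alcohol_drinks_per_day",
    "ever_12_drinks_lifetime",
    "twelve_drinks_past_year",
    "activity_level",
    "waist_cm",
    "hip_cm",
    "systolic_bp",
    "diastolic_bp",
    "htn_diagnosis",
    "htn_medication",
    "dm_diagnosis",
    "fasting_glucose",
    "two_hr_glucose",
    "fasting_insulin",
    "c_peptide",
    "alt",
    "ast",
    "total_cholesterol",
    "hdl",
    "triglyceride",
    "crp",
    "hba1c",
    "transferrin_saturation",
    "hbsag_positive",
    "anti_hbc_positive",
    "hcv_ab_positive",
    "hcv_rna_positive",
    "steatogenic_medication",
    "hei_score",
    "ultrasound_grade",
    "stratum",
    "psu",
    "weight",
)

#: Columns a cohort file must resolve; everything else may be absent/blank.
REQUIRED_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "age",
    "sex",
    "race_ethnicity",
    "ultrasound_grade",
    "stratum",
    "psu",
    "weight",
)

OPTIONAL_COLUMNS: tuple[str, ...] = tuple(
    c for c in COHORT_SCHEMA if c not in REQUIRED_COLUMNS
)


class CohortFormatError(ValueError):
    """A cohort file is structurally unusable (e.g. a required column is missing)."""


class CohortParseError(ValueError):
    """A cohort row holds a value that cannot be parsed (reported with its row index)."""


@dataclass(frozen=True)
class SubjectRecord:
    """One participant, as a plain record.

    A convenience view over a single cohort row; the DataFrame remains the
    working container.  Missing optional values are ``None``.
    """

    subject_id: str
    age: float
    sex: str
    race_ethnicity: str
    ultrasound_grade: str
    stratum: str
    psu: str
    weight: float
    extras: Mapping[str, object]

    @classmethod
    def from_row(cls, row: pd.Series) -> "SubjectRecord":
        extras = {
            k: (None if pd.isna(v) else v)
            for k, v in row.items()
            if k not in REQUIRED_COLUMNS
        }
        return cls(
            subject_id=str(row["subject_id"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            race_ethnicity=str(row["race_ethnicity"]),
            ultrasound_grade=str(row["ultrasound_grade"]),
            stratum=str(row["stratum"]),
            psu=str(row["psu"]),
            weight=float(row["weight"]),
            extras=extras,
        )


def insulin_pmol_to_uU(value: float | np.ndarray) -> float | np.ndarray:
    """Convert insulin from pmol/L to µU/mL (divide by 6.0).

    The fat-score formula takes insulin in µU/mL (= mU/L), the units of its
    original derivation cohort; modern assays often report pmol/L.
    """
    return np.asarray(value, dtype=float) / 6.0 if np.ndim(value) else float(value) / 6.0


def glucose_mmol_to_mgdl(value: float | np.ndarray) -> float | np.ndarray:
    """Convert glucose from mmol/L to mg/dL (multiply by 18.0)."""
    return np.asarray(value, dtype=float) * 18.0 if np.ndim(value) else float(value) * 18.0


def validate_cohort(df: pd.DataFrame) -> None:
    """Raise if a cohort frame violates the record invariants.

    Checks: required columns present, weights positive, categorical levels
    legal, non-negative labs/anthropometrics, hip present and positive
    wherever waist is present.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"required column(s) missing: {', '.join(missing)}")
    if len(df) and (df["weight"] <= 0).any():
        bad = df.index[df["weight"] <= 0][0]
        raise CohortParseError(f"non-positive sampling weight at row {bad}")
    for col, levels in CATEGORICAL_LEVELS.items():
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = ~vals.isin(levels)
        if bad.any():
            raise CohortParseError(
                f"illegal value {vals[bad].iloc[0]!r} in column {col!r}"
            )
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() < 0).any() and col not in ("poverty_ratio",):
            raise CohortParseError(f"negative value in column {col!r}")
    if "waist_cm" in df.columns and "hip_cm" in df.columns:
        has_waist = df["waist_cm"].notna()
        if len(df) and (df.loc[has_waist, "hip_cm"].isna() | (df.loc[has_waist, "hip_cm"] <= 0)).any():
            raise CohortParseError("hip_cm must be present and positive wherever waist_cm is present")


def read_cohort(
    path,
    dialect: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a cohort CSV into the canonical schema.

    Parameters
    ----------
    path
        CSV file with a header row (RFC 4180, UTF-8).
    dialect
        Optional map from canonical column name to the name used in the
        file, so external extracts can be adapted without code change.

    Returns
    -------
    DataFrame in :data:`COHORT_SCHEMA` order, row order preserved, missing
    optional fields as ``NaN``/``NA``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect:
        rename = {src: canon for canon, src in dialect.items() if src in raw.columns}
        raw = raw.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortFormatError(f"required column(s) missing: {', '.join(missing)}")

    out = pd.DataFrame(index=raw.index)
    for col in COHORT_SCHEMA:
        if col not in raw.columns:
            out[col] = pd.NA
            continue
        ser = raw[col].replace("", pd.NA)
        if col in NUMERIC_COLUMNS or col == "age":
            try:
                out[col] = pd.to_numeric(ser)
            except (ValueError, TypeError) as exc:
                bad = ser[pd.to_numeric(ser, errors="coerce").isna() & ser.notna()]
                row = int(bad.index[0]) if len(bad) else -1
                raise CohortParseError(
                    f"non-numeric value for {col!r} at row {row}: {exc}"
                ) from exc
        elif col in BOOLEAN_COLUMNS:
            mapped = ser.map({"True": True, "False": False, "true": True,
                              "false": False, "1": True, "0": False})
            bad = ser.notna() & mapped.isna()
            if bad.any():
                raise CohortParseError(
                    f"non-boolean value for {col!r} at row {int(bad.idxmax())}"
                )
            out[col] = mapped.astype("boolean")
        else:
            out[col] = ser
    validate_cohort(out)
    return out


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort frame as CSV with the stable schema header.

    Missing values become empty cells (never ``0``); round-trips through
    :func:`read_cohort` field-for-field on non-missing values.
    """
    if len(df) == 0:
        raise ValueError("refusing to write an empty cohort")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"required column(s) missing: {', '.join(missing)}")
    out = df.reindex(columns=COHORT_SCHEMA)
    out.to_csv(path, index=False, na_rep="")


def records(df: pd.DataFrame) -> Sequence[SubjectRecord]:
    """Materialize a cohort frame as :class:`SubjectRecord` objects."""
    return [SubjectRecord.from_row(row) for _, row in df.iterrows()]
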