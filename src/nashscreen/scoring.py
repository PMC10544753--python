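"""Clinical NASH scores, derived features, and three-class labelling.

Three validated non-invasive scores identify probable NASH among subjects
whose ultrasound shows moderate-to-severe steatosis (the NAFLD set):

* **HAIR** — one point each for HOMA-IR > 5, ALT > 40 U/L, and
  hypertension (BP ≥ 140/90, a prior diagnosis, or antihypertensive
  medication); positive at ≥ 2 points.
* **Gholam** — ``2.627 · ln(AST) + 2.13`` if type-2 diabetic (prior
  diagnosis or fasting glucose > 126 mg/dL); positive at ≥ 8.22.
* **NASH liver fat score (LFS)** —
  ``1.18·MS + 0.45·DM + 0.15·insulin + 0.04·AST − 0.94·AST/ALT − 2.89``
  with metabolic syndrome coded 0/1 and diabetes coded 0/2 (diagnosis,
  fasting glucose ≥ 126, or 2-h glucose ≥ 200 mg/dL); insulin in µU/mL;
  positive at ≥ 2.122.

Each method yields a three-class label: *nash* (NAFLD and score
positive), *simple_nafld* (NAFLD, score negative), *normal_mild*
otherwise.  The scores only partition the NAFLD set — a positive score
without moderate/severe steatosis never labels NASH.  All cutoffs and
coefficients live in :class:`ScoreConfig` (defaults = the published
values) so the threshold table has a single source of truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScoreConfig",
    "compute_homa_ir",
    "hair_score",
    "gholam_score",
    "metabolic_syndrome",
    "nash_lfs",
    "derive_features",
    "categorize_covariates",
    "classify_cohort",
    "classify_subject",
    "METHODS",
]

METHODS = ("hair", "gholam", "lfs")
SCHEMES = ("hair", "gholam", "lfs", "all3", "any1")


@dataclass
class ScoreConfig:
    """Cutoffs and coefficients for the three scores and covariate categories."""

    # HAIR
    hair_homa_cut: float = 5.0
    hair_alt_cut: float = 40.0
    hair_sbp_cut: float = 140.0
    hair_dbp_cut: float = 90.0
    hair_positive_points: int = 2
    # Gholam
    gholam_ast_coef: float = 2.627
    gholam_dm_term: float = 2.13
    gholam_cut: float = 8.22
    gholam_glucose_cut: float = 126.0      # strict >
    # NASH liver fat score
    lfs_ms_coef: float = 1.18
    lfs_dm_coef: float = 0.45
    lfs_insulin_coef: float = 0.15
    lfs_ast_coef: float = 0.04
    lfs_ratio_coef: float = 0.94
    lfs_intercept: float = -2.89
    lfs_cut: float = 2.122
    lfs_cut_inclusive: bool = True
    lfs_glucose_cut: float = 126.0         # inclusive ≥
    lfs_2hr_glucose_cut: float = 200.0
    # Metabolic syndrome
    ms_waist_male: float = 94.0            # strict >
    ms_waist_female: float = 80.0
    ms_tg_cut: float = 150.0               # inclusive ≥
    ms_hdl_male: float = 40.0              # strict <
    ms_hdl_female: float = 50.0
    ms_sbp_cut: float = 130.0
    ms_dbp_cut: float = 85.0
    ms_bp_rule: str = "and"                # "and": SBP≥130 AND DBP≥85; "or" available
    ms_glucose_cut: float = 100.0
    ms_min_criteria: int = 3
    # Covariate category boundaries
    whr_cut_male: float = 0.90             # at-risk iff ratio ≥ cut
    whr_cut_female: float = 0.85
    cpep_low: float = 0.26
    cpep_high: float = 1.03
    chol_elevated: float = 200.0           # normal ≤ 200
    chol_high: float = 240.0               # high ≥ 240
    crp_mild: float = 0.3                  # normal < 0.3; mild [0.3, 1]
    crp_high: float = 1.0                  # significant > 1
    hei_poor: float = 50.0                 # poor < 50; needs improvement [50, 80]
    hei_good: float = 80.0                 # good > 80
    version: str = "published-defaults-1"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScoreConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


DEFAULT_CONFIG = ScoreConfig()


# --------------------------------------------------------------------------
# scalar score primitives
# --------------------------------------------------------------------------

def compute_homa_ir(fasting_glucose: float, fasting_insulin: float) -> float:
    """HOMA-IR = glucose [mg/dL] × insulin [µU/mL] / 405 (Matthews)."""
    if fasting_glucose <= 0 or fasting_insulin <= 0:
        raise ValueError("fasting glucose and insulin must be positive")
    return fasting_glucose * fasting_insulin / 405.0


def hair_score(
    homa_ir: float,
    alt: float,
    sbp: float,
    dbp: float,
    htn_diagnosis: bool,
    htn_medication: bool,
    config: ScoreConfig = DEFAULT_CONFIG,
) -> tuple[int, bool]:
    """HAIR points (0–3) and positivity (≥2 points)."""
    hypertensive = (
        sbp >= config.hair_sbp_cut
        or dbp >= config.hair_dbp_cut
        or htn_diagnosis
        or htn_medication
    )
    points = int(homa_ir > config.hair_homa_cut) + int(alt > config.hair_alt_cut) + int(hypertensive)
    return points, points >= config.hair_positive_points


def gholam_score(
    ast: float, diabetes: bool, config: ScoreConfig = DEFAULT_CONFIG
) -> tuple[float, bool]:
    """Gholam value 2.627·ln(AST) (+2.13 if diabetic) and positivity (≥8.22)."""
    if ast <= 0:
        raise ValueError("AST must be positive")
    value = config.gholam_ast_coef * math.log(ast) + config.gholam_dm_term * bool(diabetes)
    return value, value >= config.gholam_cut


def metabolic_syndrome(
    waist_cm: float,
    sex: str,
    triglyceride: float,
    hdl: float,
    sbp: float,
    dbp: float,
    htn_treated: bool,
    fasting_glucose: float,
    glycemia_treated: bool,
    config: ScoreConfig = DEFAULT_CONFIG,
) -> bool:
    """At least 3 of 5: waist, triglycerides, HDL, blood pressure, glucose."""
    waist_cut = config.ms_waist_male if sex == "male" else config.ms_waist_female
    hdl_cut = config.ms_hdl_male if sex == "male" else config.ms_hdl_female
    if config.ms_bp_rule == "and":
        bp = sbp >= config.ms_sbp_cut and dbp >= config.ms_dbp_cut
    else:
        bp = sbp >= config.ms_sbp_cut or dbp >= config.ms_dbp_cut
    criteria = (
        waist_cm > waist_cut,
        triglyceride >= config.ms_tg_cut,
        hdl < hdl_cut,
        bp or htn_treated,
        fasting_glucose >= config.ms_glucose_cut or glycemia_treated,
    )
    return sum(criteria) >= config.ms_min_criteria


def nash_lfs(
    metabolic_syndrome: bool,
    diabetes: bool,
    fasting_insulin: float,
    ast: float,
    alt: float,
    config: ScoreConfig = DEFAULT_CONFIG,
) -> tuple[float, bool]:
    """NASH liver fat score value and positivity.

    Metabolic syndrome is coded 0/1 and diabetes 0/2 in the linear
    predictor; insulin is in µU/mL.
    """
    if alt <= 0:
        raise ValueError("ALT must be positive (AST/ALT ratio undefined)")
    if ast < 0 or fasting_insulin < 0:
        raise ValueError("AST and insulin must be non-negative")
    value = (
        config.lfs_ms_coef * bool(metabolic_syndrome)
        + config.lfs_dm_coef * (2 * bool(diabetes))
        + config.lfs_insulin_coef * fasting_insulin
        + config.lfs_ast_coef * ast
        - config.lfs_ratio_coef * (ast / alt)
        + config.lfs_intercept
    )
    positive = value >= config.lfs_cut if config.lfs_cut_inclusive else value > config.lfs_cut
    return value, positive


# --------------------------------------------------------------------------
# vectorized feature derivation
# --------------------------------------------------------------------------

def _cut3(values: pd.Series, low_edge: float, high_edge: float,
          labels: tuple[str, str, str], low_strict: bool, high_strict: bool) -> pd.Series:
    """Three-way categorization with explicit boundary conventions."""
    v = pd.to_numeric(values, errors="coerce")
    below = v < low_edge if low_strict else v <= low_edge
    above = v > high_edge if high_strict else v >= high_edge
    out = pd.Series(labels[1], index=values.index, dtype=object)
    out[below] = labels[0]
    out[above] = labels[2]
    out[v.isna()] = pd.NA
    return out


def categorize_covariates(
    cohort: pd.DataFrame, config: ScoreConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Categorical covariates for the statistical stage.

    Boundary conventions resolve the overlapping printed category edges:
    cholesterol normal ≤ 200 / elevated (200, 240) / high ≥ 240;
    CRP normal < 0.3 / mild [0.3, 1] / significant > 1;
    C-peptide low < 0.26 / normal [0.26, 1.03] / high > 1.03;
    HEI poor < 50 / needs improvement [50, 80] / good > 80;
    waist-to-hip at risk at ≥ 0.85 (women) / ≥ 0.90 (men);
    age 20–34, 35–49, 50–64, 65+.
    """
    out = pd.DataFrame(index=cohort.index)
    age = pd.to_numeric(cohort["age"], errors="coerce")
    out["age_group"] = pd.cut(
        age, bins=[-np.inf, 34, 49, 64, np.inf],
        labels=["20_34", "35_49", "50_64", "65_plus"],
    ).astype(object)

    waist = pd.to_numeric(cohort["waist_cm"], errors="coerce")
    hip = pd.to_numeric(cohort["hip_cm"], errors="coerce")
    whr = waist / hip
    out["whr"] = whr
    cut = pd.Series(config.whr_cut_male, index=cohort.index).where(
        cohort["sex"] == "male", config.whr_cut_female
    )
    out["whr_risk"] = np.where(whr.isna(), pd.NA,
                               np.where(whr >= cut, "at_risk", "healthy"))

    out["c_peptide_cat"] = _cut3(
        cohort["c_peptide"], config.cpep_low, config.cpep_high,
        ("low", "normal", "high"), low_strict=True, high_strict=True,
    )
    out["chol_cat"] = _cut3(
        cohort["total_cholesterol"], config.chol_elevated, config.chol_high,
        ("normal", "elevated", "high"), low_strict=False, high_strict=False,
    )
    out["crp_cat"] = _cut3(
        cohort["crp"], config.crp_mild, config.crp_high,
        ("normal", "mild", "significant"), low_strict=True, high_strict=True,
    )
    out["hei_cat"] = _cut3(
        cohort["hei_score"], config.hei_poor, config.hei_good,
        ("poor", "needs_improvement", "good"), low_strict=True, high_strict=True,
    )

    ever = cohort["ever_12_drinks_lifetime"]
    past = cohort["twelve_drinks_past_year"]
    status = np.where(
        ever.isna(), pd.NA,
        np.where(~ever.fillna(False).astype(bool), "never",
                 np.where(past.fillna(False).astype(bool), "current", "former")),
    )
    out["alcohol_status"] = status
    return out


def derive_features(
    cohort: pd.DataFrame, config: ScoreConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-subject derived quantities used by the scores and the regression.

    Returns HOMA-IR, daily alcohol average, waist-to-hip ratio, metabolic
    syndrome, the two diabetes variants (the Gholam definition uses strict
    fasting glucose > 126; the fat-score definition uses ≥ 126 or 2-h
    glucose ≥ 200), the hypertension flag, and the categorized covariates.
    """
    num = lambda c: pd.to_numeric(cohort[c], errors="coerce")
    boolean = lambda c: cohort[c].fillna(False).astype(bool)

    out = categorize_covariates(cohort, config)
    out["homa_ir"] = num("fasting_glucose") * num("fasting_insulin") / 405.0
    out["daily_alcohol"] = (
        num("alcohol_days_per_year").fillna(0) * num("alcohol_drinks_per_day").fillna(0) / 365.0
    )

    sbp, dbp = num("systolic_bp"), num("diastolic_bp")
    out["hypertension"] = (
        (sbp >= config.hair_sbp_cut) | (dbp >= config.hair_dbp_cut)
        | boolean("htn_diagnosis") | boolean("htn_medication")
    )

    glucose = num("fasting_glucose")
    out["diabetes_gholam"] = boolean("dm_diagnosis") | (glucose > config.gholam_glucose_cut)
    out["diabetes_lfs"] = (
        boolean("dm_diagnosis")
        | (glucose >= config.lfs_glucose_cut)
        | (num("two_hr_glucose") >= config.lfs_2hr_glucose_cut)
    )

    male = cohort["sex"] == "male"
    waist_cut = np.where(male, config.ms_waist_male, config.ms_waist_female)
    hdl_cut = np.where(male, config.ms_hdl_male, config.ms_hdl_female)
    if config.ms_bp_rule == "and":
        bp = (sbp >= config.ms_sbp_cut) & (dbp >= config.ms_dbp_cut)
    else:
        bp = (sbp >= config.ms_sbp_cut) | (dbp >= config.ms_dbp_cut)
    htn_treated = boolean("htn_medication")
    n_criteria = (
        (num("waist_cm") > waist_cut).astype(int)
        + (num("triglyceride") >= config.ms_tg_cut).astype(int)
        + (num("hdl") < hdl_cut).astype(int)
        + (bp | htn_treated).astype(int)
        + ((glucose >= config.ms_glucose_cut) | boolean("dm_diagnosis")).astype(int)
    )
    out["metabolic_syndrome"] = n_criteria >= config.ms_min_criteria
    return out


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def classify_cohort(
    cohort: pd.DataFrame,
    features: pd.DataFrame | None = None,
    config: ScoreConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Score panel for every subject: values, flags, and three-class labels.

    Raises if any subject has an ungradable/missing ultrasound — those
    belong to the exclusion stage, not here.
    """
    if features is None:
        features = derive_features(cohort, config)
    grade = cohort["ultrasound_grade"]
    bad = grade.isna() | grade.isin(["ungradable", "missing"])
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} subject(s) with ungradable/missing ultrasound; "
            "apply exclusions first"
        )
    nafld = grade.isin(["moderate", "severe"]).to_numpy()

    num = lambda c: pd.to_numeric(cohort[c], errors="coerce").to_numpy(dtype=float)
    panel = pd.DataFrame(index=cohort.index)

    homa = features["homa_ir"].to_numpy(dtype=float)
    alt = num("alt")
    hair_pts = (
        (homa > config.hair_homa_cut).astype(int)
        + (alt > config.hair_alt_cut).astype(int)
        + features["hypertension"].to_numpy(dtype=bool).astype(int)
    )
    panel["hair_points"] = hair_pts
    hair_pos = hair_pts >= config.hair_positive_points

    ast = num("ast")
    gholam_val = config.gholam_ast_coef * np.log(ast) + config.gholam_dm_term * features[
        "diabetes_gholam"
    ].to_numpy(dtype=bool)
    panel["gholam_value"] = gholam_val
    gholam_pos = gholam_val >= config.gholam_cut

    lfs_val = (
        config.lfs_ms_coef * features["metabolic_syndrome"].to_numpy(dtype=bool)
        + config.lfs_dm_coef * 2 * features["diabetes_lfs"].to_numpy(dtype=bool)
        + config.lfs_insulin_coef * num("fasting_insulin")
        + config.lfs_ast_coef * ast
        - config.lfs_ratio_coef * (ast / alt)
        + config.lfs_intercept
    )
    panel["lfs_value"] = lfs_val
    lfs_pos = lfs_val >= config.lfs_cut if config.lfs_cut_inclusive else lfs_val > config.lfs_cut

    panel["hair_nash"] = nafld & hair_pos
    panel["gholam_nash"] = nafld & gholam_pos
    panel["lfs_nash"] = nafld & lfs_pos
    panel["all3_nash"] = panel["hair_nash"] & panel["gholam_nash"] & panel["lfs_nash"]
    panel["any1_nash"] = panel["hair_nash"] | panel["gholam_nash"] | panel["lfs_nash"]

    for scheme in SCHEMES:
        flag = panel[f"{scheme}_nash"].to_numpy(dtype=bool)
        panel[f"label_{scheme}"] = np.where(
            flag, "nash", np.where(nafld, "simple_nafld", "normal_mild")
        )
    return panel


def classify_subject(
    record: pd.Series | dict, config: ScoreConfig = DEFAULT_CONFIG
) -> dict:
    """Score panel for a single subject, as a plain dict."""
    df = pd.DataFrame([record])
    return classify_cohort(df, config=config).iloc[0].to_dict()
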