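"""Synthetic NHANES-like cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes: a three-level latent liver state (normal/mild steatosis, simple
NAFLD, NASH) whose prevalence and covariate associations are configurable,
conditionally log-normal/Gaussian laboratory values whose score-relevant
tails (insulin, glucose, AST, ALT, blood pressure, waist) shift with the
latent state, ultrasound grades tied to the latent state with a small
misgrading rate, and a stratified multi-PSU design with unequal log-normal
sampling weights.

The latent state follows an exact baseline-category multinomial logit in
the configured covariate indicators (NASH-vs-normal log odds = the
configured ``log(OR)``; simple-NAFLD-vs-normal gets half that log odds),
with intercepts calibrated numerically so the marginal class frequencies
match ``latent_prevalence``.  Exact model form is what makes parameter
recovery by a correctly specified multinomial fit an honest test.

States that would trigger eligibility exclusions (out-of-range age,
ungradable ultrasound, chronic hepatitis serology, transferrin saturation
>50%, excessive alcohol, steatogenic medication) are injected only through
explicit :class:`ContaminationRates`, never by the natural lab draws, so a
zero-contamination configuration yields a cohort that passes the
exclusion stage untouched.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import optimize

from .cohort import COHORT_SCHEMA, validate_cohort

__all__ = ["SyntheticCohortConfig", "ContaminationRates", "generate_cohort", "LATENT_STATES"]

LATENT_STATES = ("normal_mild", "simple_nafld", "nash")


class ContaminationRates(BaseModel):
    """Per-subject probabilities of each exclusion-triggering state."""

    age_out_of_range: float = 0.02
    ungradable_ultrasound: float = 0.015
    chronic_hep_b: float = 0.004
    chronic_hep_c: float = 0.010
    high_transferrin: float = 0.010
    excessive_alcohol: float = 0.030
    steatogenic_medication: float = 0.010

    @model_validator(mode="after")
    def _probabilities(self):
        for name, v in self.model_dump().items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        return self

    @classmethod
    def none(cls) -> "ContaminationRates":
        return cls(**{k: 0.0 for k in cls.model_fields})


class SyntheticCohortConfig(BaseModel):
    """Configuration of one synthetic cohort draw.

    ``effect_or`` maps covariate contrasts written ``"column=level"``
    (e.g. ``"race_ethnicity=mexican_american"``) to the odds ratio of
    latent NASH versus latent normal for that level against the column's
    reference level.
    """

    n_subjects: int = Field(gt=0)
    seed: int = 0
    latent_prevalence: tuple[float, float, float] = (0.80, 0.12, 0.08)
    effect_or: dict[str, float] = Field(
        default_factory=lambda: {"race_ethnicity=mexican_american": 1.6}
    )
    n_strata: int = Field(default=14, gt=0)
    psus_per_stratum: int = Field(default=2, ge=2)
    weight_cv: float = Field(default=0.5, ge=0.0)
    missingness_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    misgrading_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    contamination: ContaminationRates = Field(default_factory=ContaminationRates)

    @field_validator("latent_prevalence")
    @classmethod
    def _simplex(cls, v):
        if any(p < 0 or p > 1 for p in v):
            raise ValueError("latent_prevalence entries must be in [0, 1]")
        if abs(sum(v) - 1.0) > 1e-12:
            raise ValueError("latent_prevalence must sum to 1 within 1e-12")
        return v

    @field_validator("effect_or")
    @classmethod
    def _positive_or(cls, v):
        for k, orv in v.items():
            if orv <= 0:
                raise ValueError(f"effect_or[{k!r}] must be > 0")
            if "=" not in k:
                raise ValueError(f"effect_or key {k!r} must be 'column=level'")
        return v

    @model_validator(mode="after")
    def _enough_subjects(self):
        if self.n_subjects < self.n_strata * self.psus_per_stratum:
            raise ValueError("n_subjects must cover every (stratum, psu) cell")
        return self


# Per-latent-class lab parameters: (normal_mild, simple_nafld, nash).
_CLASS = {
    "insulin_mu": (np.log(8.0), np.log(12.0), np.log(18.0)),
    "insulin_sigma": (0.45, 0.45, 0.50),
    "glucose_mean": (92.0, 97.0, 108.0),
    "glucose_sd": (9.0, 12.0, 25.0),
    "alt_mu": (np.log(18.0), np.log(28.0), np.log(45.0)),
    "alt_sigma": (0.35, 0.40, 0.45),
    "ast_mu": (np.log(20.0), np.log(24.0), np.log(40.0)),
    "ast_sigma": (0.30, 0.35, 0.45),
    "sbp_mean": (118.0, 124.0, 130.0),
    "sbp_sd": (13.0, 14.0, 15.0),
    "dbp_mean": (74.0, 77.0, 80.0),
    "dbp_sd": (9.0, 9.0, 10.0),
    "waist_shift": (0.0, 6.0, 13.0),
    "tg_mu": (np.log(110.0), np.log(140.0), np.log(180.0)),
    "tg_sigma": (0.45, 0.45, 0.50),
    "hdl_shift": (0.0, -4.0, -8.0),
    "dm_dx": (0.04, 0.09, 0.20),
    "htn_dx": (0.15, 0.22, 0.32),
    "crp_mu": (np.log(0.21), np.log(0.30), np.log(0.40)),
    "crp_sigma": (0.70, 0.70, 0.80),
}


def _contrast_matrix(df: pd.DataFrame, effect_or: Mapping[str, float]):
    """Indicator matrix and log-OR vector for the configured contrasts."""
    cols = []
    betas = []
    for key, orv in effect_or.items():
        col, level = key.split("=", 1)
        if col not in df.columns:
            raise ValueError(f"effect_or references unknown column {col!r}")
        cols.append((df[col] == level).to_numpy(dtype=float))
        betas.append(np.log(orv))
    if not cols:
        return np.zeros((len(df), 0)), np.zeros(0)
    return np.column_stack(cols), np.asarray(betas)


def _calibrate_intercepts(eta1: np.ndarray, eta2: np.ndarray, target: np.ndarray):
    """Solve for (a1, a2) so mean softmax class probabilities hit ``target``."""

    def mean_probs(a):
        e1 = np.exp(a[0] + eta1)
        e2 = np.exp(a[1] + eta2)
        denom = 1.0 + e1 + e2
        return np.array([(e1 / denom).mean(), (e2 / denom).mean()])

    x0 = np.log(target[1:] / target[0])
    sol = optimize.root(lambda a: mean_probs(a) - target[1:], x0, method="hybr")
    if not sol.success:  # pragma: no cover - well-posed for valid configs
        raise RuntimeError(f"intercept calibration failed: {sol.message}")
    return sol.x


def generate_cohort(config: SyntheticCohortConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw one synthetic cohort.

    Returns
    -------
    (cohort, latent)
        ``cohort`` is a DataFrame in the canonical schema; ``latent`` is an
        array of latent liver-state labels aligned with its rows.  The draw
        is fully determined by ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    c = config.contamination

    df = pd.DataFrame(index=pd.RangeIndex(n))
    df["subject_id"] = [f"S{i:07d}" for i in range(n)]

    # --- demographics -----------------------------------------------------
    df["age"] = np.floor(rng.uniform(20, 75, n)).astype(int)
    age_out = rng.random(n) < c.age_out_of_range
    df.loc[age_out, "age"] = np.where(
        rng.random(age_out.sum()) < 0.5,
        rng.integers(15, 20, age_out.sum()),
        rng.integers(75, 90, age_out.sum()),
    )
    df["sex"] = rng.choice(["male", "female"], n, p=[0.48, 0.52])
    df["race_ethnicity"] = rng.choice(
        ["white", "black", "mexican_american", "other"], n, p=[0.74, 0.10, 0.05, 0.11]
    )
    df["education"] = rng.choice(["lt_hs", "hs", "gt_hs"], n, p=[0.21, 0.34, 0.45])
    df["poverty_ratio"] = np.round(np.clip(rng.lognormal(np.log(2.0), 0.6, n), 0, 11), 3)
    df["urbanization"] = rng.choice(["urban", "rural"], n, p=[0.46, 0.54])
    is_ma = (df["race_ethnicity"] == "mexican_american").to_numpy()
    birth = np.where(rng.random(n) < 0.93, "us", "other").astype(object)
    birth[is_ma & (rng.random(n) < 0.45)] = "mexico"
    df["birthplace"] = birth
    stay = rng.choice(["lt5", "5to10", "gt10"], n, p=[0.15, 0.25, 0.60])
    df["years_in_us"] = np.where(birth == "us", "entire_life", stay)
    df["smoking"] = rng.choice(["never", "former", "current"], n, p=[0.45, 0.25, 0.30])
    df["activity_level"] = rng.choice(
        ["inactive", "below_guidelines", "meets_guidelines"], n, p=[0.14, 0.42, 0.44]
    )

    # --- latent liver state ----------------------------------------------
    X, beta = _contrast_matrix(df, config.effect_or)
    eta2 = X @ beta            # NASH vs normal
    eta1 = 0.5 * eta2          # simple NAFLD vs normal: half the log odds
    target = np.asarray(config.latent_prevalence)
    a1, a2 = _calibrate_intercepts(eta1, eta2, target)
    e1, e2 = np.exp(a1 + eta1), np.exp(a2 + eta2)
    denom = 1.0 + e1 + e2
    probs = np.column_stack([1.0 / denom, e1 / denom, e2 / denom])
    u = rng.random(n)
    latent_idx = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    latent = np.asarray(LATENT_STATES)[latent_idx]

    def per_class(key):
        return np.asarray(_CLASS[key])[latent_idx]

    # --- laboratory values and anthropometrics ----------------------------
    df["fasting_insulin"] = np.round(
        rng.lognormal(per_class("insulin_mu"), per_class("insulin_sigma")), 2
    )
    df["fasting_glucose"] = np.round(
        np.clip(rng.normal(per_class("glucose_mean"), per_class("glucose_sd")), 55, 450), 1
    )
    df["alt"] = np.round(rng.lognormal(per_class("alt_mu"), per_class("alt_sigma")), 1)
    df["ast"] = np.round(rng.lognormal(per_class("ast_mu"), per_class("ast_sigma")), 1)
    df["systolic_bp"] = np.round(
        np.clip(rng.normal(per_class("sbp_mean"), per_class("sbp_sd")), 85, 230), 0
    )
    df["diastolic_bp"] = np.round(
        np.clip(rng.normal(per_class("dbp_mean"), per_class("dbp_sd")), 45, 130), 0
    )
    male = (df["sex"] == "male").to_numpy()
    waist_base = np.where(male, rng.normal(94, 11, n), rng.normal(88, 13, n))
    df["waist_cm"] = np.round(np.clip(waist_base + per_class("waist_shift"), 55, 190), 1)
    whr = np.clip(
        np.where(male, rng.normal(0.93, 0.05, n), rng.normal(0.83, 0.05, n))
        + np.array([0.0, 0.02, 0.05])[latent_idx],
        0.6,
        1.35,
    )
    df["hip_cm"] = np.round(df["waist_cm"] / whr, 1)
    df["triglyceride"] = np.round(rng.lognormal(per_class("tg_mu"), per_class("tg_sigma")), 0)
    hdl_base = np.where(male, rng.normal(45, 11, n), rng.normal(55, 12, n))
    df["hdl"] = np.round(np.clip(hdl_base + per_class("hdl_shift"), 15, 130), 0)
    df["total_cholesterol"] = np.round(np.clip(rng.normal(205, 40, n), 90, 450), 0)
    df["crp"] = np.round(rng.lognormal(per_class("crp_mu"), per_class("crp_sigma")), 3)
    df["c_peptide"] = np.round(
        np.clip(0.05 * df["fasting_insulin"] + rng.normal(0.25, 0.18, n), 0.03, 6.0), 3
    )
    df["two_hr_glucose"] = np.round(
        np.clip(1.25 * df["fasting_glucose"] + rng.normal(5, 28, n), 50, 550), 1
    )
    df["hba1c"] = np.round(
        np.clip(5.3 + 0.018 * (df["fasting_glucose"] - 92) + rng.normal(0, 0.4, n), 3.8, 15), 1
    )
    df["hei_score"] = np.round(np.clip(rng.normal(63, 12, n), 5, 100), 1)

    # diagnoses and treatment
    df["dm_diagnosis"] = rng.random(n) < per_class("dm_dx")
    df["htn_diagnosis"] = rng.random(n) < per_class("htn_dx")
    df["htn_medication"] = df["htn_diagnosis"] & (rng.random(n) < 0.7)

    # --- alcohol: natural draws capped below the excess threshold ---------
    days = np.minimum(np.round(rng.lognormal(np.log(40), 1.0, n)), 365)
    drinks = rng.lognormal(np.log(1.5), 0.6, n)
    limit = np.where(male, 2.0, 1.0)
    avg = days * drinks / 365.0
    over = avg > 0.95 * limit
    drinks = np.where(over & (days > 0), 0.95 * limit * 365.0 / np.maximum(days, 1), drinks)
    excess = rng.random(n) < c.excessive_alcohol
    target_avg = limit + rng.uniform(0.5, 3.0, n)
    days = np.where(excess, np.maximum(days, 180), days)
    drinks = np.where(excess, target_avg * 365.0 / np.maximum(days, 1), drinks)
    df["alcohol_days_per_year"] = days.astype(int)
    df["alcohol_drinks_per_day"] = np.round(drinks, 3)
    ever = rng.random(n) < 0.85
    df["ever_12_drinks_lifetime"] = ever | excess
    df["twelve_drinks_past_year"] = df["ever_12_drinks_lifetime"] & (
        (rng.random(n) < 0.75) | excess
    )

    # --- serology, transferrin, medications (contamination-only exclusions)
    df["anti_hbc_positive"] = rng.random(n) < 0.05
    df["hbsag_positive"] = False
    hep_b = rng.random(n) < c.chronic_hep_b
    df.loc[hep_b, "hbsag_positive"] = True
    df.loc[hep_b, "anti_hbc_positive"] = True
    df["hcv_ab_positive"] = rng.random(n) < 0.015
    df["hcv_rna_positive"] = False
    hep_c = rng.random(n) < c.chronic_hep_c
    df.loc[hep_c, "hcv_ab_positive"] = True
    df.loc[hep_c, "hcv_rna_positive"] = True
    tsat = np.clip(rng.normal(28, 8, n), 2, 49.5)
    high_tsat = rng.random(n) < c.high_transferrin
    tsat = np.where(high_tsat, rng.uniform(51, 85, n), tsat)
    df["transferrin_saturation"] = np.round(tsat, 1)
    df["steatogenic_medication"] = rng.random(n) < c.steatogenic_medication

    # --- ultrasound grade tied to latent state ----------------------------
    grade = np.empty(n, dtype=object)
    normal = latent_idx == 0
    grade[normal] = np.where(rng.random(normal.sum()) < 0.70, "none", "mild")
    nafld = latent_idx == 1
    grade[nafld] = np.where(rng.random(nafld.sum()) < 0.75, "moderate", "severe")
    nash = latent_idx == 2
    grade[nash] = np.where(rng.random(nash.sum()) < 0.50, "moderate", "severe")
    misgraded = rng.random(n) < config.misgrading_rate
    grade[misgraded & normal] = "moderate"
    grade[misgraded & ~normal] = "mild"
    ungradable = rng.random(n) < c.ungradable_ultrasound
    grade[ungradable] = np.where(
        rng.random(ungradable.sum()) < 0.5, "ungradable", "missing"
    )
    df["ultrasound_grade"] = grade

    # --- survey design -----------------------------------------------------
    n_cells = config.n_strata * config.psus_per_stratum
    cell = np.concatenate([np.arange(n_cells), rng.integers(0, n_cells, n - n_cells)])
    rng.shuffle(cell)
    df["stratum"] = [f"S{c_ // config.psus_per_stratum + 1:02d}" for c_ in cell]
    df["psu"] = [f"P{c_ % config.psus_per_stratum + 1}" for c_ in cell]
    if config.weight_cv > 0:
        sigma = np.sqrt(np.log1p(config.weight_cv**2))
        w = rng.lognormal(-0.5 * sigma**2, sigma, n)
    else:
        w = np.ones(n)
    df["weight"] = np.round(w, 6)

    # --- missingness on optional analysis covariates -----------------------
    if config.missingness_rate > 0:
        optional = [
            "poverty_ratio", "education", "smoking", "activity_level",
            "hei_score", "crp", "c_peptide", "total_cholesterol", "hdl",
            "triglyceride", "two_hr_glucose", "hba1c",
        ]
        for col in optional:
            mask = rng.random(n) < config.missingness_rate
            df.loc[mask, col] = pd.NA if df[col].dtype == object else np.nan

    df = df.reindex(columns=COHORT_SCHEMA)
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype("boolean")
    validate_cohort(df)
    return df, latent
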