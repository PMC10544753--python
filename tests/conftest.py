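import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nashscreen import ContaminationRates, SyntheticCohortConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_subject(**overrides) -> dict:
    """One fully specified, unremarkable eligible subject."""
    base = dict(
        subject_id="S0000001",
        age=45,
        sex="male",
        race_ethnicity="white",
        education="hs",
        poverty_ratio=2.5,
        urbanization="urban",
        birthplace="us",
        years_in_us="entire_life",
        smoking="never",
        alcohol_days_per_year=24,
        alcohol_drinks_per_day=1.0,
        ever_12_drinks_lifetime=True,
        twelve_drinks_past_year=True,
        activity_level="meets_guidelines",
        waist_cm=90.0,
        hip_cm=100.0,
        systolic_bp=118.0,
        diastolic_bp=74.0,
        htn_diagnosis=False,
        htn_medication=False,
        dm_diagnosis=False,
        fasting_glucose=90.0,
        two_hr_glucose=110.0,
        fasting_insulin=6.0,
        c_peptide=0.6,
        alt=20.0,
        ast=22.0,
        total_cholesterol=190.0,
        hdl=50.0,
        triglyceride=110.0,
        crp=0.2,
        hba1c=5.3,
        transferrin_saturation=28.0,
        hbsag_positive=False,
        anti_hbc_positive=False,
        hcv_ab_positive=False,
        hcv_rna_positive=False,
        steatogenic_medication=False,
        hei_score=70.0,
        ultrasound_grade="none",
        stratum="S01",
        psu="P1",
        weight=1.0,
    )
    base.update(overrides)
    return base


def make_cohort(subjects) -> pd.DataFrame:
    df = pd.DataFrame(subjects)
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype("boolean")
    return df


@pytest.fixture
def subject_factory():
    return make_subject


@pytest.fixture
def cohort_factory():
    def build(n=4, **overrides):
        rows = []
        for i in range(n):
            row = make_subject(
                subject_id=f"S{i:07d}",
                stratum=f"S{(i % 2) + 1:02d}",
                psu=f"P{(i // 2) % 2 + 1}",
            )
            row.update(overrides)
            rows.append(row)
        return make_cohort(rows)

    return build


@pytest.fixture(scope="session")
def clean_synth_cohort():
    """A contamination-free, fully observed synthetic cohort with latent labels."""
    cfg = SyntheticCohortConfig(
        n_subjects=2000, seed=42, missingness_rate=0.0,
        contamination=ContaminationRates.none(),
    )
    return generate_cohort(cfg)


def equal_weight_design_frame(n: int, n_strata: int = 5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equal weights, round-robin strata with two PSUs each."""
    stratum = np.array([f"S{i % n_strata}" for i in range(n)])
    psu = np.array([f"P{(i // n_strata) % 2}" for i in range(n)])
    return stratum, psu, np.ones(n)
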