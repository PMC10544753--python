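"""Score formulas, covariate categorization, and three-class labelling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nashscreen import (
    ScoreConfig,
    classify_cohort,
    classify_subject,
    categorize_covariates,
    compute_homa_ir,
    derive_features,
    gholam_score,
    hair_score,
    metabolic_syndrome,
    nash_lfs,
)
from conftest import make_cohort, make_subject


class TestHomaIr:
    @pytest.mark.parametrize(
        "glucose,insulin,expected",
        [(90, 4.5, 1.0), (405, 1, 1.0), (126, 15, 126 * 15 / 405)],
    )
    def test_matthews_formula(self, glucose, insulin, expected):
        assert compute_homa_ir(glucose, insulin) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_homa_ir(0, 5)


class TestHair:
    @pytest.mark.parametrize(
        "args,points,positive",
        [
            ((6.0, 50, 150, 95, False, False), 3, True),
            ((1.0, 10, 110, 70, False, False), 0, False),
            # HOMA exactly 5 earns no point (strict >); DBP 90 does (>= 90)
            ((5.0, 41, 139, 90, False, False), 2, True),
            ((5.0, 40, 139, 89, False, True), 1, False),  # medication alone
        ],
    )
    def test_point_assignment(self, args, points, positive):
        assert hair_score(*args) == (points, positive)

    @given(
        homa=st.floats(0.1, 20), alt=st.floats(1, 200),
        sbp=st.floats(90, 200), dbp=st.floats(50, 120),
    )
    def test_points_nondecreasing_in_each_component(self, homa, alt, sbp, dbp):
        base, _ = hair_score(homa, alt, sbp, dbp, False, False)
        worse, _ = hair_score(homa + 10, alt + 100, sbp + 40, dbp + 30, False, False)
        assert worse >= base


class TestGholam:
    def test_ln_one_is_zero(self):
        value, positive = gholam_score(1.0, False)
        assert value == pytest.approx(0.0)
        assert not positive

    def test_diabetes_adds_constant(self):
        value, positive = gholam_score(50, True)
        assert value == pytest.approx(2.627 * math.log(50) + 2.13)
        assert positive

    def test_cutoff_root_is_inclusive(self):
        # exp(8.22 / 2.627) is the AST at which a non-diabetic crosses 8.22
        ast_star = math.exp(8.22 / 2.627)
        value, positive = gholam_score(ast_star, False)
        assert value == pytest.approx(8.22, abs=1e-9)
        assert positive
        _, below = gholam_score(ast_star - 0.05, False)
        assert not below

    def test_nonpositive_ast_rejected(self):
        with pytest.raises(ValueError):
            gholam_score(0, False)

    @given(ast=st.floats(1, 500), bump=st.floats(0.1, 100))
    def test_strictly_increasing_in_ast(self, ast, bump):
        assert gholam_score(ast + bump, False)[0] > gholam_score(ast, False)[0]


class TestMetabolicSyndrome:
    def test_three_criteria_suffice(self):
        assert metabolic_syndrome(100, "male", 200, 35, 120, 70, False, 90, False)

    def test_all_normal_is_negative(self):
        assert not metabolic_syndrome(90, "male", 100, 50, 118, 75, False, 90, False)

    def test_waist_cut_strict_for_women(self):
        # waist exactly 80 does not meet the female waist criterion
        at_cut = metabolic_syndrome(80.0, "female", 200, 45, 120, 70, False, 90, False)
        above = metabolic_syndrome(80.1, "female", 200, 45, 120, 70, False, 90, False)
        assert not at_cut
        assert above

    def test_bp_rule_configurable(self):
        # SBP 135 / DBP 70: fails under AND, qualifies under OR
        base = dict(waist_cm=100, sex="male", triglyceride=200, hdl=45,
                    sbp=135, dbp=70, htn_treated=False,
                    fasting_glucose=90, glycemia_treated=False)
        assert not metabolic_syndrome(**base)
        assert metabolic_syndrome(**base, config=ScoreConfig(ms_bp_rule="or"))


class TestNashLfs:
    @pytest.mark.parametrize(
        "ms,dm,insulin,ast,alt,value,positive",
        [
            (False, False, 0, 20, 20, 0.15 * 0 + 0.8 - 0.94 - 2.89, False),
            (True, True, 20, 60, 30, 1.18 + 0.9 + 3.0 + 2.4 - 1.88 - 2.89, True),
            (False, False, 0, 30, 30, -0.94 - 2.89 + 1.2, False),
        ],
    )
    def test_linear_predictor(self, ms, dm, insulin, ast, alt, value, positive):
        got, pos = nash_lfs(ms, dm, insulin, ast, alt)
        assert got == pytest.approx(value)
        assert pos is positive

    def test_cutoff_inclusive_by_default_and_configurable(self):
        insulin = (2.122 + 2.89 + 0.94 - 0.04 * 20) / 0.15
        value, pos = nash_lfs(False, False, insulin, 20, 20)
        assert value == pytest.approx(2.122)
        assert pos
        # pin the cutoff to the exactly attained value: inclusive flags it,
        # strict comparison does not
        at_cut = ScoreConfig(lfs_cut=value)
        assert nash_lfs(False, False, insulin, 20, 20, config=at_cut)[1]
        strict = ScoreConfig(lfs_cut=value, lfs_cut_inclusive=False)
        assert not nash_lfs(False, False, insulin, 20, 20, config=strict)[1]

    def test_zero_alt_rejected(self):
        with pytest.raises(ValueError):
            nash_lfs(False, False, 10, 20, 0)

    @given(ins=st.floats(0, 60), bump=st.floats(0.1, 30))
    def test_increasing_in_insulin(self, ins, bump):
        lo, _ = nash_lfs(False, False, ins, 20, 20)
        hi, _ = nash_lfs(False, False, ins + bump, 20, 20)
        assert hi > lo

    def test_increasing_in_ms_and_dm_codes(self):
        v00, _ = nash_lfs(False, False, 10, 20, 20)
        v10, _ = nash_lfs(True, False, 10, 20, 20)
        v11, _ = nash_lfs(True, True, 10, 20, 20)
        assert v00 < v10 < v11


class TestCategorization:
    @pytest.mark.parametrize(
        "col,value,expected_col,expected",
        [
            ("total_cholesterol", 200.0, "chol_cat", "normal"),    # <= 200 normal
            ("total_cholesterol", 239.9, "chol_cat", "elevated"),
            ("total_cholesterol", 240.0, "chol_cat", "high"),
            ("crp", 0.29, "crp_cat", "normal"),
            ("crp", 0.3, "crp_cat", "mild"),
            ("crp", 1.0, "crp_cat", "mild"),
            ("crp", 1.01, "crp_cat", "significant"),
            ("c_peptide", 0.25, "c_peptide_cat", "low"),
            ("c_peptide", 1.03, "c_peptide_cat", "normal"),
            ("c_peptide", 1.04, "c_peptide_cat", "high"),
            ("hei_score", 49.9, "hei_cat", "poor"),
            ("hei_score", 80.0, "hei_cat", "needs_improvement"),
            ("hei_score", 80.1, "hei_cat", "good"),
        ],
    )
    def test_lab_category_boundaries(self, col, value, expected_col, expected):
        df = make_cohort([make_subject(**{col: value})])
        assert categorize_covariates(df)[expected_col].iloc[0] == expected

    @pytest.mark.parametrize(
        "sex,waist,hip,expected",
        [
            ("female", 84.0, 100.0, "healthy"),   # ratio 0.84 < 0.85
            ("female", 85.0, 100.0, "at_risk"),
            ("male", 89.0, 100.0, "healthy"),
            ("male", 90.0, 100.0, "at_risk"),
        ],
    )
    def test_whr_risk_cutoffs_by_sex(self, sex, waist, hip, expected):
        df = make_cohort([make_subject(sex=sex, waist_cm=waist, hip_cm=hip)])
        assert categorize_covariates(df)["whr_risk"].iloc[0] == expected

    @pytest.mark.parametrize(
        "age,expected",
        [(20, "20_34"), (34, "20_34"), (35, "35_49"), (49, "35_49"),
         (50, "50_64"), (64, "50_64"), (65, "65_plus"), (74, "65_plus")],
    )
    def test_age_groups(self, age, expected):
        df = make_cohort([make_subject(age=age)])
        assert categorize_covariates(df)["age_group"].iloc[0] == expected

    @pytest.mark.parametrize(
        "ever,past,expected",
        [(False, False, "never"), (True, False, "former"), (True, True, "current")],
    )
    def test_alcohol_status_from_screening_questions(self, ever, past, expected):
        df = make_cohort([make_subject(ever_12_drinks_lifetime=ever,
                                       twelve_drinks_past_year=past)])
        assert categorize_covariates(df)["alcohol_status"].iloc[0] == expected


class TestDiabetesVariants:
    def test_gholam_strict_glucose_cut_vs_lfs_inclusive(self):
        df = make_cohort([make_subject(fasting_glucose=126.0, two_hr_glucose=100.0)])
        feats = derive_features(df)
        assert not feats["diabetes_gholam"].iloc[0]  # strict > 126
        assert feats["diabetes_lfs"].iloc[0]         # inclusive >= 126

    def test_two_hour_glucose_only_feeds_lfs_definition(self):
        df = make_cohort([make_subject(fasting_glucose=100.0, two_hr_glucose=200.0)])
        feats = derive_features(df)
        assert not feats["diabetes_gholam"].iloc[0]
        assert feats["diabetes_lfs"].iloc[0]


class TestClassification:
    def test_positive_scores_without_nafld_stay_normal(self):
        sick = make_subject(
            ultrasound_grade="none", fasting_insulin=40, fasting_glucose=180,
            alt=90, ast=80, systolic_bp=160, diastolic_bp=100, dm_diagnosis=True,
            triglyceride=300, hdl=30, waist_cm=120,
        )
        panel = classify_subject(sick)
        assert not panel["any1_nash"]
        for m in ("hair", "gholam", "lfs", "all3", "any1"):
            assert panel[f"label_{m}"] == "normal_mild"

    def test_severe_steatosis_with_all_scores_positive(self):
        sick = make_subject(
            ultrasound_grade="severe", fasting_insulin=40, fasting_glucose=180,
            alt=90, ast=80, systolic_bp=160, diastolic_bp=100, dm_diagnosis=True,
            triglyceride=300, hdl=30, waist_cm=120,
        )
        panel = classify_subject(sick)
        assert panel["all3_nash"] and panel["any1_nash"]
        assert panel["label_all3"] == "nash"

    def test_single_positive_method_splits_labels(self):
        # moderate steatosis; AST high enough for Gholam only
        subj = make_subject(ultrasound_grade="moderate", ast=30.0, alt=60.0,
                            fasting_insulin=4.0)
        panel = classify_subject(subj)
        assert panel["gholam_nash"] and not panel["hair_nash"] and not panel["lfs_nash"]
        assert panel["any1_nash"] and not panel["all3_nash"]
        assert panel["label_gholam"] == "nash"
        assert panel["label_hair"] == "simple_nafld"

    def test_ungradable_ultrasound_is_an_error(self):
        df = make_cohort([make_subject(ultrasound_grade="ungradable")])
        with pytest.raises(ValueError, match="ungradable"):
            classify_cohort(df)

    def test_flag_and_label_invariants_hold_cohortwide(self, clean_synth_cohort):
        df, _ = clean_synth_cohort
        panel = classify_cohort(df)
        assert (panel["all3_nash"] <= panel["any1_nash"]).all()
        expected_all3 = panel["hair_nash"] & panel["gholam_nash"] & panel["lfs_nash"]
        assert (panel["all3_nash"] == expected_all3).all()
        expected_any1 = panel["hair_nash"] | panel["gholam_nash"] | panel["lfs_nash"]
        assert (panel["any1_nash"] == expected_any1).all()
        n = len(panel)
        counts = {m: panel[f"{m}_nash"].sum() for m in ("hair", "gholam", "lfs")}
        assert panel["all3_nash"].sum() <= min(counts.values())
        assert max(counts.values()) <= panel["any1_nash"].sum()
        nafld = df["ultrasound_grade"].isin(["moderate", "severe"]).to_numpy()
        for m in ("hair", "gholam", "lfs", "all3", "any1"):
            assert not panel.loc[~nafld, f"{m}_nash"].any()

    def test_threshold_config_round_trips_yaml(self, tmp_path):
        cfg = ScoreConfig(ms_bp_rule="or", lfs_cut_inclusive=False)
        path = tmp_path / "thresholds.yaml"
        cfg.to_yaml(path)
        assert ScoreConfig.from_yaml(path) == cfg
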