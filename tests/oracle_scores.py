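"""Independent brute-force transcription of the three NASH score formulas.

Deliberately written as a straight per-subject transcription of the
published formulas and cutoffs, without reference to the package's
vectorized implementation, so subject-for-subject agreement is a real
cross-check.
"""

import math


def brute_force_panel(row: dict) -> dict:
    """Score one subject from a plain dict of raw fields."""
    glucose = row["fasting_glucose"]
    insulin = row["fasting_insulin"]
    alt = row["alt"]
    ast = row["ast"]
    sbp = row["systolic_bp"]
    dbp = row["diastolic_bp"]

    homa = glucose * insulin / 405.0
    hypertensive = (
        sbp >= 140 or dbp >= 90 or bool(row["htn_diagnosis"]) or bool(row["htn_medication"])
    )
    hair_points = int(homa > 5) + int(alt > 40) + int(hypertensive)
    hair_pos = hair_points >= 2

    dm_gholam = bool(row["dm_diagnosis"]) or glucose > 126
    gholam_value = 2.627 * math.log(ast) + (2.13 if dm_gholam else 0.0)
    gholam_pos = gholam_value >= 8.22

    two_hr = row.get("two_hr_glucose")
    dm_lfs = (
        bool(row["dm_diagnosis"])
        or glucose >= 126
        or (two_hr is not None and not _isnan(two_hr) and two_hr >= 200)
    )
    waist_cut = 94 if row["sex"] == "male" else 80
    hdl_cut = 40 if row["sex"] == "male" else 50
    criteria = [
        row["waist_cm"] > waist_cut,
        row["triglyceride"] >= 150,
        row["hdl"] < hdl_cut,
        (sbp >= 130 and dbp >= 85) or bool(row["htn_medication"]),
        glucose >= 100 or bool(row["dm_diagnosis"]),
    ]
    ms = sum(criteria) >= 3
    lfs_value = (
        1.18 * int(ms)
        + 0.45 * (2 if dm_lfs else 0)
        + 0.15 * insulin
        + 0.04 * ast
        - 0.94 * (ast / alt)
        - 2.89
    )
    lfs_pos = lfs_value >= 2.122

    nafld = row["ultrasound_grade"] in ("moderate", "severe")
    flags = {
        "hair_nash": nafld and hair_pos,
        "gholam_nash": nafld and gholam_pos,
        "lfs_nash": nafld and lfs_pos,
    }
    flags["all3_nash"] = all(flags.values())
    flags["any1_nash"] = any([flags["hair_nash"], flags["gholam_nash"], flags["lfs_nash"]])

    def label(flag):
        if flag:
            return "nash"
        return "simple_nafld" if nafld else "normal_mild"

    return {
        "hair_points": hair_points,
        "gholam_value": gholam_value,
        "lfs_value": lfs_value,
        **flags,
        "label_hair": label(flags["hair_nash"]),
        "label_gholam": label(flags["gholam_nash"]),
        "label_lfs": label(flags["lfs_nash"]),
        "label_all3": label(flags["all3_nash"]),
        "label_any1": label(flags["any1_nash"]),
    }


def _isnan(x) -> bool:
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return True
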