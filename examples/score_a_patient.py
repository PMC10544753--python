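"""Score one hypothetical patient with the three non-invasive NASH scores.

The patient below has moderate steatosis on ultrasound, insulin
resistance, a mildly elevated ALT, and treated hypertension — a typical
borderline presentation.
"""

from nashscreen import compute_homa_ir, gholam_score, hair_score, metabolic_syndrome, nash_lfs

glucose, insulin = 110.0, 19.0      # mg/dL, µU/mL
alt, ast = 46.0, 38.0               # U/L
sbp, dbp = 132.0, 86.0              # mmHg, on antihypertensive medication

homa = compute_homa_ir(glucose, insulin)
print(f"HOMA-IR                 : {homa:.2f}")

points, hair_pos = hair_score(homa, alt, sbp, dbp, htn_diagnosis=True, htn_medication=True)
print(f"HAIR points             : {points}  (NASH-positive: {hair_pos})")

diabetic = glucose > 126            # Gholam definition: diagnosis or glucose > 126
gval, gholam_pos = gholam_score(ast, diabetic)
print(f"Gholam score            : {gval:.3f}  (NASH-positive: {gholam_pos})")

ms = metabolic_syndrome(
    waist_cm=103, sex="male", triglyceride=180, hdl=38,
    sbp=sbp, dbp=dbp, htn_treated=True,
    fasting_glucose=glucose, glycemia_treated=False,
)
dm_lfs = glucose >= 126             # fat-score definition is inclusive at 126
lval, lfs_pos = nash_lfs(ms, dm_lfs, insulin, ast, alt)
print(f"Metabolic syndrome      : {ms}")
print(f"NASH liver fat score    : {lval:.3f}  (NASH-positive: {lfs_pos})")

# Interpretation: HOMA-IR > 5 and hypertension give two HAIR points, so
# HAIR flags NASH; the Gholam score needs roughly AST >= 23 in a
# non-diabetic, so it flags too; the fat score integrates insulin, AST
# and the metabolic syndrome and sits near its 2.122 cutoff.
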