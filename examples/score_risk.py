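"""Score cerebrovascular risk for a handful of participant profiles.

The CVR score sums seven components: measured hypertension (both
readings >= 140/90 mmHg), antihypertensive use, cholesterol-lowering
medication, diagnosed diabetes, waist-to-hip ratio above the WHO
sex-specific cut-off, a pack-year smoking band (0/1/2 points) and APOE
epsilon-4 carriage (0/1/2 points).  Totals run 0-9.
"""

from neurocvr import RiskFactors, cvr_score

profiles = {
    "low-risk 58-year-old": RiskFactors(
        sbp_readings=[118, 122], dbp_readings=[74, 78],
        on_bp_medication=False, on_cholesterol_medication=False,
        diabetic=False, sex="female", waist_cm=78, hip_cm=98,
        smoking_status="never", apoe_genotype="e3/e3", age_at_scan=58,
    ),
    "treated hypertensive ex-smoker": RiskFactors(
        sbp_readings=[148, 151], dbp_readings=[93, 95],
        on_bp_medication=True, on_cholesterol_medication=True,
        diabetic=False, sex="male", waist_cm=102, hip_cm=104,
        smoking_status="ex", cigarettes_per_day=20,
        age_started_smoking=18, age_stopped_smoking=48, age_at_scan=65,
        apoe_genotype="e3/e4",
    ),
}

for label, rf in profiles.items():
    b = cvr_score(rf)
    print(f"{label}: total {b.total}/9")
    print(f"  hypertension {b.hypertensive_point}, BP med {b.bp_med_point}, "
          f"chol med {b.chol_med_point}, diabetes {b.diabetes_point}, "
          f"WHR {b.whr_point}, smoking {b.smoking_points}, APOE {b.apoe_points}")

# The second profile collects a hypertension point (both averaged readings
# exceed 140/90), both medication points, the WHR point (0.98 >= 0.90),
# one smoking point (30 pack-years falls in the 10-50 band) and one APOE
# point (single epsilon-4 allele): total 6.
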