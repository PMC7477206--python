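"""Cohort column dictionary.

One participant per row.  All analysis modules consume these column names;
the synthetic generator emits exactly this schema.
"""

from __future__ import annotations

N_RT_TRIALS = 12

RT_TRIAL_COLUMNS = tuple(f"rt_trial_{i + 1:02d}" for i in range(N_RT_TRIALS))

#: Demographics and risk-factor fields.
DEMOGRAPHIC_COLUMNS = ("age", "sex", "townsend")
RISK_COLUMNS = (
    "sbp_1",
    "sbp_2",
    "dbp_1",
    "dbp_2",
    "on_bp_medication",
    "on_cholesterol_medication",
    "diabetic",
    "smoking_status",
    "cigarettes_per_day",
    "age_started_smoking",
    "age_stopped_smoking",
    "waist_cm",
    "hip_cm",
    "apoe_genotype",
)

#: Imaging-derived phenotypes (already image-processed upstream; this
#: package consumes scalars, never images).
GM_COLUMNS = (
    "gm_angular_gyrus",
    "gm_precuneus",
    "gm_cingulate_gyrus",
    "gm_superior_frontal_gyrus",
    "gm_frontal_pole",
    "gm_middle_temporal_gyrus",
)
IMAGING_COLUMNS = ("wmh_volume_mm3",) + GM_COLUMNS + ("slf_icvf", "slf_od")

COGNITIVE_COLUMNS = RT_TRIAL_COLUMNS + ("pairs_errors",)

ALL_COLUMNS = DEMOGRAPHIC_COLUMNS + RISK_COLUMNS + IMAGING_COLUMNS + COGNITIVE_COLUMNS

#: Ordered variables of the structural-model matrix (standardised scale).
#: ``rt`` is the negated filtered mean reaction time and ``pairs`` the
#: negated pairs-matching error count, so that a higher executive-function
#: latent means better performance.
MODEL_COLUMNS = (
    "age",
    "cvr",
    "wmh",
    "gm_angular_gyrus",
    "gm_precuneus",
    "gm_cingulate_gyrus",
    "gm_superior_frontal_gyrus",
    "gm_frontal_pole",
    "gm_middle_temporal_gyrus",
    "slf_icvf",
    "slf_od",
    "rt",
    "pairs",
)

SMOKING_STATUSES = ("never", "ex", "current")
APOE_ALLELES = ("e2", "e3", "e4")
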