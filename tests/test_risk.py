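"""Cerebrovascular risk scoring rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neurocvr.risk import (
    MissingDataError,
    RiskFactors,
    apoe_points,
    cvr_score,
    is_hypertensive,
    mean_bp,
    pack_years,
    score_cohort,
    smoking_points,
    whr_exceeds_threshold,
)


@pytest.mark.parametrize(
    "readings, expected",
    [([120, 130], 125.0), ([118], 118.0), ([90, 95, 100], 95.0)],
)
def test_mean_bp(readings, expected):
    assert mean_bp(readings) == pytest.approx(expected)


def test_mean_bp_empty_is_missing():
    with pytest.raises(MissingDataError):
        mean_bp([])


@pytest.mark.parametrize(
    "sbp, dbp, expected",
    [
        (145, 95, True),
        (150, 85, False),  # both readings must exceed the threshold
        (135, 95, False),
        (140, 90, True),  # inclusive boundary
    ],
)
def test_hypertension_requires_both_thresholds(sbp, dbp, expected):
    assert is_hypertensive(sbp, dbp) is expected


def test_hypertension_rejects_nonpositive():
    with pytest.raises(ValueError):
        is_hypertensive(-1, 80)


@pytest.mark.parametrize(
    "waist, hip, sex, expected",
    [
        (95, 100, "male", True),
        (84, 100, "female", False),
        (85, 100, "female", True),  # WHO cut-off inclusive
        (89, 100, "male", False),
    ],
)
def test_whr_cutoffs(waist, hip, sex, expected):
    assert whr_exceeds_threshold(waist, hip, sex) is expected


def test_whr_zero_hip():
    with pytest.raises(ZeroDivisionError):
        whr_exceeds_threshold(90, 0, "male")


@pytest.mark.parametrize(
    "cigs, start, end, expected",
    [(20, 20, 30, 10.0), (40, 25, 55, 60.0), (10, 30, 30, 0.0)],
)
def test_pack_years(cigs, start, end, expected):
    assert pack_years(cigs, start, end) == pytest.approx(expected)


def test_pack_years_rejects_inverted_ages():
    with pytest.raises(ValueError):
        pack_years(20, 40, 30)


@pytest.mark.parametrize(
    "status, py, expected",
    [
        ("ex", 30, 1),
        ("current", 60, 2),
        ("never", None, 0),
        ("ex", 9.99, 0),
        ("ex", 10, 1),  # band closed at both ends
        ("ex", 50, 1),
        ("current", 50.01, 2),
    ],
)
def test_smoking_points_bands(status, py, expected):
    assert smoking_points(status, py) == expected


@given(st.floats(min_value=0, max_value=200), st.floats(min_value=0, max_value=200))
def test_smoking_points_monotone(py1, py2):
    lo, hi = sorted([py1, py2])
    assert smoking_points("ex", lo) <= smoking_points("ex", hi)


@pytest.mark.parametrize(
    "genotype, expected",
    [
        ("e3/e3", 0),
        ("e3/e4", 1),
        ("e4/e4", 2),
        ("e2/e4", 1),
        ("e2/e2", 0),
        ("e2/e3", 0),
        ("ε3/ε4", 1),  # greek-letter spelling accepted
    ],
)
def test_apoe_points_counts_e4(genotype, expected):
    assert apoe_points(genotype) == expected


def test_apoe_rejects_unknown_allele():
    with pytest.raises(ValueError):
        apoe_points("e3/e5")


def _minimal_risk() -> RiskFactors:
    return RiskFactors(
        sbp_readings=[120, 122],
        dbp_readings=[78, 80],
        on_bp_medication=False,
        on_cholesterol_medication=False,
        diabetic=False,
        sex="female",
        waist_cm=80,
        hip_cm=100,
        smoking_status="never",
        apoe_genotype="e3/e3",
        age_at_scan=60,
    )


def _maximal_risk() -> RiskFactors:
    return RiskFactors(
        sbp_readings=[160, 165],
        dbp_readings=[100, 98],
        on_bp_medication=True,
        on_cholesterol_medication=True,
        diabetic=True,
        sex="male",
        waist_cm=110,
        hip_cm=100,
        smoking_status="current",
        cigarettes_per_day=40,
        age_started_smoking=15,
        age_at_scan=70,  # 2 x 55 = 110 pack-years
        apoe_genotype="e4/e4",
    )


def test_all_minimal_profile_scores_zero():
    assert cvr_score(_minimal_risk()).total == 0


def test_three_unit_components():
    rf = RiskFactors(
        sbp_readings=[150],
        dbp_readings=[95],
        on_bp_medication=True,
        diabetic=True,
    )
    b = cvr_score(rf)
    assert (b.hypertensive_point, b.bp_med_point, b.diabetes_point) == (1, 1, 1)
    assert b.total == 3
    assert set(b.missing) == {"chol_med_point", "whr_point", "smoking_points", "apoe_points"}


def test_maximal_profile_scores_nine():
    # enumerated component maxima: 1+1+1+1+1+2+2
    assert cvr_score(_maximal_risk()).total == 9


def test_all_missing_raises():
    with pytest.raises(MissingDataError):
        cvr_score(RiskFactors())


def test_propagate_mode_raises_on_partial_missingness():
    rf = RiskFactors(diabetic=True)
    with pytest.raises(MissingDataError):
        cvr_score(rf, on_missing="propagate")


_rf_strategy = st.builds(
    RiskFactors,
    sbp_readings=st.lists(st.floats(90, 200), min_size=1, max_size=2),
    dbp_readings=st.lists(st.floats(50, 120), min_size=1, max_size=2),
    on_bp_medication=st.booleans(),
    on_cholesterol_medication=st.booleans(),
    diabetic=st.booleans(),
    sex=st.sampled_from(["male", "female"]),
    waist_cm=st.floats(60, 140),
    hip_cm=st.floats(70, 140),
    smoking_status=st.sampled_from(["never", "ex", "current"]),
    cigarettes_per_day=st.floats(1, 60),
    age_started_smoking=st.floats(12, 30),
    age_stopped_smoking=st.floats(30, 60),
    age_at_scan=st.floats(60, 73),
    apoe_genotype=st.sampled_from(
        ["e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4"]
    ),
)


@given(_rf_strategy)
def test_total_equals_component_sum(rf):
    b = cvr_score(rf)
    assert 0 <= b.total <= 9
    assert b.total == (
        b.hypertensive_point
        + b.bp_med_point
        + b.chol_med_point
        + b.diabetes_point
        + b.whr_point
        + b.smoking_points
        + b.apoe_points
    )


def test_vectorised_scoring_matches_scalar(tiny_cohort):
    table = score_cohort(tiny_cohort)
    for i in range(0, len(tiny_cohort), 97):
        row = tiny_cohort.iloc[i]
        rf = RiskFactors(
            sbp_readings=[row["sbp_1"], row["sbp_2"]],
            dbp_readings=[row["dbp_1"], row["dbp_2"]],
            on_bp_medication=bool(row["on_bp_medication"]),
            on_cholesterol_medication=bool(row["on_cholesterol_medication"]),
            diabetic=bool(row["diabetic"]),
            sex=row["sex"],
            waist_cm=row["waist_cm"],
            hip_cm=row["hip_cm"],
            smoking_status=row["smoking_status"],
            cigarettes_per_day=None
            if pd.isna(row["cigarettes_per_day"])
            else row["cigarettes_per_day"],
            age_started_smoking=None
            if pd.isna(row["age_started_smoking"])
            else row["age_started_smoking"],
            age_stopped_smoking=None
            if pd.isna(row["age_stopped_smoking"])
            else row["age_stopped_smoking"],
            age_at_scan=row["age"],
            apoe_genotype=row["apoe_genotype"],
        )
        assert cvr_score(rf).total == table["cvr_total"].iloc[i]
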