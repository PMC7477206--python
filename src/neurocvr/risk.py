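"""Rule-based cerebrovascular risk (CVR) scoring.

The score is the sum of binary/graded risk components: measured
hypertension (both readings at or above 140/90 mmHg), use of
antihypertensive medication, use of cholesterol-lowering medication,
diagnosed diabetes, waist-to-hip ratio above the WHO sex-specific cut-off,
a 0-2 point smoking-history band based on pack-years, and a 0-2 point APOE
band counting epsilon-4 alleles.  Totals range 0-9.

Two equivalent routes are provided: scalar functions over a
:class:`RiskFactors` record (the definitional API) and a vectorised
:func:`score_cohort` over a cohort table.  A property test asserts their
agreement on random records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .schema import APOE_ALLELES, SMOKING_STATUSES

__all__ = [
    "Thresholds",
    "RiskFactors",
    "CvrBreakdown",
    "MissingDataError",
    "mean_bp",
    "is_hypertensive",
    "whr_exceeds_threshold",
    "pack_years",
    "smoking_points",
    "apoe_points",
    "cvr_score",
    "score_cohort",
]


class MissingDataError(ValueError):
    """Raised when a required field is absent or empty."""


@dataclass(frozen=True)
class Thresholds:
    """Clinical cut-offs, inclusive at the boundary.

    The 140/90 mmHg hypertension threshold follows NICE guidance; the
    waist-to-hip cut-offs are the WHO (2008) values of 0.90 for men and
    0.85 for women; the pack-year band [10, 50] scores one point and
    > 50 scores two.
    """

    sbp: float = 140.0
    dbp: float = 90.0
    whr_male: float = 0.90
    whr_female: float = 0.85
    pack_years_low: float = 10.0
    pack_years_high: float = 50.0


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class RiskFactors:
    """Raw risk-factor fields for one participant.

    ``None`` marks a missing field.  ``cigarettes_per_day`` is only
    available for participants who smoked on most or all days;
    ``age_stopped_smoking`` is absent for current smokers.
    """

    sbp_readings: Optional[Sequence[float]] = None
    dbp_readings: Optional[Sequence[float]] = None
    on_bp_medication: Optional[bool] = None
    on_cholesterol_medication: Optional[bool] = None
    diabetic: Optional[bool] = None
    sex: Optional[str] = None
    waist_cm: Optional[float] = None
    hip_cm: Optional[float] = None
    smoking_status: Optional[str] = None
    cigarettes_per_day: Optional[float] = None
    age_started_smoking: Optional[float] = None
    age_stopped_smoking: Optional[float] = None
    age_at_scan: Optional[float] = None
    apoe_genotype: Optional[str] = None


@dataclass(frozen=True)
class CvrBreakdown:
    """Per-component CVR breakdown; ``total`` is the component sum."""

    hypertensive_point: int = 0
    bp_med_point: int = 0
    chol_med_point: int = 0
    diabetes_point: int = 0
    whr_point: int = 0
    smoking_points: int = 0
    apoe_points: int = 0
    missing: tuple[str, ...] = field(default=())

    @property
    def total(self) -> int:
        return (
            self.hypertensive_point
            + self.bp_med_point
            + self.chol_med_point
            + self.diabetes_point
            + self.whr_point
            + self.smoking_points
            + self.apoe_points
        )


def mean_bp(readings: Sequence[float]) -> float:
    """Average blood pressure across readings taken moments apart.

    A single reading is returned unchanged; an empty list is missing data.
    """
    if readings is None or len(readings) == 0:
        raise MissingDataError("no blood pressure readings")
    return float(np.mean(readings))


def is_hypertensive(
    sbp: float, dbp: float, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Both the systolic and diastolic averages must reach 140/90 mmHg."""
    if sbp <= 0 or dbp <= 0:
        raise ValueError(f"non-positive blood pressure ({sbp}/{dbp})")
    return bool(sbp >= thresholds.sbp and dbp >= thresholds.dbp)


def whr_exceeds_threshold(
    waist_cm: float,
    hip_cm: float,
    sex: str,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Waist/hip ratio at or above the WHO sex-specific cut-off."""
    if hip_cm == 0:
        raise ZeroDivisionError("hip circumference is zero")
    if waist_cm <= 0 or hip_cm < 0:
        raise ValueError("circumferences must be positive")
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    cut = thresholds.whr_male if sex == "male" else thresholds.whr_female
    return bool(waist_cm / hip_cm >= cut)


def pack_years(
    cigs_per_day: float, age_started: float, age_end: float
) -> float:
    """(cigarettes/day / 20) x years smoked.

    ``age_end`` is the quit age for ex-smokers or the scan age for current
    smokers.  The exposure window ends at quit age, which is how quitting
    for more than six months enters the calculation; no additional
    multiplier is applied (the exact adjustment arithmetic is not
    specified anywhere authoritative, so none is silently invented).
    """
    if age_end < age_started:
        raise ValueError("smoking end age precedes start age")
    if cigs_per_day < 0:
        raise ValueError("negative cigarettes per day")
    return (cigs_per_day / 20.0) * (age_end - age_started)


def smoking_points(
    status: str,
    pack_years_value: Optional[float] = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> int:
    """0 for never-smokers or < 10 pack-years, 1 for [10, 50], 2 above 50.

    Ex-smokers without a cigarettes-per-day count (only collected for
    those who smoked most or all days) cannot accrue pack-years and score 0.
    """
    if status not in SMOKING_STATUSES:
        raise ValueError(f"unknown smoking status {status!r}")
    if status == "never" or pack_years_value is None:
        return 0
    if pack_years_value < 0:
        raise ValueError("negative pack-years")
    if pack_years_value > thresholds.pack_years_high:
        return 2
    if pack_years_value >= thresholds.pack_years_low:
        return 1
    return 0


_ALLELE_RE = re.compile(r"(?:e|ε|E)([234])")


def _parse_genotype(genotype: str) -> tuple[str, str]:
    alleles = _ALLELE_RE.findall(str(genotype))
    if len(alleles) != 2:
        raise ValueError(f"cannot parse APOE genotype {genotype!r}")
    pair = tuple(sorted(f"e{a}" for a in alleles))
    if any(a not in APOE_ALLELES for a in pair):
        raise ValueError(f"unknown APOE allele in {genotype!r}")
    return pair  # type: ignore[return-value]


def apoe_points(genotype: str) -> int:
    """Count of epsilon-4 alleles: 0, 1 (heterozygous) or 2 (homozygous)."""
    pair = _parse_genotype(genotype)
    return sum(1 for a in pair if a == "e4")


def _smoking_component(rf: RiskFactors, thresholds: Thresholds) -> Optional[int]:
    if rf.smoking_status is None:
        return None
    if rf.smoking_status == "never":
        return 0
    if rf.cigarettes_per_day is None or rf.age_started_smoking is None:
        # Smoked, but not on most/all days: no pack-year data collected.
        return 0
    if rf.smoking_status == "current":
        if rf.age_at_scan is None:
            return None
        end = rf.age_at_scan
    else:
        if rf.age_stopped_smoking is None:
            return None
        end = rf.age_stopped_smoking
    py = pack_years(rf.cigarettes_per_day, rf.age_started_smoking, end)
    return smoking_points(rf.smoking_status, py, thresholds)


def cvr_score(
    rf: RiskFactors,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    on_missing: str = "zero",
) -> CvrBreakdown:
    """Score one participant.

    Components whose fields are absent contribute 0 and are recorded in
    ``missing`` (sum-score convention); with ``on_missing='propagate'`` a
    :class:`MissingDataError` is raised instead.  If every component is
    missing the score is undefined and an error is always raised.

    Measured hypertension and antihypertensive use are independent
    components: a treated participant whose measured pressures still
    exceed 140/90 receives both points.
    """
    if on_missing not in ("zero", "propagate"):
        raise ValueError("on_missing must be 'zero' or 'propagate'")
    points: dict[str, int] = {}
    missing: list[str] = []

    def component(name: str, value: Optional[int]) -> None:
        if value is None:
            missing.append(name)
            points[name] = 0
        else:
            points[name] = int(value)

    hyp: Optional[int]
    try:
        if rf.sbp_readings is None or rf.dbp_readings is None:
            hyp = None
        else:
            hyp = int(
                is_hypertensive(
                    mean_bp(rf.sbp_readings), mean_bp(rf.dbp_readings), thresholds
                )
            )
    except MissingDataError:
        hyp = None
    component("hypertensive_point", hyp)
    component(
        "bp_med_point",
        None if rf.on_bp_medication is None else int(rf.on_bp_medication),
    )
    component(
        "chol_med_point",
        None
        if rf.on_cholesterol_medication is None
        else int(rf.on_cholesterol_medication),
    )
    component("diabetes_point", None if rf.diabetic is None else int(rf.diabetic))
    whr: Optional[int]
    if rf.waist_cm is None or rf.hip_cm is None or rf.sex is None:
        whr = None
    else:
        whr = int(whr_exceeds_threshold(rf.waist_cm, rf.hip_cm, rf.sex, thresholds))
    component("whr_point", whr)
    component("smoking_points", _smoking_component(rf, thresholds))
    component(
        "apoe_points",
        None if rf.apoe_genotype is None else apoe_points(rf.apoe_genotype),
    )

    if len(missing) == 7:
        raise MissingDataError("all CVR components missing; score undefined")
    if missing and on_missing == "propagate":
        raise MissingDataError(f"missing CVR components: {', '.join(missing)}")
    return CvrBreakdown(missing=tuple(missing), **points)


# ---------------------------------------------------------------------------
# Vectorised cohort scoring


def score_cohort(
    df: pd.DataFrame, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Vectorised CVR breakdown for a cohort table.

    Returns one row per participant with one column per component plus
    ``cvr_total``.  Missing fields contribute 0 (sum-score convention),
    matching :func:`cvr_score` with ``on_missing='zero'``.
    """
    n = len(df)
    out = pd.DataFrame(index=df.index)

    sbp = df[["sbp_1", "sbp_2"]].mean(axis=1)
    dbp = df[["dbp_1", "dbp_2"]].mean(axis=1)
    hyp = (sbp >= thresholds.sbp) & (dbp >= thresholds.dbp)
    out["hypertensive_point"] = hyp.fillna(False).astype(int)

    for col, name in (
        ("on_bp_medication", "bp_med_point"),
        ("on_cholesterol_medication", "chol_med_point"),
        ("diabetic", "diabetes_point"),
    ):
        out[name] = df[col].fillna(False).astype(bool).astype(int)

    whr = df["waist_cm"] / df["hip_cm"]
    cut = np.where(df["sex"].to_numpy() == "male", thresholds.whr_male, thresholds.whr_female)
    out["whr_point"] = (whr >= cut).fillna(False).astype(int)

    status = df["smoking_status"]
    end_age = np.where(
        status.to_numpy() == "current",
        df["age"].to_numpy(dtype=float),
        df["age_stopped_smoking"].to_numpy(dtype=float),
    )
    duration = end_age - df["age_started_smoking"].to_numpy(dtype=float)
    py = (df["cigarettes_per_day"].to_numpy(dtype=float) / 20.0) * duration
    pts = np.zeros(n)
    with np.errstate(invalid="ignore"):
        pts = np.where(py > thresholds.pack_years_high, 2, pts)
        pts = np.where(
            (py >= thresholds.pack_years_low) & (py <= thresholds.pack_years_high),
            1,
            pts,
        )
    pts = np.where(np.isnan(py) | (status.to_numpy() == "never"), 0, pts)
    out["smoking_points"] = pts.astype(int)

    geno = df["apoe_genotype"].fillna("")
    out["apoe_points"] = geno.str.count("4").astype(int)

    out["cvr_total"] = out.sum(axis=1)
    return out
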