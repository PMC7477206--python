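"""Trial filtering, robust normalisation and confound residualisation.

Cognitive trial series are filtered (reaction times kept within
[50, 2000] ms, inclusive) and summarised; analysis variables are median /
scaled-MAD normalised; total WMH volume is cube-root transformed before
normalisation; imaging phenotypes can be residualised against confounds by
ordinary least squares.  :func:`build_model_matrix` assembles the
standardised variable matrix consumed by the structural-equation and
window analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .schema import GM_COLUMNS, MODEL_COLUMNS, RT_TRIAL_COLUMNS

__all__ = [
    "RT_LOWER_MS",
    "RT_UPPER_MS",
    "MAD_CONSISTENCY",
    "DegenerateScaleError",
    "filter_rt_trials",
    "mean_rt",
    "mad_normalize",
    "cube_root_wmh",
    "residualize_confounds",
    "Normalizer",
    "summarize_cognition",
    "build_model_matrix",
]

#: Reaction-time exclusion boundaries, inclusive: responses faster than
#: 50 ms reflect anticipation; beyond 2000 ms the stimulus was gone.
RT_LOWER_MS = 50.0
RT_UPPER_MS = 2000.0

#: Normal-consistency constant for the median absolute deviation.
MAD_CONSISTENCY = 1.4826


class DegenerateScaleError(ValueError):
    """A variable has zero MAD and cannot be scale-normalised."""


def filter_rt_trials(
    trials: Sequence[float], lo: float = RT_LOWER_MS, hi: float = RT_UPPER_MS
) -> np.ndarray:
    """Keep trials with ``lo <= t <= hi``, preserving order."""
    t = np.asarray(trials, dtype=float)
    if t.size == 0:
        return t
    return t[(t >= lo) & (t <= hi)]


def mean_rt(trials: Sequence[float]) -> float:
    """Arithmetic mean of surviving trials; empty input is a missing score."""
    t = np.asarray(trials, dtype=float)
    if t.size == 0:
        raise ValueError("no trials survive filtering; reaction-time score missing")
    return float(t.mean())


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def mad_normalize(
    x: Sequence[float],
    consistency: float = MAD_CONSISTENCY,
    name: str = "variable",
) -> np.ndarray:
    """(x - median) / (consistency * MAD); output has median 0.

    Use ``consistency=1.0`` for the raw MAD.  NaNs are ignored when
    computing centre/scale and propagated in the output.
    """
    x = np.asarray(x, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size == 0:
        raise ValueError(f"{name}: no finite values")
    if not np.all(np.isfinite(finite)):
        raise ValueError(f"{name}: non-finite values present")
    mad = _mad(finite)
    if mad == 0:
        raise DegenerateScaleError(f"{name}: zero median absolute deviation")
    return (x - np.median(finite)) / (consistency * mad)


def cube_root_wmh(v):
    """Cube root of a non-negative lesion volume (mm^3); monotone."""
    v = np.asarray(v, dtype=float)
    if np.any(v[~np.isnan(v)] < 0):
        raise ValueError("negative WMH volume")
    out = np.cbrt(v)
    return float(out) if out.ndim == 0 else out


def residualize_confounds(
    Y, C, add_intercept: bool = True, rtol: float = 1e-10
) -> np.ndarray:
    """Regress every column of Y on the confound matrix C by least squares.

    An intercept is always included unless disabled, so residuals are
    centred and orthogonal to every confound column.  Idempotent.
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if Y.shape[0] != C.shape[0]:
        raise ValueError("Y and C row counts differ")
    X = np.column_stack([np.ones(C.shape[0]), C]) if add_intercept else C
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept = np.ones((X.shape[0], 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(j - 1 if add_intercept else j)
            else:
                kept = cand
        raise np.linalg.LinAlgError(
            f"confound matrix rank deficient; collinear columns {bad}"
        )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=rtol)
    resid = Y - X @ beta
    return resid[:, 0] if squeeze else resid


@dataclass
class Normalizer:
    """Per-variable centres/scales with the applied transforms, for a
    reproducibility sidecar (JSON)."""

    centers: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)
    transform_log: dict = field(default_factory=dict)
    consistency: float = MAD_CONSISTENCY

    def fit_transform(
        self, x: Sequence[float], name: str, transforms: tuple[str, ...] = ()
    ) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        log = list(transforms)
        if "cube_root" in transforms:
            x = cube_root_wmh(x)
        if "negate" in transforms:
            x = -x
        finite = x[~np.isnan(x)]
        if finite.size == 0:
            raise ValueError(f"{name}: no finite values")
        mad = _mad(finite)
        if mad == 0:
            raise DegenerateScaleError(f"{name}: zero median absolute deviation")
        center = float(np.median(finite))
        scale = float(self.consistency * mad)
        self.centers[name] = center
        self.scales[name] = scale
        self.transform_log[name] = log + ["mad_normalize"]
        return (x - center) / scale

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "centers": self.centers,
                    "scales": self.scales,
                    "transform_log": self.transform_log,
                    "consistency": self.consistency,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def summarize_cognition(df: pd.DataFrame) -> pd.DataFrame:
    """Per-participant filtered mean RT and pairs-matching errors.

    Pairs errors are used as recorded (no trial-level filter applies to a
    count).  Participants whose reaction-time trials are all excluded get
    a missing RT score.
    """
    trials = df[list(RT_TRIAL_COLUMNS)].to_numpy(dtype=float)
    keep = (trials >= RT_LOWER_MS) & (trials <= RT_UPPER_MS)
    counts = keep.sum(axis=1)
    sums = np.where(keep, trials, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mrt = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"mean_rt": mrt, "pairs_errors": df["pairs_errors"].to_numpy(dtype=float)},
        index=df.index,
    )


def build_model_matrix(
    df: pd.DataFrame,
    cvr_total: Optional[Sequence[float]] = None,
    normalizer: Optional[Normalizer] = None,
) -> tuple[pd.DataFrame, Normalizer]:
    """Assemble the standardised analysis matrix (``MODEL_COLUMNS`` order).

    Age, the CVR score, cube-root WMH load, the six frontoparietal
    grey-matter volumes, the SLF NODDI indices and the two cognitive
    summaries are each median/MAD normalised.  Reaction time and error
    counts are negated first so the executive-function latent is oriented
    "higher = better".
    """
    from .risk import score_cohort

    if cvr_total is None:
        cvr_total = score_cohort(df)["cvr_total"].to_numpy(dtype=float)
    norm = normalizer if normalizer is not None else Normalizer()
    cog = summarize_cognition(df)

    cols = {}
    cols["age"] = norm.fit_transform(df["age"], "age")
    cols["cvr"] = norm.fit_transform(np.asarray(cvr_total, dtype=float), "cvr")
    cols["wmh"] = norm.fit_transform(
        df["wmh_volume_mm3"], "wmh", transforms=("cube_root",)
    )
    for c in GM_COLUMNS:
        cols[c] = norm.fit_transform(df[c], c)
    cols["slf_icvf"] = norm.fit_transform(df["slf_icvf"], "slf_icvf")
    cols["slf_od"] = norm.fit_transform(df["slf_od"], "slf_od")
    cols["rt"] = norm.fit_transform(cog["mean_rt"], "rt", transforms=("negate",))
    cols["pairs"] = norm.fit_transform(
        cog["pairs_errors"], "pairs", transforms=("negate",)
    )
    mat = pd.DataFrame(cols, index=df.index)[list(MODEL_COLUMNS)]
    return mat, norm
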