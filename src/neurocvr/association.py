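"""Correlation and regression inference.

Pearson correlations with Fisher-z confidence intervals, the two-sample
Fisher r-to-z comparison used to contrast the medicated and unmedicated
strata, and multiple regression of the executive-function score on the
individual risk factors with variance-inflation-factor diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "pearson_ci",
    "fisher_rz_compare",
    "CorrelationComparison",
    "fit_regression",
    "RegressionTable",
    "SIGNIFICANCE_THRESHOLD",
]

#: Study-wide two-sided significance threshold.
SIGNIFICANCE_THRESHOLD = 1e-3


def pearson_ci(x, y, alpha: float = 0.05) -> Tuple[float, Tuple[float, float], float]:
    """Pearson r with a Fisher-z confidence interval and t-test p-value.

    CI: tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n-3)).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y are not aligned")
    n = x.size
    if n <= 3:
        raise ValueError("need n > 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0:  # degenerate: Fisher interval collapses
        return float(r), (float(r), float(r)), float(p)
    zc = stats.norm.ppf(1 - alpha / 2)
    z = np.arctanh(r)
    half = zc / np.sqrt(n - 3)
    return float(r), (float(np.tanh(z - half)), float(np.tanh(z + half))), float(p)


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z1: float
    z2: float
    z_stat: float
    p_two_sided: float


def fisher_rz_compare(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Compare two independent correlations after Fisher r-to-z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p-value.  Antisymmetric in the two groups.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise ValueError("|r| must be < 1 for the Fisher transform")
        if n <= 3:
            raise ValueError("need n > 3 in each group")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(
        r1=float(r1),
        n1=int(n1),
        r2=float(r2),
        n2=int(n2),
        z1=float(z1),
        z2=float(z2),
        z_stat=float(z),
        p_two_sided=float(p),
    )


@dataclass
class RegressionTable:
    """Per-predictor estimates and diagnostics plus the overall F test."""

    table: pd.DataFrame
    f_stat: float
    df_num: int
    df_den: int
    r_squared: float
    n_used: int

    def to_frame(self) -> pd.DataFrame:
        return self.table


def fit_regression(y, X: pd.DataFrame) -> RegressionTable:
    """OLS of ``y`` on the predictor table with an intercept.

    Rows with any missing value are dropped (listwise).  Standardised
    betas come from z-scoring y and each predictor; VIF_j is
    1/(1 - R^2_j) from the auxiliary regression of predictor j on the
    others.  Rank deficiency raises an error naming the collinear
    predictors.
    """
    X = pd.DataFrame(X).astype(float)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X[keep], y[keep]
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("too few complete rows")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(design.drop(columns=[c]).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear predictors: {bad}")
    res = sm.OLS(y, design).fit()
    sd_y = y.std(ddof=1)
    sd_x = X.std(ddof=1)
    arr = design.to_numpy()
    rows = []
    for j, c in enumerate(X.columns):
        rows.append(
            {
                "predictor": c,
                "beta": res.params[c],
                "se": res.bse[c],
                "std_beta": res.params[c] * sd_x[c] / sd_y,
                "t": res.tvalues[c],
                "p": res.pvalues[c],
                "vif": float(variance_inflation_factor(arr, j + 1)),
            }
        )
    table = pd.DataFrame(rows).set_index("predictor")
    return RegressionTable(
        table=table,
        f_stat=float(res.fvalue),
        df_num=int(res.df_model),
        df_den=int(res.df_resid),
        r_squared=float(res.rsquared),
        n_used=int(n),
    )
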