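"""Semi-partial correlation and bootstrap mediation.

These quantify how much of the association between white-matter lesion
load (or grey-matter volume) and executive function survives once a
second brain measure is controlled, and whether the grey-matter ->
executive-function relationship is mediated by white-matter integrity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

__all__ = ["semi_partial_corr", "mediate", "MediationResult"]


def _check_aligned(*arrays) -> list[np.ndarray]:
    out = [np.asarray(a, dtype=float).ravel() for a in arrays]
    n = out[0].size
    if any(a.size != n for a in out):
        raise ValueError("input vectors are not aligned")
    if any(not np.all(np.isfinite(a)) for a in out):
        raise ValueError("inputs must be finite (drop missing rows first)")
    return out


def _ols_residuals(x: np.ndarray, Z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(x)), Z])
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    return x - X @ beta


def semi_partial_corr(y, x, control) -> Tuple[float, float]:
    """Correlation between ``y`` and ``x`` with ``control`` residualised
    out of the predictor ``x`` only (semi-partial, not partial).

    Returns ``(r, p)`` with a two-sided t-test p-value.
    """
    y, x = _check_aligned(y, x)[:2]
    control = np.asarray(control, dtype=float)
    if control.ndim == 1:
        control = control[:, None]
    if control.shape[0] != y.size:
        raise ValueError("control not aligned with y/x")
    resid = _ols_residuals(x, control)
    if np.var(resid) < 1e-14 * max(np.var(x), 1e-30):
        raise ValueError("predictor fully collinear with control")
    r, p = stats.pearsonr(y, resid)
    return float(r), float(p)


@dataclass(frozen=True)
class MediationResult:
    """Least-squares path estimates with a percentile bootstrap CI for
    the indirect effect a*b (case resampling)."""

    a: float
    b: float
    c_total: float
    c_direct: float
    indirect: float
    boot_ci: Tuple[float, float]
    n_boot: int
    seed: int

    @property
    def proportion_mediated(self) -> float:
        return self.indirect / self.c_total if self.c_total != 0 else float("nan")


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Closed-form path coefficients: a from m~x; b, c' from y~x+m."""
    xc = x - x.mean()
    mc = m - m.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    a = (xc @ mc) / sxx
    c_total = (xc @ yc) / sxx
    # y ~ x + m via 2x2 normal equations
    smm = mc @ mc
    sxm = xc @ mc
    det = sxx * smm - sxm**2
    c_direct = (smm * (xc @ yc) - sxm * (mc @ yc)) / det
    b = (sxx * (mc @ yc) - sxm * (xc @ yc)) / det
    return a, b, c_total, c_direct


def mediate(x, m, y, n_boot: int = 10000, seed: Optional[int] = None,
            alpha: float = 0.05) -> MediationResult:
    """Simple mediation x -> m -> y with nonparametric bootstrap.

    ``a`` is the x->m slope, ``b`` the m->y slope controlling x,
    ``c_direct`` the x->y slope controlling m, ``c_total`` the marginal
    x->y slope; ``indirect = a*b``.  The CI is the percentile interval of
    the indirect effect over ``n_boot`` case resamples.  The seed is
    mandatory so that identical calls give identical intervals.
    """
    if seed is None:
        raise ValueError("a bootstrap seed is required for reproducibility")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x, m, y = _check_aligned(x, m, y)
    n = x.size
    if np.var(x) == 0 or np.var(m) == 0:
        raise ValueError("degenerate variance in x or m")
    det = np.var(x) * np.var(m) - np.cov(x, m, ddof=0)[0, 1] ** 2
    if det <= 1e-14 * np.var(x) * np.var(m):
        raise ValueError("x and m are collinear")
    a, b, c_total, c_direct = _paths(x, m, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ab = _paths(x[idx], m[idx], y[idx])
        boots[i] = ab[0] * ab[1]
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return MediationResult(
        a=float(a),
        b=float(b),
        c_total=float(c_total),
        c_direct=float(c_direct),
        indirect=float(a * b),
        boot_ci=(float(lo), float(hi)),
        n_boot=int(n_boot),
        seed=int(seed),
    )
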