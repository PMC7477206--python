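"""Model-free sliding-window association curves.

A window containing a fixed fraction of participants (default 10%) is
slid along the systolic-blood-pressure distribution in 1-percentile
steps; each window contributes the mean outcome, its standard error and
the window-median SBP.  A Gaussian kernel (sigma in window-index units)
smooths the curve.  Fixed-width binning (ten 16-mmHg systolic bins) and
quantile-bin age residualisation are provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "WindowCurve",
    "sliding_window_curve",
    "gaussian_smooth",
    "fixed_bin_curve",
    "age_quantile_residuals",
    "quantile_bin_assignments",
]


@dataclass(frozen=True)
class WindowCurve:
    """Ordered window centres with per-window mean, SEM and count."""

    centers: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    counts: np.ndarray
    parameter: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center": self.centers,
                "mean": self.means,
                "sem": self.sems,
                "count": self.counts,
            }
        )


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def sliding_window_curve(
    x, y, frac: float = 0.10, step_quantile: float = 0.01
) -> WindowCurve:
    """Quantile windows of width ``frac`` stepped by ``step_quantile``.

    At the defaults this yields 91 overlapping windows.  Ties in ``x``
    are broken by a stable sort on (x, original index).  Centres are the
    window-median x.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y are not aligned")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    n = x.size
    if not 0 < frac <= 1 or not 0 < step_quantile <= 1:
        raise ValueError("frac and step_quantile must lie in (0, 1]")
    w = int(round(frac * n))
    if w < 1 or n < 1 / frac:
        raise ValueError(f"need at least {int(np.ceil(1 / frac))} observations")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    centers, means, sems, counts = [], [], [], []
    k = 0
    while True:
        lo = int(np.floor(k * step_quantile * n))
        if lo + w > n:
            break
        win_y = ys[lo : lo + w]
        win_x = xs[lo : lo + w]
        centers.append(float(np.median(win_x)))
        means.append(float(win_y.mean()))
        sems.append(_sem(win_y))
        counts.append(w)
        k += 1
    return WindowCurve(
        centers=np.array(centers),
        means=np.array(means),
        sems=np.array(sems),
        counts=np.array(counts, dtype=int),
        parameter={"frac": frac, "step_quantile": step_quantile},
    )


def gaussian_smooth(values, kernel: float = 10.0, mode: str = "sigma") -> np.ndarray:
    """Moving-average smoothing with a normalised Gaussian kernel.

    ``kernel`` is the standard deviation in window-index units (or the
    FWHM with ``mode='fwhm'``).  Weights are renormalised at the edges so
    they always sum to one, hence a constant series is unchanged and the
    output never leaves [min(values), max(values)].
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        return v
    if kernel <= 0:
        raise ValueError("kernel must be positive")
    sigma = kernel / (2.0 * np.sqrt(2.0 * np.log(2.0))) if mode == "fwhm" else kernel
    half = int(np.ceil(4 * sigma))
    t = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (t / sigma) ** 2)
    # full convolution sliced to the input length: robust when the kernel
    # is longer than the series (np.convolve 'same' is not)
    num = np.convolve(v, w, mode="full")[half : half + v.size]
    den = np.convolve(np.ones_like(v), w, mode="full")[half : half + v.size]
    return num / den


def fixed_bin_curve(
    x, y, n_bins: int = 10, width: float = 16.0, origin: Optional[float] = None
) -> WindowCurve:
    """Fixed-width bins (default ten 16-mmHg systolic bins).

    The origin defaults to min(x) floored to a multiple of the width.
    Empty bins are flagged (NaN mean, zero count) and excluded from the
    curve arrays; the full bin table is in ``parameter['bins']``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y are not aligned")
    if width <= 0:
        raise ValueError("bin width must be positive")
    if origin is None:
        origin = np.floor(x.min() / width) * width
    edges = origin + width * np.arange(n_bins + 1)
    idx = np.digitize(x, edges) - 1
    centers, means, sems, counts, bins = [], [], [], [], []
    for b in range(n_bins):
        sel = idx == b
        c = int(sel.sum())
        center = float(origin + (b + 0.5) * width)
        bins.append(
            {
                "bin": b,
                "low": float(edges[b]),
                "high": float(edges[b + 1]),
                "count": c,
                "mean": float(y[sel].mean()) if c else float("nan"),
            }
        )
        if c == 0:
            continue
        centers.append(center)
        means.append(float(y[sel].mean()))
        sems.append(_sem(y[sel]))
        counts.append(c)
    return WindowCurve(
        centers=np.array(centers),
        means=np.array(means),
        sems=np.array(sems),
        counts=np.array(counts, dtype=int),
        parameter={"n_bins": n_bins, "width": width, "origin": float(origin), "bins": bins},
    )


def quantile_bin_assignments(age, n_bins: int = 10) -> np.ndarray:
    """Assign participants to age-quantile bins of near-equal size.

    Ties are broken by a stable sort on (age, original index), so bin
    sizes differ by at most one even with heavily tied ages.
    """
    age = np.asarray(age, dtype=float).ravel()
    n = age.size
    if n < n_bins:
        raise ValueError("fewer observations than bins")
    order = np.argsort(age, kind="stable")
    bins = np.empty(n, dtype=int)
    edges = (np.arange(n_bins + 1) * n) // n_bins
    for b in range(n_bins):
        bins[order[edges[b] : edges[b + 1]]] = b
    return bins


def age_quantile_residuals(v, age, n_bins: int = 10) -> np.ndarray:
    """Deconfound age by removing the age-quantile-bin mean from ``v``.

    Each bin's residual mean is zero, so correlating two residualised
    vectors is the bin-fixed-effects partial correlation.
    """
    v = np.asarray(v, dtype=float).ravel()
    bins = quantile_bin_assignments(age, n_bins)
    if v.size != bins.size:
        raise ValueError("v and age are not aligned")
    out = v.astype(float).copy()
    for b in range(n_bins):
        sel = bins == b
        out[sel] -= v[sel].mean()
    return out
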