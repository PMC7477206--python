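"""Maximum-likelihood fitting of structural-equation models.

The model is held in RAM form: an asymmetric matrix ``A`` of directed
coefficients (paths and loadings) and a symmetric matrix ``S`` of
variances/covariances over the stacked (observed + latent) variables.
The implied covariance of the observed block is

    Sigma = Fs (I - A)^-1 S (I - A)^-T Fs^T

with ``Fs`` the observed-variable selector.  Covariance-based ML
minimises the discrepancy

    F(S_n, Sigma) = log|Sigma| + tr(S_n Sigma^-1) - log|S_n| - p

with analytic gradients, quasi-Newton iterations and a Newton polish to
a tight gradient norm; chi-square is (n - 1) * F at the optimum.  The
sample covariance uses the ML (1/n) denominator so that full-information
ML (FIML) on complete data reproduces covariance-ML estimates exactly.
FIML evaluates the casewise Gaussian log-likelihood on each row's
observed subset (missing-at-random), with the saturated log-likelihood
obtained by EM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .spec import IdentificationError, ParamKey, SemModelSpec, model_df

__all__ = [
    "RamModel",
    "SemFit",
    "implied_covariance",
    "ml_discrepancy",
    "fit_sem",
    "standardize_solution",
    "fit_indices_from_chisq",
    "chi_square_difference",
    "factor_scores",
    "em_saturated",
    "ConvergenceError",
    "VARIANCE_FLOOR",
]

#: Lower bound applied to every variance parameter; an estimate resting on
#: this floor is a Heywood case and raises a warning, never a silent fix.
VARIANCE_FLOOR = 1e-6

GRADIENT_TOL = 1e-8


class ConvergenceError(RuntimeError):
    pass


class RamModel:
    """Index machinery mapping a spec's free-parameter vector into RAM
    matrices, with implied covariance and analytic ML gradients."""

    def __init__(self, spec: SemModelSpec):
        spec.validate()
        self.spec = spec
        self.var_names = spec.variables
        self.m = len(self.var_names)
        self.p = len(spec.observed)
        self.obs_idx = np.arange(self.p)  # observed come first in variables
        idx = {v: i for i, v in enumerate(self.var_names)}

        A0 = np.zeros((self.m, self.m))
        S0 = np.zeros((self.m, self.m))
        free_mat: list[str] = []
        free_i: list[int] = []
        free_j: list[int] = []
        free_keys: list[ParamKey] = []
        for key, fixed_value in spec.parameters():
            kind, a, b = key
            if kind == "loading":
                i, j = idx[b], idx[a]  # indicator <- latent
                mat = "A"
            elif kind == "path":
                i, j = idx[b], idx[a]  # target <- source
                mat = "A"
            elif kind in ("var", "cov"):
                i, j = idx[a], idx[b]
                mat = "S"
            else:  # pragma: no cover
                raise ValueError(f"unknown parameter kind {kind!r}")
            if fixed_value is None:
                free_mat.append(mat)
                free_i.append(i)
                free_j.append(j)
                free_keys.append(key)
            else:
                if mat == "A":
                    A0[i, j] = fixed_value
                else:
                    S0[i, j] = fixed_value
                    S0[j, i] = fixed_value
        self.A0, self.S0 = A0, S0
        self.free_mat = np.array(free_mat)
        self.free_i = np.array(free_i, dtype=int)
        self.free_j = np.array(free_j, dtype=int)
        self.free_keys: Tuple[ParamKey, ...] = tuple(free_keys)
        self.n_free = len(free_keys)
        self.is_variance = np.array(
            [k[0] == "var" for k in free_keys], dtype=bool
        )

    # -- assembly ---------------------------------------------------------------

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(
                f"theta has shape {theta.shape}, expected ({self.n_free},)"
            )
        if not np.all(np.isfinite(theta)):
            raise ValueError("non-finite parameter vector")
        A = self.A0.copy()
        S = self.S0.copy()
        a_mask = self.free_mat == "A"
        A[self.free_i[a_mask], self.free_j[a_mask]] = theta[a_mask]
        s_mask = ~a_mask
        S[self.free_i[s_mask], self.free_j[s_mask]] = theta[s_mask]
        S[self.free_j[s_mask], self.free_i[s_mask]] = theta[s_mask]
        return A, S

    def total_covariance(self, theta: np.ndarray) -> np.ndarray:
        """Implied covariance of the stacked observed + latent vector."""
        A, S = self.matrices(theta)
        B = np.linalg.inv(np.eye(self.m) - A)
        return B @ S @ B.T

    def implied_covariance(self, theta: np.ndarray) -> np.ndarray:
        C = self.total_covariance(theta)
        return C[: self.p, : self.p]

    # -- ML objective -----------------------------------------------------------

    def ml_value_and_grad(
        self, theta: np.ndarray, S_n: np.ndarray, logdet_S: float
    ) -> tuple[float, np.ndarray]:
        A, S = self.matrices(theta)
        I = np.eye(self.m)
        try:
            B = np.linalg.inv(I - A)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(self.n_free)
        C = B @ S @ B.T
        Sigma = C[: self.p, : self.p]
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(self.n_free)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        Sigma_inv = np.linalg.inv(Sigma)
        value = logdet + np.trace(S_n @ Sigma_inv) - logdet_S - self.p
        W = Sigma_inv - Sigma_inv @ S_n @ Sigma_inv
        P = np.zeros((self.m, self.m))
        P[: self.p, : self.p] = W
        PB = P @ B
        G = B.T @ PB  # gradient kernel for S-parameters
        M = C @ PB  # gradient kernel for A-parameters
        grad = np.empty(self.n_free)
        a_mask = self.free_mat == "A"
        grad[a_mask] = 2.0 * M[self.free_j[a_mask], self.free_i[a_mask]]
        s_mask = ~a_mask
        i, j = self.free_i[s_mask], self.free_j[s_mask]
        gs = G[i, j]
        grad[s_mask] = np.where(i == j, gs, 2.0 * gs)
        return float(value), grad

    # -- starting values --------------------------------------------------------

    def start_values(self, S_n: np.ndarray) -> np.ndarray:
        idx = {v: i for i, v in enumerate(self.var_names)}
        sd = np.sqrt(np.clip(np.diag(S_n), 1e-12, None))
        markers: dict[str, str] = {}
        for lat, inds in self.spec.latents:
            for ind in inds:
                if ("loading", lat, ind) in self.spec.fixed_map:
                    markers[lat] = ind
                    break
        theta = np.zeros(self.n_free)
        for k, key in enumerate(self.free_keys):
            kind, a, b = key
            if kind == "loading":
                ref = markers.get(a)
                if ref is not None:
                    theta[k] = 0.7 * sd[idx[b]] / max(sd[idx[ref]], 1e-8)
                else:
                    theta[k] = 0.7 * sd[idx[b]] if b in idx and idx[b] < self.p else 0.7
            elif kind == "path":
                theta[k] = 0.0
            elif kind == "var":
                i = idx[a]
                if i < self.p:
                    theta[k] = 0.5 * max(S_n[i, i], 1e-6)
                else:
                    ref = markers.get(a)
                    theta[k] = (
                        0.5 * max(S_n[idx[ref], idx[ref]], 1e-6)
                        if ref is not None
                        else 0.5
                    )
            else:  # cov
                i, j = idx[a], idx[b]
                indicator = set()
                for _, inds in self.spec.latents:
                    indicator.update(inds)
                exog_obs = (
                    i < self.p
                    and j < self.p
                    and a not in indicator
                    and b not in indicator
                )
                theta[k] = S_n[i, j] if exog_obs else 0.0
        return theta


def implied_covariance(spec: SemModelSpec, theta: Sequence[float]) -> np.ndarray:
    """Model-implied covariance of the observed variables at ``theta``.

    ``theta`` follows the spec's free-parameter order; fixed parameters
    come from the spec itself.
    """
    return RamModel(spec).implied_covariance(np.asarray(theta, dtype=float))


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """F = log|Sigma| + tr(S Sigma^-1) - log|S| - p; zero iff S == Sigma."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape or S.shape[0] != S.shape[1]:
        raise ValueError("S and Sigma must be square and conformable")
    p = S.shape[0]
    try:
        Ls = np.linalg.cholesky(S)
        Lm = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("S and Sigma must be positive definite") from exc
    logdet_S = 2.0 * np.sum(np.log(np.diag(Ls)))
    logdet_M = 2.0 * np.sum(np.log(np.diag(Lm)))
    return float(logdet_M + np.trace(S @ np.linalg.inv(Sigma)) - logdet_S - p)


# -- fit container --------------------------------------------------------------


@dataclass
class SemFit:
    """Converged model fit: raw and standardised estimates, standard
    errors, likelihood, chi-square against the saturated model, and
    incremental/absolute fit indices."""

    spec: SemModelSpec
    estimator: str
    theta: np.ndarray
    names: Tuple[ParamKey, ...]
    se: np.ndarray
    standardized: dict
    loglik: float
    chisq: float
    df: int
    n_used: int
    fit_indices: dict
    converged: bool
    gradient_norm: float
    heywood: Tuple[ParamKey, ...] = ()
    means: Optional[np.ndarray] = None

    def param(self, key: ParamKey) -> float:
        try:
            return float(self.theta[self.names.index(key)])
        except ValueError:
            fixed = self.spec.fixed_map
            if key in fixed:
                return float(fixed[key])
            raise KeyError(key)

    def std(self, key: ParamKey) -> float:
        return float(self.standardized[key])

    def params_table(self) -> pd.DataFrame:
        rows = []
        fixed = self.spec.fixed_map
        for k, (key, fv) in enumerate(self.spec.parameters()):
            if fv is None:
                i = self.names.index(key)
                est, se, free = self.theta[i], self.se[i], True
            else:
                est, se, free = fv, np.nan, False
            rows.append(
                {
                    "kind": key[0],
                    "lhs": key[1],
                    "rhs": key[2],
                    "free": free,
                    "estimate": est,
                    "se": se,
                    "standardized": self.standardized.get(key, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "n_used": int(self.n_used),
            "converged": bool(self.converged),
            "gradient_norm": float(self.gradient_norm),
            "loglik": float(self.loglik),
            "chisq": float(self.chisq),
            "df": int(self.df),
            "fit_indices": {k: float(v) for k, v in self.fit_indices.items()},
            "estimates": {
                "/".join(k): float(v) for k, v in zip(self.names, self.theta)
            },
            "se": {"/".join(k): float(v) for k, v in zip(self.names, self.se)},
            "standardized": {
                "/".join(k): float(v) for k, v in self.standardized.items()
            },
            "heywood": ["/".join(k) for k in self.heywood],
        }


# -- standardisation ------------------------------------------------------------


def standardize_solution(
    spec: SemModelSpec, theta: np.ndarray, model: Optional[RamModel] = None
) -> dict:
    """Standardised estimates for every parameter (free and fixed).

    Paths and loadings are scaled by implied SD(source)/SD(target);
    covariances become correlations; variances become the fraction of the
    target variance that is residual.
    """
    model = model if model is not None else RamModel(spec)
    C = model.total_covariance(np.asarray(theta, dtype=float))
    sd = np.sqrt(np.diag(C))
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        raise ValueError("zero or non-finite implied variance; cannot standardise")
    idx = {v: i for i, v in enumerate(model.var_names)}
    A, S = model.matrices(np.asarray(theta, dtype=float))
    out: dict[ParamKey, float] = {}
    for key, fixed_value in spec.parameters():
        kind, a, b = key
        if kind in ("loading", "path"):
            src, dst = idx[a], idx[b]
            value = A[dst, src]
            out[key] = value * sd[src] / sd[dst]
        elif kind == "var":
            i = idx[a]
            out[key] = S[i, i] / C[i, i]
        else:
            i, j = idx[a], idx[b]
            out[key] = S[i, j] / (sd[i] * sd[j])
    return out


# -- fit indices ----------------------------------------------------------------


def fit_indices_from_chisq(
    chisq_m: float, df_m: int, chisq_b: float, df_b: int, n: int
) -> dict:
    """CFI, TLI and RMSEA from model and baseline chi-squares.

    CFI and TLI are clipped to [0, 1] for reporting; RMSEA is flagged
    undefined (NaN) when the model has zero degrees of freedom.
    """
    num = max(chisq_m - df_m, 0.0)
    den = max(chisq_b - df_b, chisq_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    if df_b > 0 and df_m > 0 and chisq_b / df_b != 1.0:
        tli = (chisq_b / df_b - chisq_m / df_m) / (chisq_b / df_b - 1.0)
    else:
        tli = 1.0
    if df_m > 0:
        rmsea = float(np.sqrt(max(chisq_m - df_m, 0.0) / (df_m * (n - 1))))
    else:
        rmsea = float("nan")
    return {
        "CFI": float(np.clip(cfi, 0.0, 1.0)),
        "TLI": float(np.clip(tli, 0.0, 1.0)),
        "RMSEA": rmsea,
    }


def _baseline_chisq_ml(S_n: np.ndarray, n: int) -> tuple[float, int]:
    """Independence-model chi-square: its ML solution is diag(S) exactly."""
    p = S_n.shape[0]
    sign, logdet_S = np.linalg.slogdet(S_n)
    if sign <= 0:
        raise ValueError("sample covariance not positive definite")
    F0 = float(np.sum(np.log(np.diag(S_n))) - logdet_S)
    return (n - 1) * F0, p * (p - 1) // 2


# -- the fitter -----------------------------------------------------------------


def _scale_factors(model: RamModel, sd_obs: np.ndarray) -> np.ndarray:
    """Per-free-parameter multipliers mapping correlation-scale estimates
    back to the raw data scale.

    Observed variables carry their sample SD; a latent carries the SD of
    the indicator its scale is pinned to (fixed loading), or 1 when its
    variance is fixed instead.
    """
    spec = model.spec
    s: dict[str, float] = {
        v: float(sd_obs[i]) for i, v in enumerate(spec.observed)
    }
    fixed = spec.fixed_map
    for lat, inds in spec.latents:
        marker = next(
            (ind for ind in inds if ("loading", lat, ind) in fixed), None
        )
        s[lat] = s[marker] if marker is not None else 1.0
    factors = np.empty(model.n_free)
    for k, (kind, a, b) in enumerate(model.free_keys):
        if kind == "loading":
            factors[k] = s[b] / s[a]
        elif kind == "path":
            factors[k] = s[b] / s[a]
        elif kind == "var":
            factors[k] = s[a] ** 2
        else:
            factors[k] = s[a] * s[b]
    return factors


def _prepare_data(
    data: Union[pd.DataFrame, np.ndarray, tuple], spec: SemModelSpec
) -> tuple[Optional[np.ndarray], np.ndarray, int]:
    """Return (row matrix or None, ML sample covariance, n)."""
    if isinstance(data, tuple):
        S_n, n = data
        return None, np.asarray(S_n, dtype=float), int(n)
    if isinstance(data, pd.DataFrame):
        X = data[list(spec.observed)].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if X.shape[1] != len(spec.observed):
            raise ValueError("data column count does not match spec.observed")
    complete = X[~np.isnan(X).any(axis=1)]
    n = complete.shape[0]
    if n < len(spec.observed) + 2:
        raise ValueError("too few complete rows for covariance estimation")
    S_n = np.cov(complete, rowvar=False, ddof=0)
    return X, S_n, n


def _newton_polish(
    fun_grad, theta: np.ndarray, bounds_low: np.ndarray, max_iter: int = 25
) -> tuple[np.ndarray, float, np.ndarray]:
    """Newton iterations on the analytic gradient to drive its norm down
    to GRADIENT_TOL; Hessian by central differences of the gradient."""
    value, grad = fun_grad(theta)
    for _ in range(max_iter):
        gnorm = np.linalg.norm(grad)
        if gnorm < GRADIENT_TOL:
            break
        H = _hessian_from_grad(fun_grad, theta)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(len(theta)), grad)
        except np.linalg.LinAlgError:
            break
        improved = False
        for scale in (1.0, 0.5, 0.25, 0.1, 0.01):
            cand = np.maximum(theta - scale * step, bounds_low)
            v, g = fun_grad(cand)
            if np.isfinite(v) and (
                v < value or np.linalg.norm(g) < np.linalg.norm(grad)
            ):
                theta, value, grad = cand, v, g
                improved = True
                break
        if not improved:
            break
    return theta, value, grad


def _hessian_from_grad(fun_grad, theta: np.ndarray) -> np.ndarray:
    k = len(theta)
    H = np.zeros((k, k))
    for i in range(k):
        h = 1e-5 * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        H[:, i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def fit_sem(
    data,
    spec: SemModelSpec,
    estimator: str = "ML",
    n_starts: int = 3,
    compute_se: bool = True,
    baseline: bool = True,
    seed: int = 0,
) -> SemFit:
    """Fit ``spec`` to ``data`` by ML on the sample covariance or by FIML.

    ``data`` may be a DataFrame containing the spec's observed columns, a
    plain row matrix, or a ``(covariance, n)`` tuple (ML only).  Rows with
    missing values are dropped for ML (listwise) and used casewise by
    FIML.  Restarts with jittered starting values are attempted on
    non-convergence; a persistent failure raises :class:`ConvergenceError`.
    """
    estimator = estimator.upper()
    if estimator not in ("ML", "FIML"):
        raise ValueError("estimator must be 'ML' or 'FIML'")
    spec.validate()
    for lat, _ in spec.latents:
        if not spec.scale_is_set(lat):
            raise IdentificationError(
                f"latent {lat!r} has no scale: fix a loading or its variance"
            )
    if estimator == "FIML":
        return _fit_fiml(data, spec, n_starts, compute_se, baseline, seed)

    model = RamModel(spec)
    X, S_raw, n = _prepare_data(data, spec)
    sign, _ = np.linalg.slogdet(S_raw)
    if sign <= 0:
        raise ValueError("sample covariance not positive definite")
    # optimise on the correlation scale for conditioning; estimates are
    # mapped back to the raw scale afterwards (F and chi-square invariant)
    sd_obs = np.sqrt(np.diag(S_raw))
    S_n = S_raw / np.outer(sd_obs, sd_obs)
    logdet_S = float(np.linalg.slogdet(S_n)[1])
    scale_back = _scale_factors(model, sd_obs)

    def fun_grad(theta):
        return model.ml_value_and_grad(theta, S_n, logdet_S)

    bounds_low = np.where(model.is_variance, VARIANCE_FLOOR, -np.inf)
    bounds = list(zip(bounds_low, np.full(model.n_free, np.inf)))
    rng = np.random.default_rng(seed)
    theta0 = model.start_values(S_n)
    best = None
    for attempt in range(max(1, n_starts)):
        start = theta0 if attempt == 0 else theta0 * (
            1 + 0.3 * rng.standard_normal(model.n_free)
        ) + 0.1 * rng.standard_normal(model.n_free)
        start = np.maximum(start, bounds_low + 1e-8)
        res = optimize.minimize(
            fun_grad,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10},
        )
        theta, value, grad = _newton_polish(fun_grad, res.x, bounds_low)
        gnorm = float(np.linalg.norm(grad))
        if not np.isfinite(value):
            continue
        if best is None or value < best[1]:
            best = (theta, value, gnorm)
        if gnorm < GRADIENT_TOL:
            best = (theta, value, gnorm)
            break
    if best is None:
        raise ConvergenceError(
            f"ML objective non-finite at every start ({n_starts} attempts)"
        )
    theta, value, gnorm = best
    converged = bool(np.isfinite(value) and gnorm < 1e-5)
    if not converged:
        raise ConvergenceError(
            f"ML fit did not converge after {n_starts} starts "
            f"(gradient norm {gnorm:.3g})"
        )

    heywood = tuple(
        key
        for k, key in enumerate(model.free_keys)
        if model.is_variance[k] and theta[k] <= VARIANCE_FLOOR * 1.01
    )
    if heywood:
        warnings.warn(
            f"Heywood case: variance(s) at lower bound for {heywood}",
            RuntimeWarning,
        )

    df = model_df(spec)
    chisq = max((n - 1) * value, 0.0)

    se = np.full(model.n_free, np.nan)
    if compute_se:
        H = _hessian_from_grad(fun_grad, theta)
        try:
            cov_theta = np.linalg.inv(0.5 * (n - 1) * H)
            d = np.diag(cov_theta)
            se = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            pass

    # back to the raw data scale
    theta = theta * scale_back
    se = se * scale_back
    Sigma_raw = model.implied_covariance(theta)
    loglik = -0.5 * n * (
        model.p * np.log(2 * np.pi)
        + float(np.linalg.slogdet(Sigma_raw)[1])
        + float(np.trace(S_raw @ np.linalg.inv(Sigma_raw)))
    )

    indices: dict = {}
    if baseline and df > 0:
        chisq_b, df_b = _baseline_chisq_ml(S_n, n)
        indices = fit_indices_from_chisq(chisq, df, chisq_b, df_b, n)
    elif df == 0:
        indices = {"CFI": 1.0, "TLI": 1.0, "RMSEA": float("nan")}

    return SemFit(
        spec=spec,
        estimator="ML",
        theta=theta,
        names=model.free_keys,
        se=se,
        standardized=standardize_solution(spec, theta, model),
        loglik=float(loglik),
        chisq=float(chisq),
        df=df,
        n_used=n,
        fit_indices=indices,
        converged=converged,
        gradient_norm=gnorm,
        heywood=heywood,
    )


# -- FIML -----------------------------------------------------------------------


def _pattern_groups(X: np.ndarray):
    """Group rows by missingness pattern; every row must observe >= 1 var."""
    mask = ~np.isnan(X)
    if not mask.any(axis=1).all():
        raise ValueError("rows with no observed variables cannot enter FIML")
    keys = [tuple(row) for row in mask]
    groups: dict[tuple, list[int]] = {}
    for r, k in enumerate(keys):
        groups.setdefault(k, []).append(r)
    return [
        (np.flatnonzero(np.array(k)), X[np.array(rows)][:, np.array(k, bool)])
        for k, rows in groups.items()
    ]


def _fiml_loglik(groups, mu: np.ndarray, Sigma: np.ndarray) -> float:
    ll = 0.0
    for obs, rows in groups:
        k = len(obs)
        sub = Sigma[np.ix_(obs, obs)]
        try:
            L = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return -np.inf
        dev = rows - mu[obs]
        sol = np.linalg.solve(L, dev.T)
        quad = np.sum(sol**2)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        ll += -0.5 * (rows.shape[0] * (k * np.log(2 * np.pi) + logdet) + quad)
    return float(ll)


def em_saturated(
    X: np.ndarray, max_iter: int = 500, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, float]:
    """EM estimates of the unstructured mean/covariance under MAR, and the
    saturated log-likelihood."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    mu = np.nanmean(X, axis=0)
    Sigma = np.diag(np.nanvar(X, axis=0) + 1e-6)
    groups_full = []
    mask = ~np.isnan(X)
    keys = [tuple(row) for row in mask]
    gm: dict[tuple, list[int]] = {}
    for r, k in enumerate(keys):
        gm.setdefault(k, []).append(r)
    for k, rows in gm.items():
        obs = np.flatnonzero(np.array(k))
        mis = np.flatnonzero(~np.array(k))
        groups_full.append((obs, mis, X[np.array(rows)][:, obs]))
    ll_prev = -np.inf
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for obs, mis, rows in groups_full:
            m = rows.shape[0]
            Soo = Sigma[np.ix_(obs, obs)]
            Soo_inv = np.linalg.inv(Soo)
            dev = rows - mu[obs]
            if len(mis):
                Smo = Sigma[np.ix_(mis, obs)]
                reg = Smo @ Soo_inv
                x_mis = mu[mis] + dev @ reg.T
                cond = Sigma[np.ix_(mis, mis)] - reg @ Smo.T
            full = np.zeros((m, p))
            full[:, obs] = rows
            if len(mis):
                full[:, mis] = x_mis
            sum_x += full.sum(axis=0)
            sum_xx += full.T @ full
            if len(mis):
                sum_xx[np.ix_(mis, mis)] += m * cond
        mu = sum_x / n
        Sigma = sum_xx / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        groups = [(obs, rows) for obs, mis, rows in groups_full]
        ll = _fiml_loglik(groups, mu, Sigma)
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            ll_prev = ll
            break
        ll_prev = ll
    return mu, Sigma, float(ll_prev)


def _fit_fiml(data, spec, n_starts, compute_se, baseline, seed) -> SemFit:
    model = RamModel(spec)
    if isinstance(data, tuple):
        raise ValueError("FIML needs row-level data, not a covariance matrix")
    if isinstance(data, pd.DataFrame):
        X = data[list(spec.observed)].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
    keep = ~np.isnan(X).all(axis=1)
    X = X[keep]
    n = X.shape[0]
    p = model.p
    groups = _pattern_groups(X)

    def unpack(vec):
        return vec[: model.n_free], vec[model.n_free :]

    BIG = 1e12  # finite penalty keeps finite-difference gradients usable

    def neg_loglik(vec):
        theta, mu = unpack(vec)
        try:
            Sigma = model.implied_covariance(theta)
        except ValueError:
            return BIG
        ll = _fiml_loglik(groups, mu, Sigma)
        return -ll if np.isfinite(ll) else BIG

    # start from listwise ML when possible
    complete = X[~np.isnan(X).any(axis=1)]
    mu0 = np.nanmean(X, axis=0)
    if complete.shape[0] >= p + 5:
        try:
            ml_fit = fit_sem(
                complete, spec, estimator="ML", compute_se=False, baseline=False
            )
            theta0 = ml_fit.theta
        except (ConvergenceError, ValueError):
            theta0 = model.start_values(np.cov(complete, rowvar=False, ddof=0))
    else:
        theta0 = model.start_values(np.diag(np.nanvar(X, axis=0)))
    bounds_low = np.concatenate(
        [np.where(model.is_variance, VARIANCE_FLOOR, -np.inf), np.full(p, -np.inf)]
    )
    bounds = list(zip(bounds_low, np.full(model.n_free + p, np.inf)))
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max(1, n_starts)):
        theta_start = theta0 if attempt == 0 else theta0 * (
            1 + 0.3 * rng.standard_normal(model.n_free)
        )
        start = np.concatenate([np.maximum(theta_start, bounds_low[: model.n_free] + 1e-8), mu0])
        res = optimize.minimize(
            neg_loglik,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 4000, "ftol": 1e-13},
        )
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x, gnorm, res.success)
        if res.success:
            break
    assert best is not None
    fmin, vec, gnorm, success = best
    if not np.isfinite(fmin) or fmin >= 1e12:
        raise ConvergenceError("FIML optimisation failed")
    theta, mu = unpack(vec)

    heywood = tuple(
        key
        for k, key in enumerate(model.free_keys)
        if model.is_variance[k] and theta[k] <= VARIANCE_FLOOR * 1.01
    )
    if heywood:
        warnings.warn(
            f"Heywood case: variance(s) at lower bound for {heywood}",
            RuntimeWarning,
        )

    loglik = -float(fmin)
    _, _, ll_sat = em_saturated(X)
    chisq = max(2.0 * (ll_sat - loglik), 0.0)
    df = model_df(spec)

    se = np.full(model.n_free, np.nan)
    if compute_se:
        try:
            H = _numeric_hessian(neg_loglik, vec)
            cov_all = np.linalg.inv(H)
            d = np.diag(cov_all)[: model.n_free]
            se = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            pass

    indices: dict = {}
    if baseline and df > 0:
        # independence baseline under MAR: per-variable Gaussian MLEs
        ll_indep = 0.0
        for j in range(p):
            xj = X[:, j]
            xj = xj[~np.isnan(xj)]
            v = xj.var()
            ll_indep += -0.5 * len(xj) * (np.log(2 * np.pi * v) + 1.0)
        chisq_b = max(2.0 * (ll_sat - ll_indep), 0.0)
        indices = fit_indices_from_chisq(chisq, df, chisq_b, p * (p - 1) // 2, n)
    elif df == 0:
        indices = {"CFI": 1.0, "TLI": 1.0, "RMSEA": float("nan")}

    return SemFit(
        spec=spec,
        estimator="FIML",
        theta=theta,
        names=model.free_keys,
        se=se,
        standardized=standardize_solution(spec, theta, model),
        loglik=loglik,
        chisq=float(chisq),
        df=df,
        n_used=n,
        fit_indices=indices,
        converged=bool(success or gnorm < 1e-4),
        gradient_norm=gnorm,
        heywood=heywood,
        means=mu,
    )


def _numeric_hessian(fun, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = fun(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += steps[i]; xpp[j] += steps[j]
            xpm = x.copy(); xpm[i] += steps[i]; xpm[j] -= steps[j]
            xmp = x.copy(); xmp[i] -= steps[i]; xmp[j] += steps[j]
            xmm = x.copy(); xmm[i] -= steps[i]; xmm[j] -= steps[j]
            H[i, j] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                4 * steps[i] * steps[j]
            )
            H[j, i] = H[i, j]
    return H


# -- model comparison ------------------------------------------------------------


@dataclass(frozen=True)
class ChiSquareDifference:
    delta_chisq: float
    delta_df: int
    p_value: float


def chi_square_difference(full: SemFit, nested: SemFit) -> ChiSquareDifference:
    """Likelihood-ratio comparison of nested fits.

    The nested model's free parameters must be a subset of the full
    model's.  A (numerically) negative difference is clipped to zero with
    a warning.
    """
    full_free = set(full.spec.free_keys())
    nested_free = set(nested.spec.free_keys())
    if not nested_free <= full_free:
        raise ValueError("models are not nested (free parameters not a subset)")
    delta_df = nested.df - full.df
    if delta_df < 0:
        raise ValueError("nested model has fewer degrees of freedom than full")
    delta = nested.chisq - full.chisq
    if delta < 0:
        warnings.warn(
            f"negative chi-square difference ({delta:.3g}) clipped to zero",
            RuntimeWarning,
        )
        delta = 0.0
    p = float(stats.chi2.sf(delta, delta_df)) if delta_df > 0 else 1.0
    return ChiSquareDifference(float(delta), int(delta_df), p)


# -- factor scores ---------------------------------------------------------------


def factor_scores(fit: SemFit, data: pd.DataFrame) -> pd.DataFrame:
    """Regression-method factor scores from a fitted model.

    Scores are conditional expectations of the latents given each row's
    observed variables (so rows with missing entries are scored on their
    observed subset).
    """
    model = RamModel(fit.spec)
    C = model.total_covariance(fit.theta)
    p = model.p
    lat_idx = np.arange(p, model.m)
    X = data[list(fit.spec.observed)].to_numpy(dtype=float)
    mu = fit.means if fit.means is not None else np.nanmean(X, axis=0)
    out = np.full((X.shape[0], len(lat_idx)), np.nan)
    mask = ~np.isnan(X)
    keys = [tuple(r) for r in mask]
    gm: dict[tuple, list[int]] = {}
    for r, k in enumerate(keys):
        gm.setdefault(k, []).append(r)
    for k, rows in gm.items():
        obs = np.flatnonzero(np.array(k))
        if len(obs) == 0:
            continue
        rows = np.array(rows)
        Coo = C[np.ix_(obs, obs)]
        Clo = C[np.ix_(lat_idx, obs)]
        w = Clo @ np.linalg.inv(Coo)
        out[rows] = (X[np.ix_(rows, obs)] - mu[obs]) @ w.T
    return pd.DataFrame(out, index=data.index, columns=list(model.spec.latent_names))
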