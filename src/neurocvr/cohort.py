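"""Synthetic ageing-cohort generator.

Generates UK-Biobank-like per-participant raw fields (two blood-pressure
readings, medication flags, smoking history, anthropometry, APOE
genotype, WMH volume, six frontoparietal grey-matter volumes, SLF NODDI
indices, 12 reaction-time trials and pairs-matching errors) whose joint
distribution follows the standardised structural ground truth: age and
the rule-based CVR score drive WMH load, which together drive the
grey-matter and white-matter-integrity latents, which drive executive
function.  The CVR score entering the structural equations is the actual
rule-based score computed from the generated raw risk factors, so risk
scoring sits inside the generative loop.

Raw-scale mappings are chosen so the analysis pipeline's transforms
recover linear indicators: WMH is generated on the cube of a Gaussian
(cube root normalises it exactly), reaction-time trials are log-normal
around a participant mean that is linear in the latent score (with the
trial-level noise budgeted inside the indicator uniqueness so the
standardised loading is exactly the target), and pairs errors follow a
Poisson-gamma count law with the overdispersion budgeted the same way.

A direct blood-pressure channel into executive function reproduces the
sliding-window patterns (graded decline off medication; a plateau below
140 mmHg on medication).  It is driven by the SBP component
orthogonalised against age, the measured-hypertension point and the
medication flag, so it lands entirely in the executive-function residual
and leaves every structural path exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .risk import score_cohort
from .schema import ALL_COLUMNS, GM_COLUMNS, MODEL_COLUMNS, RT_TRIAL_COLUMNS
from .sem.spec import DEFAULT_CORRELATED_RESIDUALS, LATENT_INDICATORS, SemModelSpec

__all__ = [
    "GeneratorParams",
    "default_params",
    "preset",
    "generate_cohort",
    "ground_truth",
    "structural_residual_variances",
    "inject_missingness",
    "calibrate_age_link",
]

#: Shared probit slope on standardised age for the medication, diabetes
#: and smoking assignments, calibrated once (deterministic 2e6-draw
#: simulation, see :func:`calibrate_age_link`) so that the population
#: correlation between age and the rule-based CVR score is 0.25.
AGE_LINK_SLOPE = 0.1943056508  # frozen calibration output (corr 0.2500)

#: Population mean/SD of the CVR total score under default parameters at
#: the calibrated slope (same frozen run); used to standardise the score
#: inside the structural equations.
SCORE_MEAN = 1.537426
SCORE_SD = 1.104091

#: Relative weight of the age link per component (smoking status is a
#: lifetime exposure, only weakly age-graded in this 44-73 band).
AGE_LINK_WEIGHTS = {"bp_med": 1.0, "chol_med": 1.0, "diabetes": 1.0, "smoker": 0.3}

#: Loading of the underlying SBP residual on the medication probit
#: (treatment tracks established hypertension, not age alone).
MED_SBP_LOADING = 0.5

_STRUCTURAL_ORDER = ("age", "cvr", "wmh", "gm", "wm", "ef")

DEFAULT_STRUCTURAL: Dict[Tuple[str, str], float] = {
    ("age", "wmh"): 0.35,
    ("cvr", "wmh"): 0.13,
    ("age", "gm"): -0.45,
    ("cvr", "gm"): -0.07,
    ("wmh", "gm"): -0.10,
    ("age", "wm"): -0.35,
    ("cvr", "wm"): -0.01,
    ("wmh", "wm"): -0.20,
    ("gm", "ef"): 0.32,
    ("wm", "ef"): 0.34,
}

DEFAULT_LOADINGS: Dict[str, float] = {
    "gm_angular_gyrus": 0.7,
    "gm_precuneus": 0.7,
    "gm_cingulate_gyrus": 0.7,
    "gm_superior_frontal_gyrus": 0.7,
    "gm_frontal_pole": 0.7,
    "gm_middle_temporal_gyrus": 0.7,
    "slf_icvf": 0.8,
    "slf_od": -0.8,
    "rt": 0.49,
    "pairs": 0.25,
}

#: Raw scales (mean, SD) for the imaging indicators, mm^3 for volumes.
GM_SCALES = {
    "gm_angular_gyrus": (11000.0, 1300.0),
    "gm_precuneus": (13500.0, 1500.0),
    "gm_cingulate_gyrus": (9500.0, 1100.0),
    "gm_superior_frontal_gyrus": (21000.0, 2300.0),
    "gm_frontal_pole": (15500.0, 1700.0),
    "gm_middle_temporal_gyrus": (17500.0, 1900.0),
}
NODDI_SCALES = {"slf_icvf": (0.52, 0.035), "slf_od": (0.47, 0.030)}


@dataclass(frozen=True)
class GeneratorParams:
    """All generator knobs, with study-condition defaults.

    Structural coefficients are standardised; loadings are standardised
    indicator loadings; prevalences are marginal probabilities enforced
    exactly through probit thresholds.
    """

    n: int = 22059
    age_mean: float = 62.0
    age_sd: float = 7.0
    age_range: Tuple[float, float] = (44.0, 73.0)
    female_fraction: float = 0.515
    genotype_probs: Tuple[Tuple[str, float], ...] = (
        ("e3/e3", 0.76),
        ("e3/e4", 0.17),
        ("e2/e4", 0.02),
        ("e4/e4", 0.01),
        ("e2/e3", 0.035),
        ("e2/e2", 0.005),
    )
    prevalence: Tuple[Tuple[str, float], ...] = (
        ("diabetes", 0.05),
        ("chol_med", 0.21),
        ("bp_med", 0.22),
        ("smoker", 0.22),  # 78% never-smokers
    )
    structural: Tuple[Tuple[Tuple[str, str], float], ...] = tuple(
        DEFAULT_STRUCTURAL.items()
    )
    age_cvr_cov: float = 0.25
    loadings: Tuple[Tuple[str, float], ...] = tuple(DEFAULT_LOADINGS.items())
    gm_residual_cov: float = 0.15
    correlated_residuals: Tuple[Tuple[str, str], ...] = DEFAULT_CORRELATED_RESIDUALS
    # blood pressure (mmHg)
    sbp_mean: float = 137.0
    sbp_age_slope: float = 7.0
    sbp_resid_sd: float = 13.0
    dbp_mean: float = 82.0
    dbp_age_slope: float = 1.5
    dbp_resid_sd: float = 9.0
    dbp_sbp_corr: float = 0.55
    reading_noise_sd: float = 4.0
    # direct SBP -> EF channel (sliding-window phenomenology)
    sbp_ef_strength_untreated: float = 0.16
    sbp_ef_strength_treated: float = 0.10
    sbp_plateau: float = 140.0
    # reaction-time task (ms)
    rt_mean: float = 555.0
    rt_sd: float = 90.0
    rt_trial_sigma: float = 0.18
    rt_frac_anticipation: float = 0.02
    rt_frac_lapse: float = 0.012
    # pairs-matching errors
    pairs_mean: float = 4.0
    pairs_overdispersion: float = 0.5
    # WMH cube-root scale
    wmh_cbrt_mean: float = 15.0
    wmh_cbrt_sd: float = 3.8
    missing_rate: float = 0.0

    @property
    def structural_map(self) -> Dict[Tuple[str, str], float]:
        return dict(self.structural)

    @property
    def loading_map(self) -> Dict[str, float]:
        return dict(self.loadings)

    @property
    def prevalence_map(self) -> Dict[str, float]:
        return dict(self.prevalence)

    def validate(self) -> None:
        probs = dict(self.genotype_probs)
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("genotype probabilities must sum to 1")
        if any(not 0 <= p <= 1 for p in probs.values()):
            raise ValueError("genotype probabilities must lie in [0, 1]")
        if any(not 0 < p < 1 for p in self.prevalence_map.values()):
            raise ValueError("prevalences must lie in (0, 1)")
        if any(abs(v) >= 1 for v in self.structural_map.values()):
            raise ValueError("standardised coefficients must satisfy |b| < 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


def default_params(n: int = 22059, **overrides) -> GeneratorParams:
    p = GeneratorParams(n=n, **overrides)
    p.validate()
    return p


def preset(name: str) -> GeneratorParams:
    """Fixture presets: ``tiny`` (n=200), ``default`` (n=22,059) and
    ``recovery`` (n=20,000)."""
    sizes = {"tiny": 200, "default": 22059, "recovery": 20000}
    if name not in sizes:
        raise KeyError(f"unknown preset {name!r}")
    return default_params(sizes[name])


# -- age ------------------------------------------------------------------------


def _truncnorm_params(
    mean: float, sd: float, lo: float, hi: float
) -> Tuple[float, float]:
    """Parent (mu, sigma) whose truncation to [lo, hi] has the target
    post-truncation mean and SD (plain truncation would undershoot)."""

    def eqs(p):
        mu, sg = p
        a, b = (lo - mu) / sg, (hi - mu) / sg
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sg, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, msg = optimize.fsolve(
        eqs, [mean + 2.0, sd * 1.3], full_output=True
    )
    if ier != 1 or max(abs(np.asarray(eqs(sol)))) > 1e-8:
        raise ValueError(f"age calibration failed: {msg}")
    return float(sol[0]), float(sol[1])


_AGE_CACHE: dict = {}


def _sample_age(params: GeneratorParams, n: int, rng) -> np.ndarray:
    key = (params.age_mean, params.age_sd, params.age_range)
    if key not in _AGE_CACHE:
        _AGE_CACHE[key] = _truncnorm_params(
            params.age_mean, params.age_sd, *params.age_range
        )
    mu, sg = _AGE_CACHE[key]
    lo, hi = params.age_range
    a, b = (lo - mu) / sg, (hi - mu) / sg
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sg, size=n, random_state=rng)


# -- risk factors ----------------------------------------------------------------


def _probit_flag(rng, n, prevalence, slopes_and_drivers) -> np.ndarray:
    """Bernoulli flag from a probit with exact marginal prevalence.

    ``slopes_and_drivers`` is a list of (slope, standard-normal driver);
    the threshold is scaled by the total latent SD so the marginal
    probability equals ``prevalence`` regardless of the slopes.
    """
    latent = rng.standard_normal(n)
    total_var = 1.0
    for slope, driver in slopes_and_drivers:
        latent = latent + slope * driver
        total_var += slope**2
    thr = stats.norm.ppf(1 - prevalence) * np.sqrt(total_var)
    return latent > thr


def _generate_risk_factors(
    params: GeneratorParams,
    z_age: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    rng,
    gamma: float = AGE_LINK_SLOPE,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Raw risk-factor fields; returns (frame, sbp_true) where
    ``sbp_true`` is the underlying systolic pressure before reading
    noise (used by the direct BP -> EF channel)."""
    n = len(z_age)
    prev = params.prevalence_map
    out = pd.DataFrame(index=pd.RangeIndex(n))

    eps_s = rng.standard_normal(n)
    sbp_true = params.sbp_mean + params.sbp_age_slope * z_age + params.sbp_resid_sd * eps_s
    rho = params.dbp_sbp_corr
    dbp_true = (
        params.dbp_mean
        + params.dbp_age_slope * z_age
        + params.dbp_resid_sd * (rho * eps_s + np.sqrt(1 - rho**2) * rng.standard_normal(n))
    )
    for i in (1, 2):
        out[f"sbp_{i}"] = sbp_true + params.reading_noise_sd * rng.standard_normal(n)
        out[f"dbp_{i}"] = dbp_true + params.reading_noise_sd * rng.standard_normal(n)

    w = AGE_LINK_WEIGHTS
    out["on_bp_medication"] = _probit_flag(
        rng, n, prev["bp_med"], [(gamma * w["bp_med"], z_age), (MED_SBP_LOADING, eps_s)]
    )
    out["on_cholesterol_medication"] = _probit_flag(
        rng, n, prev["chol_med"], [(gamma * w["chol_med"], z_age)]
    )
    out["diabetic"] = _probit_flag(
        rng, n, prev["diabetes"], [(gamma * w["diabetes"], z_age)]
    )

    ever = _probit_flag(rng, n, prev["smoker"], [(gamma * w["smoker"], z_age)])
    current = ever & (rng.random(n) < 0.30)
    status = np.where(current, "current", np.where(ever, "ex", "never"))
    out["smoking_status"] = status
    most_days = ever & (rng.random(n) < 0.80)
    cigs = np.round(np.clip(rng.lognormal(np.log(15.0), 0.5, n), 1, 60))
    out["cigarettes_per_day"] = np.where(most_days, cigs, np.nan)
    started = np.clip(np.round(rng.normal(17.0, 3.0, n)), 12, 35)
    started = np.minimum(started, np.floor(age) - 1)
    out["age_started_smoking"] = np.where(ever, started, np.nan)
    quit_frac = rng.beta(2.0, 2.0, n)
    stopped = np.round(started + quit_frac * (age - started))
    out["age_stopped_smoking"] = np.where(ever & ~current, stopped, np.nan)

    u1 = rng.standard_normal(n)
    u2 = rng.standard_normal(n)
    male = sex == "male"
    waist = np.where(
        male,
        97.0 + 1.5 * z_age + 10.5 * u1,
        85.0 + 1.5 * z_age + 12.0 * u1,
    )
    hip_shared = 0.7 * u1 + np.sqrt(1 - 0.7**2) * u2
    hip = np.where(male, 103.0 + 7.0 * hip_shared, 103.0 + 10.0 * hip_shared)
    out["waist_cm"] = np.clip(waist, 55.0, None)
    out["hip_cm"] = np.clip(hip, 65.0, None)

    genos, probs = zip(*params.genotype_probs)
    out["apoe_genotype"] = rng.choice(genos, size=n, p=probs)
    return out, sbp_true


# -- structural algebra ----------------------------------------------------------


def structural_residual_variances(
    structural: Dict[Tuple[str, str], float], age_cvr_cov: float
) -> Dict[str, float]:
    """Residual variances making every structural variable unit-variance.

    Solved sequentially in causal order while accumulating the implied
    covariance among structural variables; a non-positive residual means
    the requested coefficients are jointly inadmissible (non-PD).
    """
    order = _STRUCTURAL_ORDER
    idx = {v: i for i, v in enumerate(order)}
    C = np.eye(len(order))
    C[0, 1] = C[1, 0] = age_cvr_cov
    resid: Dict[str, float] = {}
    for v in order[2:]:
        preds = [(s, c) for (s, d), c in structural.items() if d == v]
        b = np.zeros(len(order))
        for s, c in preds:
            b[idx[s]] = c
        var_lin = float(b @ C @ b)
        r = 1.0 - var_lin
        if r <= 0:
            raise ValueError(
                f"structural coefficients for {v!r} imply non-positive "
                f"residual variance ({r:.4f}); covariance block not PD"
            )
        resid[v] = r
        row = C @ b
        C[idx[v], :] = row
        C[:, idx[v]] = row
        C[idx[v], idx[v]] = 1.0
    return resid


def ground_truth(
    params: Optional[GeneratorParams] = None,
) -> tuple[SemModelSpec, np.ndarray]:
    """The exact structural specification and parameter vector used by
    :func:`generate_cohort`, in the standardised (unit-variance)
    parameterisation with every parameter free.

    ``implied_covariance(spec, theta)`` is the population correlation
    matrix of the model variables; positive-definiteness is checked.
    """
    from .sem.fit import RamModel

    params = params or default_params()
    params.validate()
    struct = params.structural_map
    loadings = params.loading_map
    resid = structural_residual_variances(struct, params.age_cvr_cov)

    spec = SemModelSpec.create(
        observed=MODEL_COLUMNS,
        latents=LATENT_INDICATORS,
        paths=tuple(struct.keys()),
        covariances=(("age", "cvr"),),
        correlated_residuals=params.correlated_residuals,
    )
    values: Dict[tuple, float] = {}
    for lat, inds in LATENT_INDICATORS.items():
        for ind in inds:
            values[("loading", lat, ind)] = loadings[ind]
    for key, b in struct.items():
        values[("path", key[0], key[1])] = b
    values[("var", "age", "age")] = 1.0
    values[("var", "cvr", "cvr")] = 1.0
    for v in ("wmh", "gm", "wm", "ef"):
        values[("var", v, v)] = resid[v]
    for lat, inds in LATENT_INDICATORS.items():
        for ind in inds:
            values[("var", ind, ind)] = 1.0 - loadings[ind] ** 2
    values[("cov", "age", "cvr")] = params.age_cvr_cov
    for a, b in params.correlated_residuals:
        values[("cov", a, b)] = params.gm_residual_cov

    theta = np.array([values[k] for k in spec.free_keys()])
    model = RamModel(spec)
    Sigma = model.implied_covariance(theta)
    try:
        np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "ground-truth implied covariance not positive definite; "
            "check structural coefficients, loadings and residual covariances"
        ) from exc
    return spec, theta


# -- cognitive indicator calibration ----------------------------------------------


def _rt_unique_sd(params: GeneratorParams, lam: float) -> float:
    """Between-person unique SD (z-units) so the standardised loading of
    the filtered mean RT equals ``lam`` exactly after the trial-level
    log-normal noise and contamination filtering take their share."""
    n_tr = len(RT_TRIAL_COLUMNS)
    pc = params.rt_frac_anticipation + params.rt_frac_lapse
    k = np.arange(1, n_tr + 1)
    pmf = stats.binom.pmf(k, n_tr, 1 - pc)
    e_inv_k = float(np.sum(pmf / k) / np.sum(pmf))
    q = (np.exp(params.rt_trial_sigma**2) - 1.0) * e_inv_k
    mu_ratio = (params.rt_mean / params.rt_sd) ** 2
    total = (1.0 - mu_ratio * q) / (1.0 + q)
    c2 = total - lam**2
    if c2 <= 0:
        raise ValueError(
            "reaction-time trial noise exceeds the uniqueness budget; "
            "reduce rt_trial_sigma or the loading"
        )
    return float(np.sqrt(c2))


def _pairs_scale(params: GeneratorParams, lam: float) -> float:
    """Count-scale SD such that the standardised loading of the pairs
    error count is ``lam`` under the Poisson-gamma law."""
    mu0, phi = params.pairs_mean, params.pairs_overdispersion
    denom = 1.0 - lam**2 * (1.0 + phi)
    if denom <= 0:
        raise ValueError("pairs loading incompatible with overdispersion")
    return float(np.sqrt((phi * mu0**2 + mu0) / denom))


# -- main entry -------------------------------------------------------------------


def generate_cohort(
    params: Optional[GeneratorParams] = None, seed: Optional[int] = None
) -> pd.DataFrame:
    """Generate a cohort table (schema ``ALL_COLUMNS``), reproducibly.

    The seed is mandatory.  Categorical prevalences match the parameters
    within binomial error; fitting the full structural model to the
    derived standardised matrix recovers the ground-truth standardised
    coefficients.
    """
    if seed is None:
        raise ValueError("a seed is required")
    params = params or default_params()
    params.validate()
    n = params.n
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in ALL_COLUMNS})
    rng = np.random.default_rng(seed)

    age = _sample_age(params, n, rng)
    z_age = (age - params.age_mean) / params.age_sd
    sex = np.where(rng.random(n) < params.female_fraction, "female", "male")
    townsend = np.clip(rng.normal(-1.4, 2.9, n), -6.3, 10.5)

    risk, sbp_true = _generate_risk_factors(params, z_age, age, sex, rng)
    df = pd.DataFrame({"age": age, "sex": sex, "townsend": townsend})
    df = pd.concat([df, risk], axis=1)

    breakdown = score_cohort(df)
    z_cvr = (breakdown["cvr_total"].to_numpy(dtype=float) - SCORE_MEAN) / SCORE_SD

    struct = params.structural_map
    resid = structural_residual_variances(struct, params.age_cvr_cov)

    def draw(v: str, preds: Dict[str, np.ndarray]) -> np.ndarray:
        lin = np.zeros(n)
        for (s, d), c in struct.items():
            if d == v:
                lin = lin + c * preds[s]
        return lin + np.sqrt(resid[v]) * rng.standard_normal(n)

    env = {"age": z_age, "cvr": z_cvr}
    env["wmh"] = draw("wmh", env)
    env["gm"] = draw("gm", env)
    env["wm"] = draw("wm", env)

    # executive function: structural part + direct BP channel + noise
    lin_ef = struct[("gm", "ef")] * env["gm"] + struct[("wm", "ef")] * env["wm"]
    med = df["on_bp_medication"].to_numpy(dtype=bool)
    hyp = breakdown["hypertensive_point"].to_numpy(dtype=float)
    bp_term = _bp_ef_term(params, sbp_true, med, hyp, z_age)
    var_bp = float(np.var(bp_term))
    if var_bp >= resid["ef"]:
        raise ValueError("BP->EF channel exceeds the EF residual budget")
    ef = lin_ef + bp_term + np.sqrt(resid["ef"] - var_bp) * rng.standard_normal(n)
    env["ef"] = ef

    # imaging indicators
    loadings = params.loading_map
    U = np.eye(len(GM_COLUMNS))
    gidx = {g: i for i, g in enumerate(GM_COLUMNS)}
    for g in GM_COLUMNS:
        U[gidx[g], gidx[g]] = 1.0 - loadings[g] ** 2
    for a, b in params.correlated_residuals:
        U[gidx[a], gidx[b]] = U[gidx[b], gidx[a]] = params.gm_residual_cov
    Lu = np.linalg.cholesky(U)
    uniques = rng.standard_normal((n, len(GM_COLUMNS))) @ Lu.T
    for g in GM_COLUMNS:
        m, s = GM_SCALES[g]
        std = loadings[g] * env["gm"] + uniques[:, gidx[g]]
        df[g] = np.clip(m + s * std, 100.0, None)
    for nod, (m, s) in NODDI_SCALES.items():
        lam = loadings[nod]
        std = lam * env["wm"] + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        df[nod] = np.clip(m + s * std, 0.01, 0.99)

    cbrt = np.clip(
        params.wmh_cbrt_mean + params.wmh_cbrt_sd * env["wmh"], 0.5, None
    )
    df["wmh_volume_mm3"] = cbrt**3

    # reaction-time trials (ms), log-normal around a linear participant mean
    lam_rt = loadings["rt"]
    c_rt = _rt_unique_sd(params, lam_rt)
    t_mean = params.rt_mean + params.rt_sd * (
        -lam_rt * ef + c_rt * rng.standard_normal(n)
    )
    t_mean = np.clip(t_mean, 120.0, None)
    sig = params.rt_trial_sigma
    n_tr = len(RT_TRIAL_COLUMNS)
    trials = t_mean[:, None] * rng.lognormal(-0.5 * sig**2, sig, (n, n_tr))
    u = rng.random((n, n_tr))
    low = u < params.rt_frac_anticipation
    high = (u >= params.rt_frac_anticipation) & (
        u < params.rt_frac_anticipation + params.rt_frac_lapse
    )
    trials = np.where(low, rng.uniform(5.0, 49.0, (n, n_tr)), trials)
    trials = np.where(high, rng.uniform(2001.0, 3500.0, (n, n_tr)), trials)
    for j, col in enumerate(RT_TRIAL_COLUMNS):
        df[col] = trials[:, j]

    # pairs-matching errors: Poisson-gamma, mean linear in EF
    lam_p = loadings["pairs"]
    s_p = _pairs_scale(params, lam_p)
    phi = params.pairs_overdispersion
    mu_p = np.clip(params.pairs_mean - s_p * lam_p * ef, 0.05, None)
    frailty = rng.gamma(1.0 / phi, phi, n) if phi > 0 else 1.0
    df["pairs_errors"] = rng.poisson(mu_p * frailty)

    latents = pd.DataFrame(
        {k: env[k] for k in ("age", "cvr", "wmh", "gm", "wm", "ef")}
    )
    df = df[list(ALL_COLUMNS)]
    if params.missing_rate > 0:
        df = inject_missingness(
            df, params.missing_rate, seed=int(rng.integers(2**31))
        )
    df.attrs["provenance"] = {"seed": int(seed), "n": int(n)}
    # true standardised structural scores, for validation and testing
    df.attrs["latents"] = latents
    return df


def _bp_ef_term(
    params: GeneratorParams,
    sbp_true: np.ndarray,
    med: np.ndarray,
    hyp: np.ndarray,
    z_age: np.ndarray,
) -> np.ndarray:
    """Direct SBP -> EF contribution, orthogonalised against age, the
    measured-hypertension point and the medication flag so it cannot leak
    into any structural path."""
    n = len(sbp_true)
    d0 = params.sbp_ef_strength_untreated
    d1 = params.sbp_ef_strength_treated
    if d0 == 0 and d1 == 0:
        return np.zeros(n)
    term = np.zeros(n)
    unmed = ~med
    if unmed.any():
        shape = sbp_true[unmed]
        sd = shape.std()
        if sd > 0:
            term[unmed] = -d0 * (shape - shape.mean()) / sd
    if med.any():
        shape = np.maximum(sbp_true[med] - params.sbp_plateau, 0.0)
        sd = shape.std()
        if sd > 0:
            term[med] = -d1 * (shape - shape.mean()) / sd
    X = np.column_stack([np.ones(n), z_age, hyp, med.astype(float)])
    beta, *_ = np.linalg.lstsq(X, term, rcond=None)
    return term - X @ beta


# -- missingness ------------------------------------------------------------------

#: Columns eligible for MAR deletion (imaging and cognitive measures).
MISSINGNESS_COLUMNS = (
    ("wmh_volume_mm3",) + GM_COLUMNS + ("slf_icvf", "slf_od", "pairs_errors")
    + RT_TRIAL_COLUMNS
)


def inject_missingness(
    df: pd.DataFrame,
    rate: float,
    seed: Optional[int] = None,
    columns: Sequence[str] = MISSINGNESS_COLUMNS,
) -> pd.DataFrame:
    """Delete cells at random with probability increasing in observed age
    (missing-at-random), averaging ``rate`` per eligible column."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if seed is None:
        raise ValueError("a seed is required")
    out = df.copy()
    if rate == 0 or len(df) == 0:
        return out
    rng = np.random.default_rng(seed)
    z = (df["age"].to_numpy(dtype=float) - df["age"].mean()) / max(
        df["age"].std(), 1e-9
    )
    weight = np.exp(0.4 * z)
    p = np.clip(rate * weight / weight.mean(), 0.0, 0.95)
    for c in columns:
        mask = rng.random(len(df)) < p
        out.loc[mask, c] = np.nan
    return out


# -- calibration ------------------------------------------------------------------


def calibrate_age_link(
    target_corr: float = 0.25,
    n: int = 2_000_000,
    seed: int = 20240411,
    params: Optional[GeneratorParams] = None,
) -> dict:
    """Solve for the shared probit age slope giving the target population
    correlation between age and the CVR score (common-random-number
    simulation + Brent bracketing).  Returns the slope and the implied
    score mean/SD; the frozen module constants are one run of this."""
    params = params or default_params()

    def corr_at(gamma: float) -> tuple[float, float, float]:
        rng = np.random.default_rng(seed)
        age = _sample_age(params, n, rng)
        z_age = (age - params.age_mean) / params.age_sd
        sex = np.where(rng.random(n) < params.female_fraction, "female", "male")
        risk, _ = _generate_risk_factors(params, z_age, age, sex, rng, gamma=gamma)
        risk = risk.copy()
        risk["age"] = age
        risk["sex"] = sex
        total = score_cohort(risk)["cvr_total"].to_numpy(dtype=float)
        return (
            float(np.corrcoef(total, z_age)[0, 1]),
            float(total.mean()),
            float(total.std()),
        )

    gamma = optimize.brentq(
        lambda g: corr_at(g)[0] - target_corr, 0.0, 2.0, xtol=1e-4
    )
    corr, mean, sd = corr_at(gamma)
    return {
        "age_link_slope": float(gamma),
        "achieved_corr": corr,
        "score_mean": mean,
        "score_sd": sd,
    }
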