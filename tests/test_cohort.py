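"""Synthetic cohort generator: calibration, reproducibility, ground truth."""

import numpy as np
import pandas as pd
import pytest

from neurocvr.cohort import (
    default_params,
    generate_cohort,
    ground_truth,
    inject_missingness,
    preset,
    structural_residual_variances,
)
from neurocvr.preprocess import build_model_matrix
from neurocvr.schema import ALL_COLUMNS
from neurocvr.sem import implied_covariance


def test_bit_reproducibility():
    p = default_params(300)
    a = generate_cohort(p, seed=99)
    b = generate_cohort(p, seed=99)
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(p, seed=100)
    assert not a["age"].equals(c["age"])


def test_seed_is_mandatory():
    with pytest.raises(ValueError):
        generate_cohort(default_params(10))


def test_empty_cohort_keeps_schema():
    df = generate_cohort(default_params(0), seed=1)
    assert list(df.columns) == list(ALL_COLUMNS)
    assert len(df) == 0


def test_presets():
    assert preset("tiny").n == 200
    assert preset("default").n == 22059
    assert preset("recovery").n == 20000
    with pytest.raises(KeyError):
        preset("huge")


def test_age_calibration_hits_target_moments():
    df = generate_cohort(default_params(22059), seed=17)
    assert df["age"].mean() == pytest.approx(62.0, abs=0.1)
    assert df["age"].std() == pytest.approx(7.0, abs=0.1)
    assert df["age"].min() >= 44.0 and df["age"].max() <= 73.0


def test_structural_residuals_chain_oracle():
    # y <- x with coefficient b: residual must be 1 - b^2; downstream
    # variable z <- y with c: residual 1 - c^2 (y has unit variance)
    struct = {("age", "wmh"): 0.6, ("wmh", "gm"): 0.5, ("gm", "ef"): 0.3,
              ("cvr", "wmh"): 0.0, ("age", "gm"): 0.0, ("cvr", "gm"): 0.0,
              ("age", "wm"): 0.0, ("cvr", "wm"): 0.0, ("wmh", "wm"): 0.0,
              ("wm", "ef"): 0.0}
    resid = structural_residual_variances(struct, 0.0)
    assert resid["wmh"] == pytest.approx(1 - 0.36)
    assert resid["gm"] == pytest.approx(1 - 0.25)
    assert resid["ef"] == pytest.approx(1 - 0.09)


def test_structural_residuals_reject_inadmissible():
    struct = dict(default_params().structural)
    struct[("age", "wmh")] = 0.9
    struct[("cvr", "wmh")] = 0.9
    with pytest.raises(ValueError, match="non-positive"):
        structural_residual_variances(struct, 0.25)


def test_ground_truth_round_trip():
    params = default_params()
    spec, theta = ground_truth(params)
    keys = spec.free_keys()
    vals = dict(zip(keys, theta))
    for (src, dst), coef in params.structural:
        assert vals[("path", src, dst)] == pytest.approx(coef)
    assert vals[("cov", "age", "cvr")] == pytest.approx(0.25)
    Sigma = implied_covariance(spec, theta)
    assert np.all(np.linalg.eigvalsh(Sigma) > 0)
    np.testing.assert_allclose(np.diag(Sigma), 1.0, atol=1e-10)


def test_large_sample_covariance_matches_implied():
    """Law-of-large-numbers check: the correlation matrix of the derived
    model variables converges to the ground-truth implied covariance."""
    params = default_params(400000)
    spec, theta = ground_truth(params)
    Sigma = implied_covariance(spec, theta)
    df = generate_cohort(params, seed=8)
    mat, _ = build_model_matrix(df)
    R = np.corrcoef(mat.to_numpy(), rowvar=False)
    np.testing.assert_allclose(R, Sigma, atol=0.01)


def test_marginal_age_trends():
    df = generate_cohort(default_params(10000), seed=23)
    sbp = df[["sbp_1", "sbp_2"]].mean(axis=1)
    assert np.polyfit(df["age"], sbp, 1)[0] > 0  # SBP rises with age
    ef = df.attrs["latents"]["ef"]
    assert np.polyfit(df["age"], ef, 1)[0] < 0  # EF declines with age


def test_bp_ef_channel_plateau_for_medicated():
    df = generate_cohort(default_params(40000), seed=29)
    lat = df.attrs["latents"]
    sbp = df[["sbp_1", "sbp_2"]].mean(axis=1).to_numpy()
    ef = lat["ef"].to_numpy()
    med = df["on_bp_medication"].to_numpy(dtype=bool)
    # untreated stratum: graded negative association beyond the age effect
    from neurocvr.windows import age_quantile_residuals

    age = df["age"].to_numpy()
    r_un = np.corrcoef(
        age_quantile_residuals(sbp[~med], age[~med]),
        age_quantile_residuals(ef[~med], age[~med]),
    )[0, 1]
    assert r_un < -0.10
    # treated stratum: flat below the 140 mmHg plateau, declining above
    # (reading noise leaks a little of the above-plateau decline into the
    # measured-SBP<135 subset, so "flat" is near-zero rather than zero)
    low = med & (sbp < 135)
    high = med & (sbp > 145)
    r_low = np.corrcoef(sbp[low], ef[low])[0, 1]
    r_high = np.corrcoef(sbp[high], ef[high])[0, 1]
    assert abs(r_low) < 0.10
    assert r_high < r_low - 0.05


def test_missingness_rate_and_mar_mechanism():
    df = generate_cohort(default_params(8000), seed=41)
    out = inject_missingness(df, 0.2, seed=7)
    miss = out["wmh_volume_mm3"].isna()
    se = np.sqrt(0.2 * 0.8 / len(df))
    assert abs(miss.mean() - 0.2) < 3 * se + 0.01
    # probability increases with age (missing-at-random given age)
    assert df.loc[miss, "age"].mean() > df.loc[~miss, "age"].mean()
    # rate 0 leaves the table untouched
    pd.testing.assert_frame_equal(inject_missingness(df, 0.0, seed=7), df)
    with pytest.raises(ValueError):
        inject_missingness(df, 1.0, seed=7)


def test_missingness_reproducible():
    df = generate_cohort(default_params(500), seed=2)
    a = inject_missingness(df, 0.3, seed=5)
    b = inject_missingness(df, 0.3, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_recovery_unbiasedness_smoke():
    """Five seeded replicates at n = 20,000: the refitted standardised
    coefficients track the injected truth closely on average."""
    import neurocvr as nc

    spec = nc.build_structural_spec()
    p = default_params(20000)
    targets = {
        ("path", "cvr", "wmh"): 0.13,
        ("path", "wm", "ef"): 0.34,
        ("loading", "ef", "rt"): 0.49,
    }
    devs = {k: [] for k in targets}
    for seed in range(1000, 1005):
        df = generate_cohort(p, seed=seed)
        mat, _ = build_model_matrix(df)
        fit = nc.fit_sem(mat, spec, compute_se=False)
        for k, v in targets.items():
            devs[k].append(fit.std(k) - v)
    for k, d in devs.items():
        assert abs(np.mean(d)) < 0.015, (k, d)
        assert max(np.abs(d)) < 0.06, (k, d)
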