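"""Pearson/Fisher inference and the risk-factor regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neurocvr.association import fisher_rz_compare, fit_regression, pearson_ci


def test_pearson_perfect_linear(rng):
    x = rng.standard_normal(100)
    r, ci, p = pearson_ci(x, 2.0 * x)
    assert r == pytest.approx(1.0)


def test_pearson_ci_closed_form():
    # r = 0.5, n = 103: Fisher SE = 1/sqrt(100) = 0.1
    x = np.linspace(-1, 1, 103)
    # construct data with exactly r = 0.5 via Gram-Schmidt
    z = np.sin(17 * x)
    z = z - z.mean()
    z = z - (z @ (x - x.mean())) / ((x - x.mean()) @ (x - x.mean())) * (x - x.mean())
    xc = (x - x.mean()) / np.std(x)
    zc = z / np.std(z)
    y = 0.5 * xc + np.sqrt(1 - 0.25) * zc
    r, ci, p = pearson_ci(x, y)
    assert r == pytest.approx(0.5, abs=1e-12)
    assert ci[0] == pytest.approx(0.339, abs=2e-3)
    assert ci[1] == pytest.approx(0.632, abs=2e-3)


def test_pearson_independent_pairs_small_r(rng):
    x = rng.standard_normal(10000)
    y = rng.standard_normal(10000)
    r, _, _ = pearson_ci(x, y)
    assert abs(r) < 0.05


def test_pearson_rejects_constant(rng):
    with pytest.raises(ValueError):
        pearson_ci(np.ones(10), rng.standard_normal(10))


def test_fisher_equal_correlations():
    c = fisher_rz_compare(0.3, 500, 0.3, 700)
    assert c.z_stat == 0.0
    assert c.p_two_sided == pytest.approx(1.0)


def test_fisher_closed_form_example():
    # independent recomputation: (atanh(.3) - atanh(.1)) / sqrt(2/100)
    c = fisher_rz_compare(0.3, 103, 0.1, 103)
    expected = (np.arctanh(0.3) - np.arctanh(0.1)) / np.sqrt(2.0 / 100.0)
    assert c.z_stat == pytest.approx(expected, abs=1e-12)
    assert c.z_stat == pytest.approx(1.479, abs=1e-3)


def test_fisher_rejects_degenerate():
    with pytest.raises(ValueError):
        fisher_rz_compare(1.0, 100, 0.5, 100)


@given(
    st.floats(-0.95, 0.95),
    st.floats(-0.95, 0.95),
    st.integers(10, 10000),
    st.integers(10, 10000),
)
def test_fisher_antisymmetric(r1, r2, n1, n2):
    a = fisher_rz_compare(r1, n1, r2, n2)
    b = fisher_rz_compare(r2, n2, r1, n1)
    assert a.z_stat == pytest.approx(-b.z_stat, abs=1e-12)


def test_regression_matches_normal_equations_oracle(rng):
    n = 50
    X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
    y = 1.0 + 0.5 * X["a"] - 0.3 * X["b"] + rng.standard_normal(n)
    res = fit_regression(y, X)
    D = np.column_stack([np.ones(n), X.to_numpy()])
    beta = np.linalg.solve(D.T @ D, D.T @ y.to_numpy())
    np.testing.assert_allclose(res.table["beta"].to_numpy(), beta[1:], atol=1e-10)
    assert res.df_num == 3


def test_vif_of_orthogonal_design():
    n = 64
    base = np.array([[1, 1], [1, -1]])
    H = base
    while H.shape[0] < n:
        H = np.kron(H, base)
    X = pd.DataFrame(H[:n, 1:4].astype(float), columns=["h1", "h2", "h3"])
    y = X["h1"] + np.sin(np.arange(n))
    res = fit_regression(y, X)
    np.testing.assert_allclose(res.table["vif"].to_numpy(), 1.0, atol=1e-10)


def test_standardised_betas_scale_invariant(rng):
    n = 200
    X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
    y = 0.4 * X["a"] - 0.2 * X["c"] + rng.standard_normal(n)
    base = fit_regression(y, X)
    X2 = X.copy()
    X2["a"] = X2["a"] * 1000.0 + 5.0
    X2["c"] = X2["c"] * 0.001
    rescaled = fit_regression(y, X2)
    np.testing.assert_allclose(
        rescaled.table["std_beta"].to_numpy(),
        base.table["std_beta"].to_numpy(),
        atol=1e-10,
    )


def test_regression_rank_deficiency_named(rng):
    X = pd.DataFrame(rng.standard_normal((40, 2)), columns=["a", "b"])
    X["c"] = 2.0 * X["a"]
    with pytest.raises(ValueError, match="collinear"):
        fit_regression(rng.standard_normal(40), X)


def test_age_dominates_risk_factor_regression():
    """On generator cohorts the executive-function score declines with age
    and age carries the largest standardised coefficient."""
    from neurocvr.cohort import default_params, generate_cohort
    from neurocvr.pipeline import REGRESSION_COVARIATES
    from neurocvr.preprocess import build_model_matrix
    from neurocvr.sem import build_structural_spec, factor_scores, fit_sem

    df = generate_cohort(default_params(8000), seed=31)
    mat, _ = build_model_matrix(df)
    fit = fit_sem(mat, build_structural_spec(), compute_se=False)
    ef = factor_scores(fit, mat)["ef"]
    X = pd.DataFrame(
        {
            "whr": df["waist_cm"] / df["hip_cm"],
            "smoking_code": df["smoking_status"].map(
                {"never": 0, "ex": 1, "current": 2}
            ),
            "on_cholesterol_medication": df["on_cholesterol_medication"].astype(float),
            "on_bp_medication": df["on_bp_medication"].astype(float),
            "diabetic": df["diabetic"].astype(float),
            "apoe_points": df["apoe_genotype"].str.count("4").astype(float),
            "age": df["age"],
            "townsend": df["townsend"],
        }
    )
    res = fit_regression(ef, X[list(REGRESSION_COVARIATES)])
    assert res.df_num == 8
    std = res.table["std_beta"]
    assert std["age"] < 0
    assert std.abs().idxmax() == "age"
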