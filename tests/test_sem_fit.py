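"""ML/FIML estimation: closed-form oracles, gradients, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from neurocvr.cohort import default_params, generate_cohort
from neurocvr.preprocess import build_model_matrix
from neurocvr.sem import (
    RamModel,
    SemModelSpec,
    build_structural_spec,
    chi_square_difference,
    constrain_variable_paths,
    factor_scores,
    fit_indices_from_chisq,
    fit_sem,
    implied_covariance,
    ml_discrepancy,
)


# -- implied covariance ----------------------------------------------------------


def test_implied_single_variable():
    spec = SemModelSpec.create(observed=("x",))
    assert implied_covariance(spec, [2.0]) == pytest.approx(np.array([[2.0]]))


def test_implied_simple_regression_closed_form():
    spec = SemModelSpec.create(observed=("x", "y"), paths=(("x", "y"),))
    # free order: path, var(x), var(y)
    Sigma = implied_covariance(spec, [0.5, 1.0, 0.75])
    assert Sigma[0, 0] == pytest.approx(1.0)
    assert Sigma[0, 1] == pytest.approx(0.5)
    assert Sigma[1, 1] == pytest.approx(0.5**2 + 0.75)


def test_implied_one_factor_closed_form():
    lam, phi = 0.8, 1.3
    theta_u = np.array([0.4, 0.5])
    spec = SemModelSpec.create(
        observed=("a", "b"),
        latents={"f": ["a", "b"]},
        fixed={("loading", "f", "a"): 1.0, ("var", "f", "f"): phi},
    )
    # free: loading f->b, var a, var b
    Sigma = implied_covariance(spec, [lam, theta_u[0], theta_u[1]])
    lam_vec = np.array([1.0, lam])
    expected = phi * np.outer(lam_vec, lam_vec) + np.diag(theta_u)
    np.testing.assert_allclose(Sigma, expected, atol=1e-12)


# -- discrepancy -----------------------------------------------------------------


def test_ml_discrepancy_zero_at_equality(rng):
    A = rng.standard_normal((4, 4))
    S = A @ A.T + 4 * np.eye(4)
    assert ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)


def test_ml_discrepancy_scalar_closed_form():
    # p = 1, S = 2, Sigma = 1: F = log 1 + 2 - log 2 - 1 = 1 - ln 2
    assert ml_discrepancy([[2.0]], [[1.0]]) == pytest.approx(1 - np.log(2.0))


def test_ml_discrepancy_nonnegative(rng):
    for _ in range(20):
        A = rng.standard_normal((3, 3))
        B = rng.standard_normal((3, 3))
        S = A @ A.T + 3 * np.eye(3)
        Sigma = B @ B.T + 3 * np.eye(3)
        assert ml_discrepancy(S, Sigma) >= -1e-12


def test_ml_discrepancy_rejects_non_pd():
    with pytest.raises(ValueError):
        ml_discrepancy([[1.0, 2.0], [2.0, 1.0]], np.eye(2))


# -- analytic gradient -----------------------------------------------------------


def test_analytic_gradient_matches_finite_differences(rng):
    spec = SemModelSpec.create(
        observed=("x", "a", "b"),
        latents={"f": ["a", "b"]},
        paths=(("x", "f"),),
        fixed={("loading", "f", "a"): 1.0},
    )
    model = RamModel(spec)
    X = rng.standard_normal((200, 3))
    X[:, 1] += 0.5 * X[:, 0]
    X[:, 2] += 0.5 * X[:, 1]
    S_n = np.cov(X, rowvar=False, ddof=0)
    logdet = np.linalg.slogdet(S_n)[1]
    theta = model.start_values(S_n) + 0.05
    _, grad = model.ml_value_and_grad(theta, S_n, logdet)
    num = optimize.approx_fprime(
        theta, lambda t: model.ml_value_and_grad(t, S_n, logdet)[0], 1e-7
    )
    np.testing.assert_allclose(grad, num, atol=1e-5)


# -- fitting oracles -------------------------------------------------------------


def test_path_model_equals_ols_slope(rng):
    x = rng.standard_normal(300)
    y = 0.7 * x + rng.standard_normal(300)
    spec = SemModelSpec.create(observed=("x", "y"), paths=(("x", "y"),))
    fit = fit_sem(pd.DataFrame({"x": x, "y": y}), spec)
    slope = np.cov(x, y, ddof=0)[0, 1] / np.var(x)
    assert fit.param(("path", "x", "y")) == pytest.approx(slope, abs=1e-8)
    assert fit.df == 0
    assert fit.chisq == pytest.approx(0.0, abs=1e-8)
    # standardised path of a single-predictor regression is Pearson r
    assert fit.std(("path", "x", "y")) == pytest.approx(
        np.corrcoef(x, y)[0, 1], abs=1e-8
    )


def test_saturated_model_chisq_zero(rng):
    X = rng.standard_normal((120, 3))
    spec = SemModelSpec.create(
        observed=("a", "b", "c"),
        covariances=(("a", "b"), ("a", "c"), ("b", "c")),
    )
    fit = fit_sem(pd.DataFrame(X, columns=["a", "b", "c"]), spec)
    assert fit.df == 0
    assert fit.chisq == pytest.approx(0.0, abs=1e-8)


def test_observed_path_system_matches_equationwise_ols(rng):
    # x -> m -> y with x -> y: coefficients equal per-equation least squares
    n = 400
    x = rng.standard_normal(n)
    m = 0.5 * x + rng.standard_normal(n)
    y = 0.3 * x + 0.4 * m + rng.standard_normal(n)
    spec = SemModelSpec.create(
        observed=("x", "m", "y"),
        paths=(("x", "m"), ("x", "y"), ("m", "y")),
    )
    fit = fit_sem(pd.DataFrame({"x": x, "m": m, "y": y}), spec)
    X2 = np.column_stack([np.ones(n), x, m])
    beta = np.linalg.lstsq(X2, y, rcond=None)[0]
    assert fit.param(("path", "x", "m")) == pytest.approx(
        np.cov(x, m, ddof=0)[0, 1] / np.var(x), abs=1e-6
    )
    assert fit.param(("path", "x", "y")) == pytest.approx(beta[1], abs=1e-6)
    assert fit.param(("path", "m", "y")) == pytest.approx(beta[2], abs=1e-6)


# -- fit indices -----------------------------------------------------------------


def test_fit_indices_worked_example():
    out = fit_indices_from_chisq(100, 40, 1000, 55, 1001)
    assert out["CFI"] == pytest.approx(0.9365, abs=5e-5)
    assert out["TLI"] == pytest.approx(0.9127, abs=5e-5)
    assert out["RMSEA"] == pytest.approx(0.0387, abs=5e-5)


def test_fit_indices_perfect_fit():
    out = fit_indices_from_chisq(40, 40, 900, 55, 500)
    assert out["CFI"] == 1.0
    assert out["RMSEA"] == 0.0


def test_fit_indices_zero_df_flags_rmsea():
    out = fit_indices_from_chisq(0, 0, 900, 55, 500)
    assert np.isnan(out["RMSEA"])


# -- chi-square difference -------------------------------------------------------


def test_chisq_difference_identical_models(tiny_matrix):
    spec = build_structural_spec()
    fit = fit_sem(tiny_matrix, spec, compute_se=False)
    d = chi_square_difference(fit, fit)
    assert (d.delta_chisq, d.delta_df, d.p_value) == (0.0, 0, 1.0)


def test_chisq_difference_critical_value():
    # chi2(4) upper 5% point is 9.488
    assert stats.chi2.sf(9.488, 4) == pytest.approx(0.05, abs=1e-4)


def test_chisq_difference_rejects_non_nested(tiny_matrix, rng):
    spec = build_structural_spec()
    fit = fit_sem(tiny_matrix, spec, compute_se=False)
    other = SemModelSpec.create(observed=("x", "y"), paths=(("x", "y"),))
    ofit = fit_sem(
        pd.DataFrame(rng.standard_normal((50, 2)), columns=["x", "y"]), other
    )
    with pytest.raises(ValueError, match="not nested"):
        chi_square_difference(fit, ofit)


def test_nested_comparison_on_synthetic_cohort(tiny_matrix):
    spec = build_structural_spec()
    full = fit_sem(tiny_matrix, spec, compute_se=False)
    nested = fit_sem(
        tiny_matrix, constrain_variable_paths(spec, "wm"), compute_se=False
    )
    d = chi_square_difference(full, nested)
    assert d.delta_df == 4
    assert d.delta_chisq >= 0


# -- FIML ------------------------------------------------------------------------


def test_fiml_equals_ml_on_complete_data(tiny_matrix):
    spec = build_structural_spec()
    ml = fit_sem(tiny_matrix, spec, compute_se=False)
    fiml = fit_sem(tiny_matrix, spec, estimator="FIML", compute_se=False)
    np.testing.assert_allclose(fiml.theta, ml.theta, atol=1e-6)
    np.testing.assert_allclose(
        fiml.means, tiny_matrix.mean().to_numpy(), atol=1e-6
    )


def test_fiml_recovers_paths_under_mar(rng):
    df = generate_cohort(default_params(6000), seed=77)
    mat, _ = build_model_matrix(df)
    for c in ("wmh", "slf_icvf", "pairs", "gm_precuneus"):
        mask = rng.random(len(mat)) < 0.15
        mat.loc[mask, c] = np.nan
    fit = fit_sem(mat, build_structural_spec(), estimator="FIML", compute_se=False)
    assert fit.converged
    assert fit.std(("path", "age", "gm")) == pytest.approx(-0.45, abs=0.05)
    assert fit.std(("path", "wm", "ef")) == pytest.approx(0.34, abs=0.06)


def test_fiml_model_loglik_bounded_by_saturated(tiny_matrix):
    from neurocvr.sem import em_saturated

    spec = build_structural_spec()
    fit = fit_sem(tiny_matrix, spec, estimator="FIML", compute_se=False)
    _, _, ll_sat = em_saturated(tiny_matrix.to_numpy())
    assert fit.loglik <= ll_sat + 1e-6


# -- invariances ------------------------------------------------------------------


def test_standardised_solution_invariant_to_indicator_rescaling(tiny_matrix):
    spec = build_structural_spec()
    base = fit_sem(tiny_matrix, spec, compute_se=False)
    scaled = tiny_matrix.copy()
    scaled["rt"] = scaled["rt"] * 37.0
    scaled["gm_precuneus"] = scaled["gm_precuneus"] * 0.01 + 3.0
    refit = fit_sem(scaled, spec, compute_se=False)
    for key in base.standardized:
        assert refit.standardized[key] == pytest.approx(
            base.standardized[key], abs=1e-6
        )


def test_fit_invariant_to_variable_order(tiny_matrix):
    spec = build_structural_spec()
    base = fit_sem(tiny_matrix, spec, compute_se=False)
    shuffled = tiny_matrix[list(reversed(tiny_matrix.columns))]
    refit = fit_sem(shuffled, spec, compute_se=False)
    assert refit.chisq == pytest.approx(base.chisq, abs=1e-6)
    for key in base.standardized:
        assert refit.standardized[key] == pytest.approx(
            base.standardized[key], abs=1e-6
        )


# -- factor scores ----------------------------------------------------------------


def test_factor_scores_track_true_latents():
    df = generate_cohort(default_params(4000), seed=55)
    mat, _ = build_model_matrix(df)
    fit = fit_sem(mat, build_structural_spec(), compute_se=False)
    scores = factor_scores(fit, mat)
    truth = df.attrs["latents"]
    for lat in ("gm", "wm", "ef"):
        r = np.corrcoef(scores[lat], truth[lat])[0, 1]
        assert r > 0.6, (lat, r)
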