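"""Path-model engine: specification, moments, ML fitting, indices, effects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from regenpath import sem
from regenpath.dataset import STUDY_VARIABLES
from regenpath.pipeline import study_model

from conftest import random_dag_model, simulate_from


# ---------------------------------------------------------------------------
# Model specification


def test_study_model_dimensions():
    m = study_model()
    assert m.p == 5 and len(m.paths) == 8
    assert m.exogenous == ("cu",)
    assert set(m.endogenous) == {"chh_sv", "chh_dnmv", "gsh", "gpre"}
    assert m.n_free == 13 and m.df == 2


def test_df_closed_forms():
    sat = sem.build_model(["x", "y"], [("x", "y")])
    assert sat.df == 0
    empty = sem.build_model(list("abcd"), [])
    assert empty.df == 4 * 5 // 2 - 4


def test_model_validation_errors():
    with pytest.raises(ValueError, match="cycle"):
        sem.build_model(["a", "b"], [("a", "b"), ("b", "a")])
    with pytest.raises(ValueError, match="duplicate path"):
        sem.build_model(["a", "b"], [("a", "b"), ("a", "b")])
    with pytest.raises(ValueError, match="unknown variable"):
        sem.build_model(["a", "b"], [("a", "c")])
    with pytest.raises(ValueError, match="self-loop"):
        sem.build_model(["a"], [("a", "a")])


def test_parse_model_config_toml():
    text = 'variables = ["x", "m", "y"]\npaths = ["x -> m", "m -> y"]\n'
    m = sem.parse_model_config(text)
    assert m.paths == (("x", "m"), ("m", "y"))


# ---------------------------------------------------------------------------
# Moments and descriptives


def test_sample_moments_matches_numpy(rng):
    df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
    mom = sem.sample_moments(df, ["a", "b", "c"], ddof=1)
    np.testing.assert_allclose(mom.cov.to_numpy(), np.cov(df.to_numpy().T, ddof=1))
    mom0 = sem.sample_moments(df, ["a", "b"], ddof=0)
    np.testing.assert_allclose(mom0.cov.to_numpy(), np.cov(df[["a", "b"]].to_numpy().T, ddof=0))


def test_sample_moments_names_missing_record():
    df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="field 'a'"):
        sem.sample_moments(df, ["a", "b"])


def test_describe_matches_pandas_convention(rng):
    x = pd.DataFrame({"v": rng.gamma(2.0, size=200)})
    d = sem.describe(x, "v")
    assert d["skewness"] == pytest.approx(x["v"].skew(), rel=1e-12)
    assert d["kurtosis"] == pytest.approx(x["v"].kurt(), rel=1e-12)
    sym = pd.DataFrame({"v": [-1.0, 1.0, -1.0, 1.0]})
    assert sem.describe(sym, "v")["skewness"] == pytest.approx(0.0, abs=1e-12)


def test_describe_large_normal_sample_has_no_skew(rng):
    x = pd.DataFrame({"v": rng.normal(size=100_000)})
    assert abs(sem.describe(x, "v")["skewness"]) < 0.03


def test_pearson_matrix_matches_scipy(rng):
    df = pd.DataFrame(rng.normal(size=(30, 3)) @ rng.normal(size=(3, 3)), columns=list("abc"))
    r, p = sem.pearson_matrix(df, ["a", "b", "c"])
    for i, j in [("a", "b"), ("a", "c"), ("b", "c")]:
        ref = stats.pearsonr(df[i], df[j])
        assert r.loc[i, j] == pytest.approx(ref.statistic, rel=1e-12)
        assert p.loc[i, j] == pytest.approx(ref.pvalue, rel=1e-9)
    assert (np.diag(r) == 1.0).all()
    with pytest.raises(ValueError, match="constant"):
        sem.pearson_matrix(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}), ["a", "b"])


# ---------------------------------------------------------------------------
# Implied covariance


def test_implied_sigma_zero_paths_is_diagonal():
    m = sem.build_model(["a", "b"], [])
    sig = sem.implied_sigma(m, [2.0, 3.0])
    np.testing.assert_allclose(sig, np.diag([2.0, 3.0]))


def test_implied_sigma_single_path_hand_algebra():
    m = sem.build_model(["x", "y"], [("x", "y")])
    b, v, psi = 0.7, 2.0, 0.5
    sig = sem.implied_sigma(m, [b, v, psi])  # order: path, var(x), resid(y)
    np.testing.assert_allclose(sig, [[v, b * v], [b * v, b * b * v + psi]])


# ---------------------------------------------------------------------------
# ML fit


def _fit(df, model):
    return sem.fit_ml(model, sem.sample_moments(df, list(model.variables)))


def test_saturated_model_fits_exactly(rng):
    model, coefs, variances = random_dag_model(rng, p_max=3)
    df = simulate_from(model, coefs, variances, 100, rng)
    sat = sem.build_model(["x", "y"], [("x", "y")])
    data = pd.DataFrame({"x": df.iloc[:, 0], "y": df.iloc[:, -1]})
    fit = _fit(data, sat)
    assert fit.converged
    assert fit.discrepancy == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(
        fit.implied_cov.to_numpy(), data.cov().to_numpy(), rtol=1e-8, atol=1e-10
    )


def test_single_path_closed_form_and_statsmodels_oracle(rng):
    import statsmodels.api as sm

    x = rng.normal(size=200)
    y = 0.8 * x + rng.normal(scale=0.5, size=200)
    df = pd.DataFrame({"x": x, "y": y})
    fit = _fit(df, sem.build_model(["x", "y"], [("x", "y")]))
    S = df.cov()
    assert fit.estimates["x -> y"] == pytest.approx(S.loc["x", "y"] / S.loc["x", "x"], rel=1e-10)
    ols = sm.OLS(y - y.mean(), (x - x.mean())).fit()
    assert fit.estimates["x -> y"] == pytest.approx(ols.params[0], rel=1e-8)


def test_ml_equals_per_equation_ols_on_random_models(rng):
    for _ in range(20):
        model, coefs, variances = random_dag_model(rng)
        df = simulate_from(model, coefs, variances, 200, rng)
        fit = _fit(df, model)
        assert fit.converged
        S = df.cov()
        for t in model.endogenous:
            srcs = list(model.parents(t))
            b_ols = np.linalg.solve(S.loc[srcs, srcs], S.loc[srcs, t])
            for s, b in zip(srcs, b_ols):
                assert fit.estimates[f"{s} -> {t}"] == pytest.approx(b, rel=1e-6, abs=1e-9)


def test_fit_rejects_bad_inputs():
    m = sem.build_model(["x", "y"], [("x", "y")])
    degenerate = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 6.0, 8.0]})
    with pytest.raises(ValueError, match="positive definite"):
        _fit(degenerate, m)
    tiny = pd.DataFrame({"x": [0.0, 1.0, 3.0], "y": [1.0, 0.0, 2.0]})
    with pytest.raises(ValueError, match="free parameters"):
        _fit(tiny, m)


# ---------------------------------------------------------------------------
# Standard errors and standardization


def test_residual_critical_ratios_closed_form(study_fit):
    table = sem.standard_errors(study_fit)
    expected = np.sqrt((study_fit.n - 1) / 2.0)
    for v in study_fit.model.endogenous:
        assert table.loc[f"resid({v})", "critical_ratio"] == pytest.approx(expected, rel=1e-4)
    assert table.loc["var(cu)", "critical_ratio"] == pytest.approx(expected, rel=1e-4)


def test_se_scales_with_sample_size(rng):
    x = rng.normal(size=400)
    y = 0.5 * x + rng.normal(size=400)
    df = pd.DataFrame({"x": x, "y": y})
    m = sem.build_model(["x", "y"], [("x", "y")])
    mom = sem.sample_moments(df, ["x", "y"])
    fit_n = sem.fit_ml(m, mom)
    # same covariance matrix presented with 2(n-1)+1 records
    mom2 = sem.MomentSummary(n=2 * mom.n - 1, means=mom.means, cov=mom.cov)
    fit_2n = sem.fit_ml(m, mom2)
    se_n = sem.standard_errors(fit_n).loc["x -> y", "se"]
    se_2n = sem.standard_errors(fit_2n).loc["x -> y", "se"]
    assert se_2n == pytest.approx(se_n / np.sqrt(2.0), rel=1e-6)


def test_standardized_bivariate_equals_pearson_r(rng):
    x = rng.normal(size=300)
    y = 1.3 * x + rng.normal(size=300)
    df = pd.DataFrame({"x": x, "y": y})
    fit = _fit(df, sem.build_model(["x", "y"], [("x", "y")]))
    r = df.corr().loc["x", "y"]
    assert sem.standardize(fit)["x -> y"] == pytest.approx(r, rel=1e-8)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scales=st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=5, max_size=5))
def test_standardized_solution_invariant_to_rescaling(study_records, scales):
    df = study_records[list(STUDY_VARIABLES)].copy()
    base = _fit(df, study_model())
    ref = sem.standardize(base)
    scaled = df * np.asarray(scales)
    fit = _fit(scaled, study_model())
    np.testing.assert_allclose(sem.standardize(fit).to_numpy(), ref.to_numpy(), rtol=1e-6)


# ---------------------------------------------------------------------------
# Fit indices


def test_saturated_model_indices(rng):
    x = rng.normal(size=50)
    y = x + rng.normal(size=50)
    fit = _fit(pd.DataFrame({"x": x, "y": y}), sem.build_model(["x", "y"], [("x", "y")]))
    idx = sem.fit_indices(fit)
    assert idx.chi2 == pytest.approx(0.0, abs=1e-8)
    assert idx.cfi == 1.0 and idx.df == 0
    assert np.isnan(idx.rmsea) and np.isnan(idx.rfi)  # undefined at df = 0


def test_index_identities_on_study_fit(study_fit):
    idx = sem.fit_indices(study_fit)
    assert idx.df == 2
    assert 0 <= idx.gfi <= 1 and 0 <= idx.cfi <= 1 and idx.rmsea >= 0
    assert idx.pnfi == pytest.approx((idx.df / 10) * idx.nfi, rel=1e-12)
    assert idx.p_value == pytest.approx(stats.chi2.sf(idx.chi2, 2), rel=1e-12)
    assert idx.chi2 == pytest.approx((study_fit.n - 1) * study_fit.discrepancy, rel=1e-12)


# ---------------------------------------------------------------------------
# Effects


def brute_force_paths(model, A, order, src, tgt):
    """Sum of coefficient products over every directed route src -> tgt."""
    total = 0.0
    stack = [(src, 1.0)]
    children = {v: [t for s, t in model.paths if s == v] for v in model.variables}
    while stack:
        node, prod = stack.pop()
        for child in children[node]:
            w = prod * A[order[child], order[node]]
            if child == tgt:
                total += w
            else:
                stack.append((child, w))
    return total


def test_chain_indirect_effect_product_rule(rng):
    m = sem.build_model(["x", "m", "y"], [("x", "m"), ("m", "y")])
    df = simulate_from(m, {("x", "m"): 0.5, ("m", "y"): 0.5}, dict.fromkeys("xmy", 1.0), 500, rng)
    fit = _fit(df, m)
    eff = sem.decompose_effects(fit).set_index(["source", "target"])
    b1 = fit.estimates["x -> m"]
    b2 = fit.estimates["m -> y"]
    row = eff.loc[("x", "y")]
    assert row["direct_b"] == 0.0
    assert row["indirect_b"] == pytest.approx(b1 * b2, rel=1e-10)
    assert row["total_b"] == pytest.approx(b1 * b2, rel=1e-10)


def test_effect_matrix_equals_path_enumeration(rng):
    for _ in range(10):
        model, coefs, variances = random_dag_model(rng)
        df = simulate_from(model, coefs, variances, 150, rng)
        fit = _fit(df, model)
        eff = sem.decompose_effects(fit).set_index(["source", "target"])
        order = {v: i for i, v in enumerate(model.variables)}
        for scale in ("b", "beta"):
            A = fit.coefficient_matrix(standardized=scale == "beta").to_numpy()
            for (s, t), row in eff.iterrows():
                assert row[f"total_{scale}"] == pytest.approx(
                    brute_force_paths(model, A, order, s, t), rel=1e-9, abs=1e-12
                )
                # additivity is exact by construction
                assert row[f"total_{scale}"] == row[f"direct_{scale}"] + row[f"indirect_{scale}"]


def test_parameter_recovery_from_known_model(rng):
    model, coefs, variances = random_dag_model(rng, p_max=4)
    df = simulate_from(model, coefs, variances, 2000, rng)
    fit = _fit(df, model)
    se = sem.standard_errors(fit)
    for (s, t), b_true in coefs.items():
        est = fit.estimates[f"{s} -> {t}"]
        assert abs(est - b_true) < 4 * se.loc[f"{s} -> {t}", "se"]
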