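"""Linear association, covariate encoding, descriptive screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dopagrs as d
from dopagrs.association import AssociationError, DesignMatrix


def _design(y, X):
    idx = pd.Index([f"S{i}" for i in range(len(y))], name="subject_id")
    Xf = pd.DataFrame(X, index=idx)
    if "const" not in Xf.columns:
        Xf.insert(0, "const", 1.0)
    return DesignMatrix(y=pd.Series(y, index=idx, dtype=float), X=Xf)


def test_simple_regression_matches_closed_form():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.1, 3.9, 6.2, 8.1, 9.8])
    fit = d.ols_fit(_design(y, {"x": x}))
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    assert fit.term("x")["beta"] == pytest.approx(slope, rel=1e-12)


def test_exact_linear_data_recovered():
    x = np.arange(10.0)
    fit = d.ols_fit(_design(3.0 - 0.8 * x, {"x": x}))
    assert fit.term("x")["beta"] == pytest.approx(-0.8, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)


def test_intercept_only_model_is_mean():
    y = np.array([1.0, 2.0, 6.0])
    fit = d.ols_fit(_design(y, {}))
    assert fit.term("const")["beta"] == pytest.approx(y.mean())
    assert fit.r_squared == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_ols_matches_normal_equations_oracle(seed):
    """Estimates, SEs, t, p and CI agree with a hand-rolled normal-equations fit."""
    rng = np.random.default_rng(seed)
    n, k = rng.integers(8, 21), rng.integers(1, 5)
    X = rng.normal(size=(n, k))
    y = rng.normal(size=n)
    fit = d.ols_fit(_design(y, {f"x{j}": X[:, j] for j in range(k)}))

    Xc = np.column_stack([np.ones(n), X])
    xtx_inv = np.linalg.inv(Xc.T @ Xc)
    beta = xtx_inv @ Xc.T @ y
    resid = y - Xc @ beta
    dof = n - Xc.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    tval = beta / se
    pval = 2 * stats.t.sf(np.abs(tval), dof)
    tcrit = stats.t.ppf(0.975, dof)

    got = fit.params
    assert np.allclose(got["beta"], beta, rtol=1e-8)
    assert np.allclose(got["se"], se, rtol=1e-8)
    assert np.allclose(got["p"], pval, rtol=1e-8)
    assert np.allclose(got["ci_low"], beta - tcrit * se, rtol=1e-8)
    assert np.allclose(got["ci_high"], beta + tcrit * se, rtol=1e-8)


def test_rank_deficiency_names_columns():
    x = np.arange(6.0)
    with pytest.raises(AssociationError, match="x2"):
        d.ols_fit(_design(x, {"x1": x, "x2": 2 * x}))


def _cov_cohort():
    idx = pd.Index([f"S{i}" for i in range(8)], name="subject_id")
    cov = pd.DataFrame({
        "age": [20, 25, 30, 22, 24, 28, 21, 26],
        "sex": [0, 1, 1, 0, 1, 1, 0, 1],
        "marital": ["married", "never", "divorced", "married", "never",
                    "married", "married", "divorced"],
        "ethnicity": ["Asian", "White", "Asian", "Other", "Black",
                      "Asian", "White", "Asian"],
    }, index=idx)
    y = pd.Series(np.arange(8.0), index=idx)
    return d.CohortTable(covariates=cov, phenotype=y)


def test_covariate_encoding_shapes():
    cohort = _cov_cohort()
    enc = d.encode_covariates(cohort, ["age", "sex", "marital"])
    assert list(enc.columns) == ["age", "sex", "marital[divorced]", "marital[never]"]
    enc4 = d.encode_covariates(cohort, ["ethnicity"])   # 4 levels -> 3 indicators
    assert enc4.shape[1] == 3
    assert "ethnicity[Asian]" not in enc4.columns       # most frequent is reference


def test_covariate_encoding_errors():
    cohort = _cov_cohort()
    with pytest.raises(AssociationError, match="not present"):
        d.encode_covariates(cohort, ["income"])
    with pytest.raises(AssociationError, match="reference"):
        d.encode_covariates(cohort, ["marital"], reference_levels={"marital": "widowed"})
    const = d.CohortTable(covariates=pd.DataFrame(
        {"site": ["A", "A"]}, index=pd.Index(["S1", "S2"], name="subject_id")))
    with pytest.raises(AssociationError, match="constant"):
        d.encode_covariates(const, ["site"])


def test_grs_association_recovers_noiseless_slope(hs5):
    spec = d.SimulationSpec(seed=11, n=80, noise_sd=0.0, covariate_effects={})
    cohort = d.simulate_cohort(spec, hs5)
    fit = d.grs_association(cohort, hs5)
    assert fit.term("grs")["beta"] == pytest.approx(-0.80, abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0)


def test_phenotype_shift_moves_only_intercept(hs5, sim_cohort):
    from dataclasses import replace
    fit = d.grs_association(sim_cohort, hs5, covariate_spec=["ethnicity"])
    shifted = replace(sim_cohort, phenotype=sim_cohort.phenotype + 7.0)
    fit2 = d.grs_association(shifted, hs5, covariate_spec=["ethnicity"])
    assert fit2.term("grs")["beta"] == pytest.approx(fit.term("grs")["beta"], rel=1e-10)
    assert fit2.term("const")["beta"] == pytest.approx(fit.term("const")["beta"] + 7.0)


def test_nested_model_r_squared_ordering(hs5, sim_cohort):
    plain = d.grs_association(sim_cohort, hs5)
    adjusted = d.grs_association(sim_cohort, hs5, covariate_spec=["ethnicity", "age", "sex"])
    assert adjusted.r_squared >= plain.r_squared


def test_single_variant_scan_and_bonferroni(hs5, sim_cohort):
    fits, report = d.single_variant_scan(sim_cohort, hs5, covariate_spec=["ethnicity"])
    assert set(fits) == set(hs5.variant_ids)
    assert report.m == 5
    assert report.threshold == pytest.approx(0.01)
    assert d.bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
    with pytest.raises(AssociationError):
        d.bonferroni_threshold(0.05, 0)


def test_descriptive_stats_hand_oracle():
    """{0,0,0,1}: bias-adjusted G1 = 2, G2 (excess) = 4 by direct moment arithmetic."""
    desc = d.descriptive_stats([0, 0, 0, 1])
    assert desc.skewness == pytest.approx(2.0, rel=1e-12)
    assert desc.kurtosis == pytest.approx(4.0, rel=1e-12)
    pearson = d.descriptive_stats([0, 0, 0, 1], excess_kurtosis=False)
    assert pearson.kurtosis == pytest.approx(7.0, rel=1e-12)


def test_descriptive_stats_symmetry_and_degenerate():
    sym = d.descriptive_stats([-2, -1, 1, 2])
    assert sym.skewness == pytest.approx(0.0, abs=1e-12)
    const = d.descriptive_stats([3.0, 3.0, 3.0])
    assert not const.defined and np.isnan(const.skewness)
    with pytest.raises(AssociationError):
        d.descriptive_stats([1.0])


def test_predicted_difference():
    x = np.arange(20.0)
    fit_08 = d.ols_fit(_design(3.0 - 0.80 * x, {"x": x}))
    assert d.predicted_difference(fit_08, "x", 10) == pytest.approx(8.0)
    fit_051 = d.ols_fit(_design(2.0 - 0.51 * x, {"x": x}))
    assert d.predicted_difference(fit_051, "x", 6) == pytest.approx(3.06)
    fit_0 = d.ols_fit(_design(np.full(20, 5.0) + 1e-15 * x, {"x": x}))
    assert d.predicted_difference(fit_0, "x", 10) == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(AssociationError):
        d.predicted_difference(fit_08, "z", 1)


def test_score_stratified_means(hs5):
    idx = pd.Index(["S1", "S2", "S3", "S4", "S5"], name="subject_id")
    pheno = pd.Series([4.0, 6.0, 1.0, 3.0, 9.0], index=idx)
    cohort = d.CohortTable(phenotype=pheno)
    scores = pd.DataFrame({"score": [0, 0, 1, 1, 2]}, index=idx)
    table = d.score_stratified_means(cohort, scores).set_index("score")
    assert table.loc[0, "mean"] == pytest.approx(5.0)
    assert table.loc[0, "se"] == pytest.approx(1.0)
    assert table.loc[1, "mean"] == pytest.approx(2.0)
    assert table.loc[1, "se"] == pytest.approx(1.0)
    assert np.isnan(table.loc[2, "se"])  # single subject: SE undefined


def test_stratified_means_trend_downward(hs5):
    spec = d.SimulationSpec(seed=21, n=4000, noise_sd=3.0, covariate_effects={})
    cohort = d.simulate_cohort(spec, hs5)
    scores = d.compute_grs_hardcall(cohort, hs5)
    table = d.score_stratified_means(cohort, scores)
    big = table[table["n"] >= 30]
    slope = np.polyfit(big["score"], big["mean"], 1)[0]
    assert slope == pytest.approx(-0.80, abs=0.15)
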