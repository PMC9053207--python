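"""EMM model chain vs an independent brute-force oracle, plus closed forms."""

import numpy as np
import pandas as pd
import pytest

import helpers_oracle as oracle
from conftest import make_specimens, random_stratum
from tmbsite.emm import (
    SiteEffectModel,
    emm_contrasts,
    fit_site_model,
    metastatic_vs_primary,
    reference_grid,
    regrid_response,
    run_all,
)

COVS = ["purity_pathologist"]
FULL_COVS = ("median_coverage", "purity_pathologist", "purity_computational")


def test_fit_matches_normal_equations_oracle(ols_fixture):
    fit = fit_site_model(ols_fixture, covariates=tuple(COVS))
    beta, cov, dof, sigma2, names, levels = oracle.oracle_ols(ols_fixture, "biopsy_site", COVS)
    assert fit.columns == names
    np.testing.assert_allclose(fit.params, beta, atol=1e-10)
    np.testing.assert_allclose(fit.cov, cov, atol=1e-10)
    assert fit.df_resid == dof
    assert fit.sigma2 == pytest.approx(sigma2, abs=1e-10)


def test_grid_eta_matches_oracle_prediction_at_means(ols_fixture):
    fit = fit_site_model(ols_fixture, covariates=tuple(COVS))
    grid = reference_grid(fit, ols_fixture)
    beta, cov, dof, _, names, levels = oracle.oracle_ols(ols_fixture, "biopsy_site", COVS)
    eta, eta_cov = oracle.oracle_grid(ols_fixture, "biopsy_site", COVS, beta, cov, names, levels)
    np.testing.assert_allclose(grid.eta, eta, atol=1e-10)
    np.testing.assert_allclose(grid.eta_cov, eta_cov, atol=1e-10)


def test_regrid_covariance_matches_finite_difference_jacobian(ols_fixture):
    fit = fit_site_model(ols_fixture, covariates=tuple(COVS))
    grid = reference_grid(fit, ols_fixture)
    rg = regrid_response(grid)
    m, V = oracle.oracle_regrid_fd(grid.eta, grid.eta_cov)
    np.testing.assert_allclose(rg.mean, m, atol=1e-8)
    np.testing.assert_allclose(rg.mean, np.exp(grid.eta) - 1.0, atol=1e-12)
    np.testing.assert_allclose(rg.cov, V, atol=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_full_chain_matches_oracle_on_random_strata(seed):
    """End-to-end estimate/CI/p agree with the independent chain to 1e-8 (n<=200)."""
    rng = np.random.default_rng(seed)
    df = random_stratum(rng, n=150)
    df[list(FULL_COVS)] = df[list(FULL_COVS)].astype(float)
    fit = fit_site_model(df, covariates=FULL_COVS)
    rg = regrid_response(reference_grid(fit, df))
    ours = emm_contrasts(rg, "site0")
    theirs = oracle.oracle_chain(df, "site0", list(FULL_COVS))
    for site, (est, lo, hi, p) in theirs.items():
        row = ours.set_index("site").loc[site]
        assert row["estimate"] == pytest.approx(est, abs=1e-8)
        assert row["ci_low"] == pytest.approx(lo, abs=1e-8)
        assert row["ci_high"] == pytest.approx(hi, abs=1e-8)
        assert row["p_value"] == pytest.approx(p, abs=1e-8)


def test_no_covariate_contrast_is_difference_of_geometric_style_means():
    rng = np.random.default_rng(5)
    df = random_stratum(rng, 120, n_sites=2)
    fit = fit_site_model(df, covariates=())
    rg = regrid_response(reference_grid(fit, df))
    con = emm_contrasts(rg, "site0").set_index("site")
    g = df.groupby("biopsy_site")["tmb"].apply(lambda t: np.exp(np.log(t + 1).mean()) - 1)
    assert con.loc["site1", "estimate"] == pytest.approx(g["site1"] - g["site0"], abs=1e-10)


def test_constant_response_gives_zero_site_effects():
    df = random_stratum(np.random.default_rng(2), 60)
    df["tmb"] = 4.0
    fit = fit_site_model(df, covariates=())
    assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(fit.params[1:], 0.0, atol=1e-10)


def test_deterministic_two_site_contrast_is_exact():
    rows = [(f"S{i}", f"P{i}", "X", "a" if i < 3 else "b", "2019-01-01",
             4.0 if i < 3 else 9.0, 0.5, 0.5, 500.0) for i in range(6)]
    df = make_specimens(rows)
    fit = fit_site_model(df, covariates=())
    con = emm_contrasts(regrid_response(reference_grid(fit, df)), "a").set_index("site")
    assert con.loc["b", "estimate"] == pytest.approx(5.0, abs=1e-9)
    assert con.loc["b", "ci_low"] == pytest.approx(5.0, abs=1e-9)  # CI collapses


def test_reference_vs_itself_row():
    df = random_stratum(np.random.default_rng(3), 80)
    fit = fit_site_model(df, covariates=())
    con = emm_contrasts(regrid_response(reference_grid(fit, df)), "site0").set_index("site")
    assert con.loc["site0", "estimate"] == 0.0
    assert con.loc["site0", "p_value"] == 1.0


def test_single_site_level_errors():
    df = random_stratum(np.random.default_rng(4), 40, n_sites=1)
    with pytest.raises(ValueError, match="2 levels"):
        fit_site_model(df, covariates=())


def test_rank_deficient_design_names_aliased_column():
    df = random_stratum(np.random.default_rng(6), 60)
    df["purity_computational"] = df["purity_pathologist"]  # perfectly aliased
    with pytest.raises(ValueError, match="purity_computational|purity_pathologist"):
        fit_site_model(df, covariates=("purity_pathologist", "purity_computational"))


def test_unknown_reference_site_errors():
    df = random_stratum(np.random.default_rng(7), 60)
    fit = fit_site_model(df, covariates=())
    with pytest.raises(ValueError, match="nowhere"):
        emm_contrasts(regrid_response(reference_grid(fit, df)), "nowhere")


def test_contrasts_invariant_to_covariate_shift_and_site_relabeling():
    rng = np.random.default_rng(8)
    df = random_stratum(rng, 150)
    fit = fit_site_model(df, covariates=("purity_pathologist",))
    base = emm_contrasts(regrid_response(reference_grid(fit, df)), "site0")
    # shifting a covariate by a constant must not move the contrasts
    shifted = df.assign(purity_pathologist=df["purity_pathologist"] + 5.0)
    fit2 = fit_site_model(shifted, covariates=("purity_pathologist",))
    alt = emm_contrasts(regrid_response(reference_grid(fit2, shifted)), "site0")
    np.testing.assert_allclose(base["estimate"], alt["estimate"], atol=1e-8)
    # relabeling non-reference sites permutes rows but not values
    relabeled = df.assign(biopsy_site=df["biopsy_site"].map(
        {"site0": "site0", "site1": "zzz", "site2": "aaa"}))
    fit3 = fit_site_model(relabeled, covariates=("purity_pathologist",))
    ren = emm_contrasts(regrid_response(reference_grid(fit3, relabeled)), "site0").set_index("site")
    ours = base.set_index("site")
    assert ren.loc["zzz", "estimate"] == pytest.approx(ours.loc["site1", "estimate"], abs=1e-8)
    assert ren.loc["aaa", "estimate"] == pytest.approx(ours.loc["site2", "estimate"], abs=1e-8)


def test_pooled_contrast_invariant_to_metastatic_site_labels():
    rng = np.random.default_rng(9)
    df = random_stratum(rng, 150)
    df["is_primary_site"] = df["biopsy_site"] == "site0"
    a = metastatic_vs_primary(df)
    relabeled = df.assign(biopsy_site=df["biopsy_site"].replace({"site1": "m1", "site2": "m2"}))
    b = metastatic_vs_primary(relabeled)
    assert a["estimate"].iloc[0] == pytest.approx(b["estimate"].iloc[0], abs=1e-12)


def test_run_all_row_count_single_cancer():
    df = random_stratum(np.random.default_rng(10), 200)
    table = run_all(df, {"X": "site0"}, covariates=())
    # one pooled row + one row per site level (reference included)
    assert len(table) == 1 + df["biopsy_site"].nunique()


def test_sklearn_estimator_api():
    df = random_stratum(np.random.default_rng(11), 150)
    df["is_primary_site"] = df["biopsy_site"] == "site0"
    m = SiteEffectModel(covariates=("purity_pathologist",))
    assert m.get_params()["alpha"] == 0.05
    m.set_params(alpha=0.10).fit(df)
    assert m.reference_site_ == "site0"
    assert {"estimate", "ci_low", "p_value"} <= set(m.contrasts_.columns)
    assert m.n_obs_ == len(df)
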