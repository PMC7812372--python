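"""Tests for design construction, the Gibbs sampler, and contrasts."""

import numpy as np
import pandas as pd
import pytest

from audpsych import (
    standardize, effect_code, RegressionSpec, PriorConfig, FitSettings,
    build_design, fit_model, summarize_ci, contrast_draws,
    covariate_slopes_by_factor, factor_level_shifts,
)

FAST = FitSettings(n_chains=2, n_warmup=400, n_draws=1500,
                   ess_floor=100.0, rhat_max=1.2, seed=42)


def make_data(rng, n_subj=40, n_cond=2, beta_x=1.0, beta_int=0.0,
              subject_sd=0.0, resid_sd=1.0, levels=(40, 80)):
    """Long-format data: outcome = beta_x*x + level shift + interaction."""
    rows = []
    x_subj = rng.standard_normal(n_subj)
    u = subject_sd * rng.standard_normal(n_subj)
    for i in range(n_subj):
        for k in range(n_cond):
            lev = levels[k]
            code = 1.0 if k == 0 else -1.0  # effect code, 2 levels
            y = (beta_x * x_subj[i] + 0.5 * code
                 + beta_int * code * x_subj[i] + u[i]
                 + resid_sd * rng.standard_normal())
            rows.append({"subject": f"S{i:03d}", "x": x_subj[i],
                         "level": lev, "y": y})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standardization and effect coding
# ---------------------------------------------------------------------------

def test_standardize_round_trip(rng):
    x = rng.normal(5.0, 3.0, size=200)
    z, m, s = standardize(x)
    assert m == pytest.approx(x.mean(), abs=1e-12)
    assert s == pytest.approx(x.std(ddof=1), abs=1e-12)
    np.testing.assert_allclose(z * s + m, x, atol=1e-10)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        standardize(np.ones(10))


def test_effect_code_two_levels():
    codes, levels = effect_code([40, 80, 40, 80], name="level")
    assert levels == [40, 80]
    np.testing.assert_array_equal(codes["level[40]"], [1.0, -1.0, 1.0, -1.0])


def test_effect_code_three_levels_sum_to_zero():
    vals = [25, 50, 100, 25, 50, 100]
    codes, levels = effect_code(vals, name="mf")
    assert levels == [25, 50, 100]  # numeric order, not string order
    assert list(codes.columns) == ["mf[25]", "mf[50]"]
    # implied level effects (code rows) sum to zero across levels
    rows = {lev: codes[vals.index(lev) == np.arange(len(vals))].iloc[0]
            for lev in levels}
    total = sum(rows[lev].to_numpy() for lev in levels)
    np.testing.assert_allclose(total, 0.0, atol=1e-12)
    # reference level is -1 everywhere
    np.testing.assert_array_equal(rows[100].to_numpy(), [-1.0, -1.0])


def test_effect_code_unknown_level_and_single_level():
    with pytest.raises(ValueError):
        effect_code([1, 2], levels=[1], name="f")
    with pytest.raises(ValueError):
        effect_code([1, 2, 3], levels=[1, 2], name="f")


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def test_build_design_interactions_are_products_of_parents(rng):
    df = make_data(rng)
    spec = RegressionSpec(outcome="y", continuous=("x",), factors=("level",),
                          interactions=(("x", "level"),))
    des = build_design(spec, df)
    i_x = des.names.index("x")
    i_c = des.names.index("level[40]")
    i_i = des.names.index("x:level[40]")
    # Friedrich convention: product of standardized parents, NOT a
    # re-standardized product column
    np.testing.assert_allclose(des.X[:, i_i], des.X[:, i_x] * des.X[:, i_c],
                               atol=1e-12)
    assert des.prior_class[i_x] == "shrinkage"
    assert des.prior_class[i_c] == "broad"
    assert des.prior_class[i_i] == "shrinkage"
    assert des.prior_class[des.names.index("(Intercept)")] == "broad"


def test_build_design_outcome_standardized_and_recoverable(rng):
    df = make_data(rng)
    spec = RegressionSpec(outcome="y", continuous=("x",))
    des = build_design(spec, df)
    np.testing.assert_allclose(des.y * des.y_sd + des.y_mean,
                               df["y"].to_numpy(), atol=1e-10)


def test_build_design_log_transform(rng):
    df = make_data(rng)
    df["y"] = np.exp(df["y"] / 4)
    spec = RegressionSpec(outcome="y", continuous=("x",), transform="log")
    des = build_design(spec, df)
    logged = np.log(df["y"].to_numpy())
    assert des.y_mean == pytest.approx(logged.mean(), abs=1e-10)
    df.loc[0, "y"] = -1.0
    with pytest.raises(ValueError):
        build_design(spec, df)


def test_build_design_rank_deficiency_detected(rng):
    df = make_data(rng)
    df["x2"] = 2.0 * df["x"]  # perfectly collinear after standardization
    spec = RegressionSpec(outcome="y", continuous=("x", "x2"))
    with pytest.raises(ValueError, match="rank deficient"):
        build_design(spec, df)


def test_prior_overrides_and_spec_validation(rng):
    df = make_data(rng)
    spec = RegressionSpec(outcome="y", continuous=("x",),
                          prior_overrides={"x": "broad"})
    des = build_design(spec, df)
    assert des.prior_class[des.names.index("x")] == "broad"
    with pytest.raises(ValueError):
        build_design(RegressionSpec(outcome="y",
                                    prior_overrides={"nope": "broad"}), df)
    with pytest.raises(ValueError):
        RegressionSpec(outcome="y", interactions=(("a", "b"),))
    with pytest.raises(ValueError):
        RegressionSpec(outcome="y", transform="sqrt")


# ---------------------------------------------------------------------------
# Sampler correctness against classical oracles
# ---------------------------------------------------------------------------

def test_normal_flat_limit_matches_ols(rng):
    """Broad priors + fixed normal residuals + no random intercept
    reproduce ordinary least squares."""
    df = make_data(rng, n_subj=100, beta_x=0.8, beta_int=0.3)
    spec = RegressionSpec(
        outcome="y", continuous=("x",), factors=("level",),
        interactions=(("x", "level"),), random_intercept=False,
        prior_overrides={"x": "broad"})
    pri = PriorConfig(nu_fixed=np.inf)
    fit = fit_model(spec, df, priors=pri, settings=FAST)
    des = fit.design
    ols = np.linalg.lstsq(des.X, des.y, rcond=None)[0]
    post_mean = fit.coef.reshape(-1, fit.coef.shape[-1]).mean(axis=0)
    # prior sd is 100 in sd units, so the posterior mean is OLS to ~1e-3
    np.testing.assert_allclose(post_mean, ols, atol=0.02)
    # posterior sd matches the classical standard errors
    resid = des.y - des.X @ ols
    s2 = resid @ resid / (len(des.y) - des.X.shape[1])
    se = np.sqrt(np.diag(s2 * np.linalg.inv(des.X.T @ des.X)))
    post_sd = fit.coef.reshape(-1, fit.coef.shape[-1]).std(axis=0)
    np.testing.assert_allclose(post_sd, se, rtol=0.25)


def test_mixed_model_matches_statsmodels_mixedlm(rng):
    """With a real random intercept, posterior means track REML estimates."""
    import statsmodels.formula.api as smf

    df = make_data(rng, n_subj=80, beta_x=1.0, subject_sd=1.0, resid_sd=0.8)
    spec = RegressionSpec(outcome="y", continuous=("x",), factors=("level",),
                          prior_overrides={"x": "broad"})
    fit = fit_model(spec, df, priors=PriorConfig(nu_fixed=np.inf),
                    settings=FAST)
    des = fit.design
    sm_df = pd.DataFrame({"y": des.y, "x": des.X[:, des.names.index("x")],
                          "lev": des.X[:, des.names.index("level[40]")],
                          "subject": df["subject"]})
    m = smf.mixedlm("y ~ x + lev", sm_df, groups=sm_df["subject"]).fit()
    flat = fit.coef.reshape(-1, fit.coef.shape[-1])
    assert flat[:, des.names.index("x")].mean() == pytest.approx(
        m.params["x"], abs=m.bse["x"] + 0.03)
    assert flat[:, des.names.index("level[40]")].mean() == pytest.approx(
        m.params["lev"], abs=0.03)
    # random-intercept scale is recovered too
    tau_hat = np.median(fit.tau)
    tau_reml = np.sqrt(m.cov_re.iloc[0, 0])
    assert tau_hat == pytest.approx(tau_reml, rel=0.35)


def test_shrinkage_prior_pulls_noise_toward_zero(rng):
    """A true-zero coefficient under shrinkage gets a smaller posterior
    magnitude than the same coefficient under the broad prior."""
    df = make_data(rng, n_subj=25, beta_x=0.0, resid_sd=1.0)
    base = dict(outcome="y", continuous=("x",), random_intercept=False)
    f_shr = fit_model(RegressionSpec(**base), df, settings=FAST)
    f_brd = fit_model(RegressionSpec(**base, prior_overrides={"x": "broad"}),
                      df, settings=FAST)
    m_shr = abs(np.median(f_shr.coef_flat("x")))
    m_brd = abs(np.median(f_brd.coef_flat("x")))
    assert m_shr <= m_brd + 1e-6


def test_diagnostics_flag_when_floors_unmet(rng):
    df = make_data(rng, n_subj=20)
    spec = RegressionSpec(outcome="y", continuous=("x",),
                          random_intercept=False)
    settings = FitSettings(n_chains=2, n_warmup=20, n_draws=50,
                           ess_floor=1e7, rhat_max=1.0001, seed=0)
    with pytest.warns(UserWarning, match="diagnostic floors"):
        fit = fit_model(spec, df, settings=settings)
    assert not fit.converged


# ---------------------------------------------------------------------------
# Summaries and contrasts
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def demo_fit():
    rng = np.random.default_rng(7)
    df = make_data(rng, n_subj=60, beta_x=1.0, beta_int=0.4, subject_sd=0.5)
    spec = RegressionSpec(outcome="y", continuous=("x",), factors=("level",),
                          interactions=(("x", "level"),))
    return fit_model(spec, df, settings=FAST), df


def test_summarize_ci_against_quantile_oracle(demo_fit):
    fit, _ = demo_fit
    ci = summarize_ci(fit, level=0.99).set_index("name")
    for i, nm in enumerate(fit.names):
        draws = np.sort(fit.coef[:, :, i].reshape(-1))
        lo, hi = np.quantile(draws, [0.005, 0.995])
        assert ci.loc[nm, "ci_lo"] == pytest.approx(lo, abs=1e-9)
        assert ci.loc[nm, "ci_hi"] == pytest.approx(hi, abs=1e-9)
        assert ci.loc[nm, "median"] == pytest.approx(np.median(draws),
                                                     abs=1e-9)
        assert ci.loc[nm, "credible"] == bool(lo > 0 or hi < 0)


def test_contrast_draws_linearity(demo_fit):
    fit, _ = demo_fit
    d = contrast_draws(fit, {"x": 2.0, "x:level[40]": -1.0})
    oracle = 2.0 * fit.coef_flat("x") - fit.coef_flat("x:level[40]")
    np.testing.assert_allclose(d, oracle, atol=1e-12)
    with pytest.raises(ValueError):
        contrast_draws(fit, {"nope": 1.0})
    with pytest.raises(ValueError):
        contrast_draws(fit, {})


def test_covariate_slopes_by_factor_oracle(demo_fit):
    fit, _ = demo_fit
    des = fit.design
    per = 10.0
    con = covariate_slopes_by_factor(fit, "x", "level", per=per)
    unit = des.y_sd / des.x_sds["x"] * per
    main = fit.coef_flat("x")
    inter = fit.coef_flat("x:level[40]")
    # level 40 coded +1, level 80 (reference) coded -1
    slope_40 = (main + inter) * unit
    slope_80 = (main - inter) * unit
    row40 = con[con["contrast"] == "x@level=40"].iloc[0]
    row80 = con[con["contrast"] == "x@level=80"].iloc[0]
    diff = con[con["contrast"] == "x@level:80-40"].iloc[0]
    assert row40["median"] == pytest.approx(np.median(slope_40), abs=1e-9)
    assert row80["median"] == pytest.approx(np.median(slope_80), abs=1e-9)
    assert diff["median"] == pytest.approx(np.median(slope_80 - slope_40),
                                           abs=1e-9)
    lo, hi = np.quantile(slope_40, [0.005, 0.995])
    assert row40["ci_lo"] == pytest.approx(lo, abs=1e-9)
    assert row40["ci_hi"] == pytest.approx(hi, abs=1e-9)


def test_covariate_slopes_recover_generating_values(demo_fit):
    fit, _ = demo_fit
    # generating: y = 1.0*x + 0.4*code*x, so slope at level 40 is 1.4,
    # at level 80 is 0.6, per 1 raw unit of x
    con = covariate_slopes_by_factor(fit, "x", "level", per=1.0)
    row40 = con[con["contrast"] == "x@level=40"].iloc[0]
    row80 = con[con["contrast"] == "x@level=80"].iloc[0]
    assert row40["median"] == pytest.approx(1.4, abs=0.25)
    assert row80["median"] == pytest.approx(0.6, abs=0.25)


def test_covariate_slopes_validation(demo_fit):
    fit, _ = demo_fit
    with pytest.raises(ValueError):
        covariate_slopes_by_factor(fit, "x", "nofactor")
    with pytest.raises(ValueError):
        covariate_slopes_by_factor(fit, "nocov", "level")


def test_log_outcome_exponentiated_contrasts(rng):
    df = make_data(rng, n_subj=40, beta_x=0.5)
    df["y"] = np.exp(df["y"] / 4)
    spec = RegressionSpec(outcome="y", continuous=("x",), factors=("level",),
                          interactions=(("x", "level"),), transform="log")
    fit = fit_model(spec, df, settings=FAST)
    con = covariate_slopes_by_factor(fit, "x", "level", per=1.0)
    assert {"factor_median", "factor_ci_lo", "factor_ci_hi"} <= \
        set(con.columns)
    row = con.iloc[0]
    assert row["factor_median"] == pytest.approx(np.exp(row["median"]),
                                                 rel=1e-9)


def test_factor_level_shifts_sum_to_zero(demo_fit):
    fit, _ = demo_fit
    shifts = factor_level_shifts(fit, "level")
    assert shifts["median"].sum() == pytest.approx(0.0, abs=1e-9)
    # generating level effect: +-0.5 in raw units
    lev40 = shifts[shifts["level"] == 40]["median"].iloc[0]
    assert lev40 == pytest.approx(0.5, abs=0.2)
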