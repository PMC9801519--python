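"""Exact BMA engine: enumeration, closed forms, averaging, grading.

The heavier numerical checks use independent oracles: direct 2-D
quadrature of likelihood x prior for the marginal likelihood, 50-digit
arithmetic for probability normalisation, and a from-scratch loop over
all models (least squares + explicit weighting) for the averaged
summaries.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import (
    brute_force_bma as _brute_force_bma,
    log_marginal_null_quadrature as _log_marginal_null_quadrature,
    log_marginal_quadrature as _log_marginal_quadrature,
)
from bma_vision import (
    ModelIndex,
    ModelSpaceError,
    PriorSettings,
    SingularModelError,
    StudyTable,
    average,
    classify_evidence,
    enumerate_models,
    fit_all_models,
    fit_model,
    model_size_distribution,
    posterior_model_probs,
    run_bma,
    validate_and_center,
)

# ---------------------------------------------------------------- enumeration


@pytest.mark.parametrize("s,count", [(1, 2), (3, 8), (5, 32)])
def test_enumeration_counts(s, count):
    models = enumerate_models(s)
    assert len(models) == count
    assert len(set(models)) == count  # no duplicates
    assert models[0].included == ()  # null model first
    assert models[-1].included == tuple(range(s))  # full model last


def test_enumeration_order_by_size_then_lex():
    models = enumerate_models(3)
    assert [m.included for m in models] == [
        (),
        (0,),
        (1,),
        (2,),
        (0, 1),
        (0, 2),
        (1, 2),
        (0, 1, 2),
    ]


@pytest.mark.parametrize("s", [0, -1, 26])
def test_enumeration_rejects_bad_sizes(s):
    with pytest.raises(ModelSpaceError):
        enumerate_models(s)


def test_model_index_rejects_duplicates_and_negatives():
    with pytest.raises(ModelSpaceError):
        ModelIndex((1, 1))
    with pytest.raises(ModelSpaceError):
        ModelIndex((-1,))


# ------------------------------------------------------------------ fit_model


def test_null_model_has_zero_r_squared(make_table):
    centered, _ = validate_and_center(make_table(seed=5))
    fit = fit_model(centered, ModelIndex(()), PriorSettings())
    assert fit.r_squared == 0.0
    assert fit.coef_mean.size == 0 and fit.coef_var.size == 0
    assert np.isfinite(fit.log_marginal)


def test_single_covariate_g1_gives_half_ols_slope(make_table):
    """With g=1 the shrinkage factor g/(1+g) is exactly one half."""
    centered, _ = validate_and_center(make_table(seed=6, s=1, beta=[0.4]))
    x = centered.covariates[:, 0]
    ols = float(x @ centered.outcome / (x @ x))
    fit = fit_model(centered, ModelIndex((0,)), PriorSettings("fixed", g=1.0))
    assert fit.coef_mean[0] == pytest.approx(0.5 * ols, abs=1e-12)


def test_shrinkage_matches_statsmodels_ols(make_table):
    """Conditional means are g/(1+g) times the OLS estimates, any model."""
    import statsmodels.api as sm

    centered, _ = validate_and_center(
        make_table(seed=7, n=35, s=4, beta=[0.3, 0.0, -0.2, 0.1])
    )
    prior = PriorSettings()
    g = prior.resolve_g(centered.n, centered.s)
    for model in enumerate_models(4)[1:]:
        x = centered.covariates[:, list(model.included)]
        ols = sm.OLS(centered.outcome, x).fit()
        fit = fit_model(centered, model, prior)
        np.testing.assert_allclose(
            fit.coef_mean, g / (1 + g) * ols.params, atol=1e-8
        )


def test_log_marginal_matches_quadrature_on_tiny_table():
    """Closed form equals brute 2-D integration of likelihood x prior."""
    gen = np.random.default_rng(99)
    n = 8
    x = gen.normal(0, 1, n)
    y = 0.5 * x + gen.normal(0, 0.8, n)
    x = x - x.mean()
    y = y - y.mean()
    table = StudyTable(outcome=y, covariates=x[:, None], names=("x0",))
    for g in (1.0, 4.0, float(n)):
        fit = fit_model(table, ModelIndex((0,)), PriorSettings("fixed", g=g))
        oracle = _log_marginal_quadrature(y, x, g)
        assert fit.log_marginal == pytest.approx(oracle, abs=1e-5)
    null = fit_model(table, ModelIndex(()), PriorSettings("fixed", g=1.0))
    assert null.log_marginal == pytest.approx(_log_marginal_null_quadrature(y), abs=1e-5)


def test_collinear_model_rejected(rng):
    x = rng.normal(size=(30, 3))
    x[:, 2] = x[:, 0] + x[:, 1]  # exact collinearity inside the full model
    y = rng.normal(size=30)
    # raw columns have nonzero variance, so the table itself is valid
    table = StudyTable(outcome=y - y.mean(), covariates=x - x.mean(0), names=("a", "b", "c"))
    with pytest.raises(SingularModelError):
        fit_model(table, ModelIndex((0, 1, 2)), PriorSettings())


# -------------------------------------------------------- posterior_model_probs


def test_pmp_equal_and_analytic_ratios(make_table):
    centered, _ = validate_and_center(make_table(seed=8))
    fit = fit_model(centered, ModelIndex(()), PriorSettings())

    def with_logml(lm):
        return type(fit)(**{**fit.__dict__, "log_marginal": lm})

    pmp = posterior_model_probs([with_logml(3.0), with_logml(3.0)])
    np.testing.assert_allclose(pmp, [0.5, 0.5], atol=1e-15)
    pmp = posterior_model_probs([with_logml(math.log(3.0)), with_logml(0.0)])
    np.testing.assert_allclose(pmp, [0.75, 0.25], atol=1e-12)


def test_pmp_matches_50_digit_normalisation(make_table):
    """Log-sum-exp normalisation agrees with extended-precision arithmetic."""
    import sympy

    gen = np.random.default_rng(2718)
    log_ml = gen.uniform(-350.0, 350.0, size=32)
    centered, _ = validate_and_center(make_table(seed=9))
    base = fit_model(centered, ModelIndex(()), PriorSettings())
    fits = [type(base)(**{**base.__dict__, "log_marginal": lm}) for lm in log_ml]
    pmp = posterior_model_probs(fits)

    exact = [sympy.exp(sympy.Float(lm, 50)) for lm in log_ml]
    total = sum(exact)
    oracle = np.array([float(e / total) for e in exact])
    np.testing.assert_allclose(pmp, oracle, atol=1e-12)
    assert abs(pmp.sum() - 1.0) < 1e-12


def test_pmp_survives_extreme_spreads(make_table):
    centered, _ = validate_and_center(make_table(seed=10))
    base = fit_model(centered, ModelIndex(()), PriorSettings())
    fits = [
        type(base)(**{**base.__dict__, "log_marginal": lm})
        for lm in (-700.0, 0.0, 700.0)
    ]
    pmp = posterior_model_probs(fits)
    assert np.all(np.isfinite(pmp))
    assert pmp[2] == pytest.approx(1.0)
    assert pmp.sum() == pytest.approx(1.0, abs=1e-12)


def test_pmp_empty_list_rejected():
    with pytest.raises(ModelSpaceError):
        posterior_model_probs([])


# -------------------------------------------------------------------- average


def test_average_matches_brute_force_loop(make_table):
    """pip/post_mean/post_sd agree with an independent all-models loop."""
    table = make_table(seed=11, n=40, s=3, beta=[0.5, 0.0, -0.3], noise_sd=0.8)
    centered, _ = validate_and_center(table)
    prior = PriorSettings()
    g = prior.resolve_g(centered.n, centered.s)
    result = run_bma(table, prior)
    w, pip, post_mean, post_sd = _brute_force_bma(
        centered.outcome, centered.covariates, g
    )
    np.testing.assert_allclose(result.pmp, w, atol=1e-8)
    np.testing.assert_allclose(result.pip, pip, atol=1e-8)
    np.testing.assert_allclose(result.post_mean, post_mean, atol=1e-8)
    np.testing.assert_allclose(result.post_sd, post_sd, atol=1e-8)


def test_pip_is_sum_of_pmp_over_including_models(make_table):
    result = run_bma(make_table(seed=12, n=60, s=4, beta=[0.2, 0, 0, 0.4]))
    for j in range(4):
        direct = sum(
            w for w, m in zip(result.pmp, result.models) if j in m
        )
        assert result.pip[j] == pytest.approx(direct, abs=1e-12)


def test_single_model_inclusion_weights_posterior_mean(make_table):
    """A variable carried by models of total weight w contributes w times
    its conditional mean to the averaged mean."""
    table = make_table(seed=13, n=50, s=2, beta=[0.8, 0.0], noise_sd=0.5)
    centered, _ = validate_and_center(table)
    prior = PriorSettings()
    models = enumerate_models(2)
    fits = fit_all_models(centered, models, prior)
    pmp = posterior_model_probs(fits)
    result = average(fits, pmp, table.names)
    expected = sum(
        w * f.coef_mean[list(f.model.included).index(0)]
        for w, f in zip(pmp, fits)
        if 0 in f.model
    )
    assert result.post_mean[0] == pytest.approx(expected, abs=1e-14)


def test_column_permutation_permutes_results(make_table):
    table = make_table(seed=14, n=45, s=3, beta=[0.4, -0.2, 0.0])
    perm = [2, 0, 1]
    permuted = StudyTable(
        outcome=table.outcome,
        covariates=table.covariates[:, perm],
        names=tuple(table.names[j] for j in perm),
    )
    r1 = run_bma(table)
    r2 = run_bma(permuted)
    for j_new, j_old in enumerate(perm):
        assert r2.pip[j_new] == pytest.approx(r1.pip[j_old], abs=1e-12)
        assert r2.post_mean[j_new] == pytest.approx(r1.post_mean[j_old], abs=1e-12)
        assert r2.post_sd[j_new] == pytest.approx(r1.post_sd[j_old], abs=1e-12)


def test_within_model_variance_flag_understates_spread(make_table):
    """The naive average of within-model variances omits between-model
    dispersion, so it can only narrow the reported SD."""
    table = make_table(seed=15, n=40, s=3, beta=[0.5, 0.1, 0.0])
    full = run_bma(table)
    naive = run_bma(table, within_model_variance_only=True)
    assert np.all(naive.post_sd <= full.post_sd + 1e-14)
    assert np.any(naive.post_sd < full.post_sd - 1e-12)


def test_sign_consistency_bounds_and_never_included_convention(make_table):
    result = run_bma(make_table(seed=16, n=80, s=3, beta=[1.5, 0.0, 0.0], noise_sd=0.3))
    assert np.all(result.sign_consistency >= 0.0)
    assert np.all(result.sign_consistency <= 1.0)
    # overwhelming positive effect: sign essentially certain
    assert result.sign_consistency[0] > 0.99
    # a variable in no model at all reports 1.0 by convention
    centered, _ = validate_and_center(make_table(seed=16, n=80, s=3))
    prior = PriorSettings()
    models = [m for m in enumerate_models(3) if 2 not in m]
    fits = fit_all_models(centered, models, prior)
    pmp = posterior_model_probs(fits)
    res = average(fits, pmp, centered.names)
    assert res.pip[2] == 0.0
    assert res.sign_consistency[2] == 1.0


def test_lindley_effect_null_model_dominates_as_g_grows(make_table):
    """On fixed data, ever-larger prior scales push all mass to the null
    model (the Lindley/Bartlett effect of the g prior)."""
    table = make_table(seed=17, n=50, s=3, beta=[0.3, 0.0, 0.0], noise_sd=0.8)
    centered, _ = validate_and_center(table)
    models = enumerate_models(3)
    null_pmps = []
    for g in (1e2, 1e4, 1e8):
        fits = fit_all_models(centered, models, PriorSettings("fixed", g=g))
        pmp = posterior_model_probs(fits)
        null_pmps.append(pmp[0])
    assert null_pmps[0] <= null_pmps[1] <= null_pmps[2]
    assert null_pmps[2] > 0.9


# ----------------------------------------------------------- evidence grading


@pytest.mark.parametrize(
    "pip,grade",
    [
        (0.0431452, "none"),  # primary-stage exercise territory
        (0.49999, "none"),
        (0.5, "weak"),  # left-closed boundary
        (0.74999, "weak"),
        (0.75, "positive"),
        (0.94999, "positive"),
        (0.95, "strong"),
        (0.9736, "strong"),  # junior-stage exercise territory
        (1.0, "strong"),
    ],
)
def test_evidence_bands(pip, grade):
    assert classify_evidence(pip) == grade


@pytest.mark.parametrize("bad", [-0.1, 1.0001, float("nan")])
def test_evidence_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        classify_evidence(bad)


# ----------------------------------------------------- model size distribution


def test_size_distribution_concentrated_and_uniform_cases():
    models = enumerate_models(2)
    conc = np.array([1.0, 0.0, 0.0, 0.0])
    np.testing.assert_allclose(model_size_distribution(conc, models), [1, 0, 0])
    uniform = np.full(4, 0.25)
    np.testing.assert_allclose(
        model_size_distribution(uniform, models), [0.25, 0.5, 0.25]
    )


def test_size_distribution_mode_at_one_for_single_effect(make_table):
    """A single strong predictor puts the posterior size mode at 1."""
    table = make_table(seed=18, n=2000, s=5, beta=[0.3, 0, 0, 0, 0], noise_sd=0.6)
    result = run_bma(table)
    assert int(np.argmax(result.size_distribution)) == 1
    assert result.size_distribution.sum() == pytest.approx(1.0, abs=1e-10)


# ------------------------------------------------------------- property tests


@given(
    seed=st.integers(0, 2**20),
    s=st.integers(1, 4),
    n_extra=st.integers(5, 40),
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_probability_invariants_hold_for_random_tables(seed, s, n_extra):
    gen = np.random.default_rng(seed)
    n = s + 3 + n_extra
    x = gen.normal(size=(n, s))
    y = gen.normal(size=n)
    table = StudyTable(outcome=y, covariates=x, names=tuple(f"v{j}" for j in range(s)))
    result = run_bma(table)
    assert abs(result.pmp.sum() - 1.0) < 1e-10
    assert abs(result.size_distribution.sum() - 1.0) < 1e-10
    assert np.all((result.pip >= 0) & (result.pip <= 1))
    for j in range(s):
        direct = sum(w for w, m in zip(result.pmp, result.models) if j in m)
        assert result.pip[j] == pytest.approx(direct, abs=1e-10)
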