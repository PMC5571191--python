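import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import peakeffort as pe
from peakeffort.glmm import ModelSpec, parse_term

from conftest import glmm_population


class TestModelSpec:
    def test_term_parsing(self):
        assert parse_term("x") == ("lin", ("x",))
        assert parse_term("x^2") == ("quad", ("x",))
        assert parse_term("a:b") == ("inter", ("a", "b"))

    @pytest.mark.parametrize("terms", [("x^2",), ("a:b", "a"), ("x", "y^2")])
    def test_marginality_enforced_at_construction(self, terms):
        with pytest.raises(ValueError):
            ModelSpec("y", "poisson", terms)

    def test_removable_terms_respect_marginality(self):
        spec = ModelSpec("y", "poisson", ("x", "x^2", "z", "x:z", "w"))
        assert set(spec.removable_terms()) == {"x^2", "x:z", "w"}


class TestGLMOracle:
    """With the random-effect variance forced to zero the Laplace fit must
    collapse onto an ordinary GLM; statsmodels' IRLS is the oracle."""

    def test_gaussian_reduces_to_ols(self):
        df = glmm_population(3, family="gaussian")
        fit = pe.fit_glmm(ModelSpec("y", "gaussian", ("x",)), df,
                          fix_sd={"cohort": 0.0}, satterthwaite=False)
        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        np.testing.assert_allclose(fit.beta, ols.params, atol=1e-6)
        # ML sigma^2 = RSS/n (no df correction); sigma found numerically
        assert abs(fit.sigma ** 2 - ols.ssr / len(df)) < 1e-4

    def test_binomial_matches_logit_glm(self):
        df = glmm_population(4, family="binomial")
        fit = pe.fit_glmm(ModelSpec("y", "binomial", ("x",)), df,
                          fix_sd={"cohort": 0.0})
        glm = sm.GLM(df["y"], sm.add_constant(df["x"]),
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, glm.bse, rtol=1e-4)


def test_quadratic_design_is_scale_then_square():
    rng = np.random.default_rng(5)
    x = rng.gamma(4.0, 1.5, 300)
    df = pd.DataFrame({"y": rng.poisson(2.0, 300), "x": x, "cohort": 0})
    spec = ModelSpec("y", "poisson", ("x", "x^2"), "none", scaled_vars=("x",))
    X, names, infos = pe.build_design(spec, df)
    xs = (x - infos["x"].mean) / infos["x"].sd
    np.testing.assert_allclose(X[:, 1], xs)
    np.testing.assert_allclose(X[:, 2], xs ** 2)


def test_scaling_equivariance_of_slopes():
    """Fixed-effects Poisson fit on scaled x equals the raw-x slope times
    the sample SD (intercept shifts by the mean term)."""
    df = glmm_population(6)
    raw = pe.fit_glmm(ModelSpec("y", "poisson", ("x",), "none"), df)
    scl = pe.fit_glmm(ModelSpec("y", "poisson", ("x",), "none",
                                scaled_vars=("x",)), df)
    sd = scl.scaling_info["x"].sd
    assert abs(scl.coef("x") - raw.coef("x") * sd) < 1e-6


def test_likelihood_never_drops_when_adding_a_term():
    df = glmm_population(8)
    df["z"] = np.random.default_rng(9).normal(size=len(df))
    small = pe.fit_glmm(ModelSpec("y", "poisson", ("x",)), df)
    large = pe.fit_glmm(ModelSpec("y", "poisson", ("x", "z")), df)
    assert large.log_likelihood >= small.log_likelihood - 1e-6


def test_nb_limit_recovers_poisson_fit():
    """On Poisson-generated data the free-theta NB fit drives theta large;
    with theta pinned at a huge value the NB coefficients coincide with
    the Poisson GLMM's (the mathematical limit)."""
    df = glmm_population(10, family="poisson")
    pois = pe.fit_glmm(ModelSpec("y", "poisson", ("x",)), df)
    nb_free = pe.fit_glmm(ModelSpec("y", "negative_binomial", ("x",)), df)
    assert nb_free.nb_dispersion > 50
    nb_limit = pe.fit_glmm(ModelSpec("y", "negative_binomial", ("x",)), df,
                           fix_theta=1e8)
    np.testing.assert_allclose(nb_limit.beta, pois.beta, atol=1e-3)


def test_nb_theta_recovery_within_30_percent():
    df = glmm_population(11, n=2000, family="negative_binomial", theta=10.0)
    fit = pe.fit_glmm(ModelSpec("y", "negative_binomial", ("x",)), df)
    assert 7.0 <= fit.nb_dispersion <= 13.0


def test_degenerate_and_invalid_inputs_error():
    df = glmm_population(12)
    df["const"] = 3.0
    with pytest.raises(ValueError):                    # constant response
        pe.fit_glmm(ModelSpec("const", "poisson", ("x",)), df)
    with pytest.raises(ValueError):                    # non-binary response
        pe.fit_glmm(ModelSpec("y", "binomial", ("x",)), df)
    with pytest.raises(ValueError):                    # missing column
        pe.fit_glmm(ModelSpec("y", "poisson", ("nope",)), df)
    with pytest.raises(ValueError):                    # empty data
        pe.fit_glmm(ModelSpec("y", "poisson", ("x",)), df.iloc[:0])


class TestBackwardSelection:
    def test_all_significant_spec_unchanged(self):
        df = glmm_population(13, beta1=0.8)
        spec = ModelSpec("y", "poisson", ("x",))
        final, fit, trace = pe.backward_select(spec, df)
        assert final == spec and trace == []

    def test_null_quadratic_dropped_before_linear(self):
        df = glmm_population(14, n=1000, beta1=0.5)
        spec = ModelSpec("y", "poisson", ("x", "x^2"), scaled_vars=("x",))
        final, fit, trace = pe.backward_select(spec, df)
        assert "x" in final.fixed_terms
        assert "x^2" not in final.fixed_terms
        assert trace[0]["dropped"] == "x^2"

    def test_null_quadratic_retention_matches_alpha(self):
        """A truly-zero quadratic should survive selection in roughly
        alpha = 5% of replicates (type-I error of the drop rule)."""
        kept = 0
        n_rep = 40
        for s in range(n_rep):
            df = glmm_population(200 + s, n=1000, q=15, beta1=0.4, sd=0.15)
            final, _, _ = pe.backward_select(
                ModelSpec("y", "poisson", ("x", "x^2"), scaled_vars=("x",)), df)
            kept += "x^2" in final.fixed_terms
        assert kept / n_rep <= 0.15


class TestWaldTests:
    def test_zero_coefficient_gives_p_one(self):
        fit = pe.fit_glmm(ModelSpec("y", "poisson", ("x",), "none"),
                          glmm_population(15))
        fit.beta[1] = 0.0
        from peakeffort.glmm import _fill_wald
        _fill_wald(fit)
        assert fit.p_value[1] == 1.0

    def test_null_predictor_p_values_uniform(self):
        """Under H0 the Wald p for an unrelated predictor is Uniform(0,1)
        (KS test at the 1% level over 200 replicates)."""
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            n = 150
            x = rng.normal(size=n)
            y = rng.poisson(2.0, n)
            df = pd.DataFrame({"y": y, "x": x, "cohort": 0})
            fit = pe.fit_glmm(ModelSpec("y", "poisson", ("x",), "none"), df)
            pvals.append(fit.p_value[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_satterthwaite_df_close_to_balanced_anova_df(self):
        """Balanced one-way Gaussian design: the between-groups predictor is
        confounded with the random intercept, so dfs are small; a unit-level
        predictor keeps near-residual df."""
        rng = np.random.default_rng(21)
        q, m = 12, 25
        g = np.repeat(np.arange(q), m)
        x = rng.normal(size=q * m)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.5, q)[g] + rng.normal(0, 1, q * m)
        df = pd.DataFrame({"y": y, "x": x, "cohort": g})
        fit = pe.fit_glmm(ModelSpec("y", "gaussian", ("x",)), df)
        assert fit.df_method == "satterthwaite"
        j = fit.terms.index("x")
        assert fit.df[j] > 0.5 * (q * m)       # unit-level slope: large df
        assert fit.df[fit.terms.index("(Intercept)")] < 3 * q


class TestBootstrap:
    def test_matches_analytic_ci_for_fixed_effects_gaussian(self):
        df = glmm_population(16, n=400, family="gaussian")
        fit = pe.fit_glmm(ModelSpec("y", "gaussian", ("x",), "none"), df,
                          satterthwaite=False)
        wald_lo, wald_hi = fit.ci_low.copy(), fit.ci_high.copy()
        pe.bootstrap_ci(fit, n_boot=2000, seed=4)
        for j in range(len(fit.beta)):
            w = wald_hi[j] - wald_lo[j]
            assert abs((fit.ci_high[j] - fit.ci_low[j]) - w) < 0.10 * w
            assert abs(fit.ci_low[j] - wald_lo[j]) < 0.10 * w
        assert fit.ci_method == "parametric_bootstrap"

    def test_zero_iterations_rejected(self):
        df = glmm_population(17)
        fit = pe.fit_glmm(ModelSpec("y", "poisson", ("x",), "none"), df)
        with pytest.raises(ValueError):
            pe.bootstrap_ci(fit, n_boot=0, seed=1)
        with pytest.raises(ValueError):
            pe.bootstrap_ci(fit, n_boot=10, seed=None)

    def test_seeded_reproducibility(self):
        df = glmm_population(18)
        spec = ModelSpec("y", "poisson", ("x",))
        f1 = pe.fit_glmm(spec, df)
        f2 = pe.fit_glmm(spec, df)
        pe.bootstrap_ci(f1, n_boot=40, seed=5)
        pe.bootstrap_ci(f2, n_boot=40, seed=5)
        np.testing.assert_array_equal(f1.ci_low, f2.ci_low)


class TestPrediction:
    def test_identity_link_predictions_equal_linear_predictor(self):
        df = glmm_population(19, family="gaussian")
        fit = pe.fit_glmm(ModelSpec("y", "gaussian", ("x",), "none"), df,
                          satterthwaite=False)
        grid = np.linspace(-2, 2, 5)
        pred = pe.predict_curve(fit, "x", grid)
        np.testing.assert_allclose(pred["response"], pred["eta"])
        np.testing.assert_allclose(
            pred["eta"], fit.beta[0] + fit.beta[1] * grid)

    def test_log_link_closed_form(self):
        df = glmm_population(20)
        fit = pe.fit_glmm(ModelSpec("y", "poisson", ("x",), "none"), df)
        fit.beta = np.array([0.0, 1.0])
        pred = pe.predict_curve(fit, "x", np.array([1.0]))
        assert abs(pred["response"].iloc[0] - np.e) < 1e-12

    def test_unknown_covariate_rejected(self):
        df = glmm_population(22)
        fit = pe.fit_glmm(ModelSpec("y", "poisson", ("x",), "none"), df)
        with pytest.raises(ValueError):
            pe.predict_curve(fit, "x", np.array([0.0]), at={"bogus": 1.0})


class TestVertex:
    def _fit_with(self, b1, b2):
        df = glmm_population(23)
        fit = pe.fit_glmm(
            ModelSpec("y", "poisson", ("x", "x^2"), "none", scaled_vars=("x",)),
            df)
        fit.beta[fit.terms.index("x")] = b1
        fit.beta[fit.terms.index("x^2")] = b2
        return fit

    def test_reported_coefficients_give_reported_optimum(self):
        # the lifetime-pups coefficients: scaled vertex -b1/(2 b2)
        fit = self._fit_with(0.454, -0.061)
        v = pe.vertex_in_natural_units(fit, "x")
        assert v.has_maximum
        assert abs(v.scaled_vertex - 3.7213) < 1e-3
        info = fit.scaling_info["x"]
        assert abs(v.natural_vertex - (info.mean + info.sd * 3.72131)) < 1e-3

    def test_zero_linear_term_peaks_at_predictor_mean(self):
        fit = self._fit_with(0.0, -0.5)
        v = pe.vertex_in_natural_units(fit, "x")
        assert v.scaled_vertex == 0.0
        assert abs(v.natural_vertex - fit.scaling_info["x"].mean) < 1e-12

    def test_convex_fit_has_no_interior_maximum(self):
        fit = self._fit_with(0.3, 0.02)
        v = pe.vertex_in_natural_units(fit, "x")
        assert not v.has_maximum and np.isnan(v.natural_vertex)


def test_variance_param_ci_covers_in_simple_case():
    df = glmm_population(24, n=1500, sd=0.4)
    fit = pe.fit_glmm(ModelSpec("y", "poisson", ("x",)), df)
    ci = pe.variance_param_ci(fit)
    lo, hi = ci["cohort"]
    assert lo < 0.16 < hi        # true cohort variance 0.4^2
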