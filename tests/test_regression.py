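"""Confounder regression: Poisson GLM, deviance residuals, OLS,
standardisation and the residual pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netconsist import (SyntheticScenario, deviance_residuals,
                        fit_linear_model, fit_poisson_glm, generate_covariates,
                        render_count_platform, residual_pipeline, simulate,
                        standardize)
from netconsist.regression import COUNT_COVARIATES, build_design

from ._oracles import ols_normal_equations, poisson_loglik_optimizer


class TestPoissonGLM:
    def test_intercept_only_mle_is_log_mean(self):
        fit = fit_poisson_glm(np.array([1, 2, 3]),
                              pd.DataFrame(index=range(3)))
        assert fit.coefficients["intercept"] == pytest.approx(np.log(2),
                                                              abs=1e-8)

    def test_offset_exact_rate(self):
        n_j = np.array([10, 20, 40, 80])
        y = 2 * n_j
        fit = fit_poisson_glm(y, pd.DataFrame(index=range(4)),
                              offset=np.log(n_j))
        assert fit.coefficients["intercept"] == pytest.approx(np.log(2),
                                                              abs=1e-8)
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)

    def test_matches_generic_likelihood_optimizer(self, rng):
        n = 200
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        offset = rng.uniform(1, 2, n)
        eta = 1.0 + 0.3 * X["x1"].to_numpy() - 0.2 * X["x2"].to_numpy()
        y = rng.poisson(np.exp(eta + offset))
        fit = fit_poisson_glm(y, X, offset=offset)
        design = np.column_stack([np.ones(n), X.to_numpy()])
        beta_opt = poisson_loglik_optimizer(y, design, offset)
        assert np.allclose(fit.coefficients.to_numpy(), beta_opt, atol=1e-6)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        n = 150
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = rng.poisson(np.exp(0.5 + 0.4 * X["x"].to_numpy()))
        fit = fit_poisson_glm(y, X)
        design = sm.add_constant(X.to_numpy())
        sm_fit = sm.GLM(y, design, family=sm.families.Poisson()).fit()
        assert np.allclose(fit.coefficients.to_numpy(), sm_fit.params,
                           atol=1e-7)

    def test_recovers_generator_age_effect(self):
        # counts rendered with a known age coefficient; GLM recovers it
        sc = SyntheticScenario(
            p=12, n=500, seed=21,
            confounder_effects_count={"age": 0.01},
        )
        cov = generate_covariates(500, seed=21)
        z = np.zeros((12, 500))
        counts = render_count_platform(z, cov, sc, scales=np.ones(12))
        # the rendered age coefficients are N(0, 0.01); refit each gene with
        # the true design and compare against the realised coefficients
        from netconsist.synthetic import _draw_effects
        seeds = sc.stage_seeds()
        betas = _draw_effects(sc, "counts",
                              np.random.default_rng(seeds["effects_count"]))
        X = build_design(cov, ["age"])[["age"]]
        offset = np.log(cov["library_size"].to_numpy(dtype=float))
        for i in range(12):
            fit = fit_poisson_glm(counts.iloc[i].to_numpy(), X, offset)
            assert fit.coefficients["age"] == pytest.approx(
                betas["age"].iloc[i], abs=0.005)

    def test_rank_deficient_design_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="collinear"):
            fit_poisson_glm(np.array([1, 2, 3, 4]), X)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_poisson_glm(np.array([1, -1, 2]), pd.DataFrame(index=range(3)))


class TestDevianceResiduals:
    @pytest.mark.parametrize("y,mu,expected", [
        (5.0, 5.0, 0.0),
        (0.0, 2.0, -2.0),  # y=0 convention leaves 2*mu under the root
        (4.0, 2.0, np.sqrt(8 * np.log(2) - 4)),
    ])
    def test_exact_values(self, y, mu, expected):
        d = deviance_residuals(np.array([y]), np.array([mu]))[0]
        assert d == pytest.approx(expected, abs=1e-10)

    def test_sign_matches_raw_residual(self, rng):
        y = rng.poisson(10.0, 500).astype(float)
        mu = rng.uniform(5, 15, 500)
        d = deviance_residuals(y, mu)
        assert np.all(np.sign(d) == np.sign(y - mu))
        assert np.all(np.isfinite(d))

    def test_approximately_standard_normal_at_large_mean(self, rng):
        y = rng.poisson(25.0, 10_000).astype(float)
        d = deviance_residuals(y, np.full(10_000, 25.0))
        assert abs(stats.skew(d)) < 0.2
        assert abs(stats.kurtosis(d)) < 0.3

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            deviance_residuals(np.array([1.0]), np.array([0.0]))


class TestLinearModel:
    def test_exact_fit_gives_zero_residuals(self):
        X = pd.DataFrame({"x": [1.0, 2, 3, 4]})
        y = 2.0 + 3.0 * X["x"].to_numpy()
        fit = fit_linear_model(y, X)
        assert np.allclose(y - fit.fitted, 0.0, atol=1e-10)

    def test_intercept_only_residuals(self):
        fit = fit_linear_model(np.array([1.0, 2, 3]),
                               pd.DataFrame(index=range(3)))
        assert np.allclose(np.array([1.0, 2, 3]) - fit.fitted, [-1, 0, 1])

    def test_matches_normal_equations_and_orthogonality(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = rng.normal(size=100)
        fit = fit_linear_model(y, X)
        design = np.column_stack([np.ones(100), X.to_numpy()])
        assert np.allclose(fit.coefficients.to_numpy(),
                           ols_normal_equations(y, design), atol=1e-10)
        resid = y - fit.fitted
        assert np.all(np.abs(design.T @ resid) < 1e-8)


class TestStandardize:
    def test_row_convention(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"])
        out = standardize(df)
        assert np.allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 100)))
        once = standardize(df)
        twice = standardize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)
        assert np.all(np.abs(once.to_numpy().mean(axis=1)) < 1e-12)
        assert np.allclose(once.to_numpy().var(axis=1, ddof=1), 1.0,
                           atol=1e-12)

    def test_constant_row_names_gene(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                          index=["flatgene", "g2"])
        with pytest.raises(ValueError, match="flatgene"):
            standardize(df)


class TestResidualPipeline:
    def test_counts_scaled_composition(self, chain_data):
        res = residual_pipeline(chain_data.counts.iloc[:, :100],
                                chain_data.covariates.iloc[:100],
                                "counts", scale=True)
        assert res.standardized and res.platform == "counts"
        v = res.values.to_numpy()
        assert np.allclose(v.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(v.var(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_continuous_uncorrected_is_standardised_raw(self, chain_data):
        expr = chain_data.continuous.iloc[:, :50]
        cov = chain_data.covariates.iloc[:50]
        res = residual_pipeline(expr, cov, "continuous", scale=True,
                                correct_confounders=False)
        expected = standardize(expr)
        assert np.allclose(res.values.to_numpy(), expected.to_numpy(),
                           atol=1e-12)

    def test_count_residuals_decorrelated_from_covariates(self):
        sc = SyntheticScenario(p=8, n=500, seed=6)
        data = simulate(sc)
        res = residual_pipeline(data.counts, data.covariates, "counts",
                                scale=True)
        for c in COUNT_COVARIATES:
            x = pd.to_numeric(data.covariates[c]).to_numpy(dtype=float)
            for i in range(8):
                r = np.corrcoef(res.values.iloc[i].to_numpy(), x)[0, 1]
                assert abs(r) < 0.05

    def test_counts_keep_technical_correction_without_confounders(self,
                                                                  chain_data):
        res = residual_pipeline(chain_data.counts.iloc[:, :80],
                                chain_data.covariates.iloc[:80],
                                "counts", scale=False,
                                correct_confounders=False)
        # library size must not leak into the residuals: offset is retained
        lib = chain_data.covariates["library_size"].iloc[:80].to_numpy(float)
        for i in range(res.values.shape[0]):
            r = np.corrcoef(res.values.iloc[i].to_numpy(), lib)[0, 1]
            assert abs(r) < 0.2

    def test_sample_mismatch_rejected(self, chain_data):
        with pytest.raises(ValueError):
            residual_pipeline(chain_data.counts.iloc[:, :10],
                              chain_data.covariates.iloc[:20], "counts")
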