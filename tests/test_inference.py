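"""Sampler behaviour: model structure, parameter recovery, a numerically
exact posterior oracle on a tiny reduction, imputation full conditionals,
OR summaries, and convergence diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import geoprev as gp
from geoprev.mcmc import McmcConfig, PosteriorSamples, convergence_diagnostics, fit, \
    summarize_fixed_effects
from geoprev.model import Covariate, CovariateSchema

from conftest import small_world


def _make_samples(coef, names, schema=None, **extra):
    """Hand-built PosteriorSamples for summary-level tests."""
    schema = schema or CovariateSchema([])
    draws = {"coef": np.asarray(coef, dtype=float)}
    draws.update({k: np.asarray(v) for k, v in extra.items()})
    return PosteriorSamples(model=2 if "s" in extra else 1, coef_names=list(names),
                            draws=draws, loglik_obs=None, imputed={},
                            cluster_ids=np.array([0]), schema=schema)


class TestModelStructure:
    def test_model1_has_no_spatial_field(self, demo_fit):
        cfg, table, clusters = (demo_fit["config"], demo_fit["table"], demo_fit["clusters"])
        m1 = fit(table, clusters, cfg.covariate_schema,
                 mcmc=McmcConfig(n_iterations=300, burn_in=150, seed=1), spatial=False)
        assert m1.model == 1
        assert "s" not in m1.draws and "sigma_s" not in m1.draws and "phi" not in m1.draws

    def test_draws_respect_prior_support(self, demo_fit):
        s = demo_fit["samples"]
        for key in ("sigma_beta", "sigma_gamma", "sigma_u", "sigma_s"):
            assert np.all(s.draws[key] > 0) and np.all(s.draws[key] < 10)
        assert np.all(s.draws["phi"] > 0) and np.all(s.draws["phi"] < 1)

    def test_retained_draw_count(self, demo_fit):
        s = demo_fit["samples"]
        assert s.n_draws == (2500 - 1000) // 1

    def test_constant_outcome_rejected(self):
        cfg, table, clusters, _ = small_world(seed=2, n_clusters=5, children=(3, 4))
        table["y"] = 1
        with pytest.raises(ValueError, match="constant"):
            fit(table, clusters, cfg.covariate_schema,
                mcmc=McmcConfig(n_iterations=20, burn_in=10, seed=1))


class TestRecovery:
    def test_intercept_only_prevalence(self):
        # world at 38% prevalence: the identified intercept level
        # (beta0 + mean of realized cluster effects) covers the truth
        schema = CovariateSchema([Covariate("x1", "continuous", mean=0, sd=1)])
        cfg = gp.SyntheticConfig(n_clusters=50, children_per_cluster=(35, 45),
                                 beta0=math.log(0.38 / 0.62), beta=np.zeros(1), gamma={},
                                 sigma_s=0.3, phi=0.05, sigma_u=0.2,
                                 covariate_schema=schema, missing_rates={}, seed=3)
        table, clusters, truth = gp.simulate(cfg)
        s = fit(table, clusters, schema,
                mcmc=McmcConfig(n_iterations=3000, burn_in=1500, seed=4), spatial=True)
        level = s.coef("(Intercept)") + s.draws["s"].mean(axis=1) + s.draws["u"].mean(axis=1)
        p = expit(level)
        target = expit(cfg.beta0 + truth.s.mean() + truth.u.mean())
        lo, hi = np.quantile(p, [0.025, 0.975])
        assert lo <= target <= hi
        assert abs(p.mean() - 0.38) < 0.06

    def test_exchangeability_under_row_permutation(self):
        cfg, table, clusters, _ = small_world(seed=5, n_clusters=20, children=(8, 10),
                                              missing={})
        perm = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        m = McmcConfig(n_iterations=2000, burn_in=1000, seed=6)
        a = fit(table, clusters, cfg.covariate_schema, mcmc=m, spatial=False)
        b = fit(perm, clusters, cfg.covariate_schema, mcmc=m, spatial=False)
        # same posterior, different MC noise: means agree within MC error
        np.testing.assert_allclose(a.draws["coef"].mean(axis=0),
                                   b.draws["coef"].mean(axis=0), atol=0.2)


class TestExactPosteriorOracle:
    def test_quantiles_match_numerical_integration(self):
        # Tiny reduction: intercept-only, six clusters of six children. The
        # exact marginal posterior of beta0 is computed by quadrature: per
        # cluster, the random effect is integrated out on a standardized
        # grid (u = sigma_u * z), then sigma_u over its uniform prior.
        J, m = 6, 6
        k = np.array([2, 4, 1, 3, 5, 2])
        y = np.concatenate([[1] * k[j] + [0] * (m - k[j]) for j in range(J)])
        ids = [f"c{j}" for j in range(J)]
        table = pd.DataFrame({"child_id": np.arange(J * m),
                              "cluster_id": np.repeat(ids, m), "y": y})
        clusters = gp.ClusterSet(ids=np.array(ids),
                                 coords=np.column_stack([np.arange(J) * 30.0, np.zeros(J)]),
                                 crs="km")
        s = fit(table, clusters, CovariateSchema([]),
                mcmc=McmcConfig(n_iterations=24_000, burn_in=4000, seed=1), spatial=False)
        sampler_q = np.quantile(s.coef("(Intercept)"), [0.25, 0.5, 0.75])

        # ---- quadrature oracle (independent of the sampler) ---------------
        b_grid = np.linspace(-6, 6, 481)
        z = np.linspace(-9, 9, 601)
        dz = z[1] - z[0]
        phi = np.exp(-0.5 * z ** 2) / math.sqrt(2 * math.pi)
        su = np.linspace(1e-5, 10, 500)
        post = np.empty(len(b_grid))
        for i, b in enumerate(b_grid):
            a = b + su[:, None] * z[None, :]
            prod = np.ones(len(su))
            for j in range(J):
                prod *= np.exp(k[j] * a - m * np.logaddexp(0, a)) @ phi * dz
            post[i] = math.exp(-0.5 * (b / 10.0) ** 2) * np.trapezoid(prod, su)
        post /= np.trapezoid(post, b_grid)
        cdf = np.concatenate([[0.0], np.cumsum((post[1:] + post[:-1]) / 2
                                               * np.diff(b_grid))])
        cdf /= cdf[-1]
        exact_q = np.interp([0.25, 0.5, 0.75], cdf, b_grid)
        np.testing.assert_allclose(sampler_q, exact_q, atol=0.06)


class TestImputation:
    def test_zero_missingness_keeps_state_clean(self):
        cfg, table, clusters, _ = small_world(seed=8, n_clusters=10, children=(5, 6),
                                              missing={})
        s = fit(table, clusters, cfg.covariate_schema,
                mcmc=McmcConfig(n_iterations=200, burn_in=100, seed=9), spatial=False)
        assert s.imputed == {}

    def test_flat_outcome_imputation_reduces_to_submodel(self, demo_fit):
        # x2 was simulated with effect -0.5 but the *sub-model* moments must
        # still track the observed column; with a null-effect covariate the
        # full conditional is the sub-model itself
        cfg, table, clusters, _ = small_world(
            seed=10, n_clusters=25, children=(12, 16), beta=(0.3, 0.0),
            missing={"x2": 0.5})
        s = fit(table, clusters, cfg.covariate_schema,
                mcmc=McmcConfig(n_iterations=2000, burn_in=1000, seed=11), spatial=False)
        imputed = s.imputed["x2"].astype(float).ravel()
        # N(mu_X, sigma_X) with mu ~ 2.0, sigma ~ 0.5 (the generating marginal)
        assert imputed.mean() == pytest.approx(2.0, abs=0.1)
        assert imputed.std() == pytest.approx(0.5, abs=0.1)
        assert s.draws["mu_x:x2"].mean() == pytest.approx(2.0, abs=0.1)

    def test_categorical_imputation_matches_fitted_pi(self):
        # covariate fully unrelated to outcome: imputed category frequencies
        # agree with the sub-model's fitted softmax probabilities
        cfg, table, clusters, _ = small_world(
            seed=12, n_clusters=25, children=(12, 16), gamma_g=0.0,
            missing={"g": 0.6})
        s = fit(table, clusters, cfg.covariate_schema,
                mcmc=McmcConfig(n_iterations=2500, burn_in=1000, seed=13), spatial=False)
        codes = s.imputed["g"].astype(int)
        freq_b = (codes == 1).mean()
        eta = np.column_stack([np.zeros(s.n_draws), s.draws["eta_z:g"][:, 0]])
        pi_b = (np.exp(eta[:, 1]) / np.exp(eta).sum(axis=1)).mean()
        assert freq_b == pytest.approx(pi_b, abs=0.05)
        assert pi_b == pytest.approx(0.5, abs=0.08)  # generating marginal


class TestSummaries:
    def test_constant_zero_coefficient(self):
        T = 200
        s = _make_samples(np.zeros((T, 1)), ["(Intercept)"])
        rep = summarize_fixed_effects(s)
        row = rep.iloc[0]
        assert row["odds_ratio"] == 1.0 and row["ci_low"] == 1.0 and row["ci_high"] == 1.0

    def test_lognormal_closed_form(self):
        # OR = mean over draws of exp(coef); for coef ~ N(m, v) this is
        # exp(m + v/2), pinning the mean-of-exp (not exp-of-mean) convention
        rng = np.random.default_rng(14)
        m, sd = math.log(1.32), 0.3
        draws = rng.normal(m, sd, size=(40_000, 1))
        s = _make_samples(draws, ["(Intercept)"])
        rep = summarize_fixed_effects(s)
        expected = math.exp(m + sd ** 2 / 2)
        assert rep.iloc[0]["odds_ratio"] == pytest.approx(expected, rel=0.01)

    def test_reference_rows_report_unit_or(self, demo_fit):
        rep = summarize_fixed_effects(demo_fit["samples"])
        refs = rep[rep["reference"]]
        assert set(refs["term"]) == {"g[a]", "h[p]"}
        assert (refs["odds_ratio"] == 1.0).all()

    def test_minimum_draw_requirement(self):
        with pytest.raises(ValueError):
            summarize_fixed_effects(_make_samples(np.zeros((50, 1)), ["(Intercept)"]))


class TestDiagnostics:
    def test_white_noise_chains_rhat_near_one(self):
        rng = np.random.default_rng(15)
        z = rng.standard_normal(2000)
        rep = convergence_diagnostics({"theta": np.stack([z, z.copy()])})
        assert rep.iloc[0]["rhat"] == pytest.approx(1.0, abs=0.02)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(16)
        chains = np.stack([rng.standard_normal(1000), rng.standard_normal(1000) + 10])
        with pytest.warns(UserWarning, match="R-hat"):
            rep = convergence_diagnostics({"theta": chains})
        assert rep.iloc[0]["rhat"] > 1.1

    def test_ar1_effective_sample_size(self):
        # ESS/N for AR(1) with rho = 0.9 is (1-rho)/(1+rho) ~ 0.0526
        rng = np.random.default_rng(17)
        n, rho = 60_000, 0.9
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for t in range(1, n):
            x[t] = rho * x[t - 1] + math.sqrt(1 - rho ** 2) * eps[t]
        rep = convergence_diagnostics({"theta": x[None, :]})
        ratio = rep.iloc[0]["ess"] / n
        assert ratio == pytest.approx((1 - rho) / (1 + rho), rel=0.2)
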