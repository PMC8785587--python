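"""Design construction, distances, covariance, likelihood and priors, each
against an independently coded oracle where the spec of the quantity allows
one."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal, norm

import geoprev as gp
from geoprev.model import (ClusterSet, Covariate, CovariateSchema, Parameters,
                           PriorSpec, bernoulli_loglik, build_design,
                           covariance_cholesky, exponential_covariance,
                           haversine_km, imputation_logdensity, linear_predictor,
                           log_likelihood, log_prior, pairwise_distances, softmax)


def _table(n=8, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "child_id": np.arange(n), "cluster_id": rng.integers(0, 3, n),
        "y": rng.integers(0, 2, n).astype(float),
        "age": rng.uniform(0, 59, n),
        "wealth": rng.choice(["Richest", "Richer", "Middle", "Poorer", "Poorest"], n),
    })


def _schema():
    return CovariateSchema([
        Covariate("age", "continuous"),
        Covariate("wealth", "categorical",
                  categories=["Richest", "Richer", "Middle", "Poorer", "Poorest"]),
    ])


class TestBuildDesign:
    def test_binary_categorical_single_indicator(self):
        tab = pd.DataFrame({"child_id": [0, 1, 2], "cluster_id": [0, 0, 1],
                            "y": [0, 1, 0], "g": ["a", "b", "a"]})
        schema = CovariateSchema([Covariate("g", "categorical", categories=["a", "b"])])
        d = build_design(tab, schema)
        Z, names = d.indicator_matrix()
        assert Z.shape == (3, 1) and names == ["g[b]"]
        np.testing.assert_array_equal(Z[:, 0], [0.0, 1.0, 0.0])

    def test_continuous_centered_on_observed_mean(self):
        tab = _table(50)
        d = build_design(tab, _schema())
        assert abs(d.X[:, 0].mean()) < 1e-12

    def test_wealth_expands_to_four_contrasts(self):
        d = build_design(_table(40), _schema())
        _, names = d.indicator_matrix()
        assert names == ["wealth[Richer]", "wealth[Middle]", "wealth[Poorer]", "wealth[Poorest]"]

    def test_decode_recovers_labels(self):
        tab = _table(30)
        d = build_design(tab, _schema())
        np.testing.assert_array_equal(d.decode_categories("wealth"), tab["wealth"].to_numpy())

    def test_unknown_category_names_row_and_column(self):
        tab = _table(5)
        tab.loc[3, "wealth"] = "Mystery"
        with pytest.raises(ValueError, match=r"wealth.*row 3|row 3.*wealth|'Mystery'"):
            build_design(tab, _schema())

    def test_bad_outcomes_rejected(self):
        tab = _table(5)
        tab.loc[2, "y"] = 2
        with pytest.raises(ValueError, match="0/1"):
            build_design(tab, _schema())
        tab = _table(5)
        tab.loc[1, "y"] = np.nan
        with pytest.raises(ValueError, match="missing outcome"):
            build_design(tab, _schema())


class TestDistances:
    def test_identical_points_zero(self):
        assert haversine_km(30.0, -2.0, 30.0, -2.0) == 0.0

    def test_one_degree_latitude(self):
        # 1 degree of latitude = pi R / 180 ~ 111.2 km
        assert haversine_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(111.195, abs=0.01)

    def test_matches_brute_force_haversine(self):
        rng = np.random.default_rng(1)
        lon = rng.uniform(28, 31, 10)
        lat = rng.uniform(-3, -1, 10)
        cs = ClusterSet(ids=np.arange(10), coords=np.column_stack([lon, lat]))
        d = pairwise_distances(cs)
        R = 6371.0088
        for i in range(10):
            for j in range(10):
                p1, l1 = math.radians(lat[i]), math.radians(lon[i])
                p2, l2 = math.radians(lat[j]), math.radians(lon[j])
                h = (math.sin((p2 - p1) / 2) ** 2
                     + math.cos(p1) * math.cos(p2) * math.sin((l2 - l1) / 2) ** 2)
                ref = 2 * R * math.asin(math.sqrt(h))
                assert d[i, j] == pytest.approx(ref, rel=1e-9, abs=1e-9)

    def test_invalid_latitude(self):
        with pytest.raises(ValueError, match="latitude"):
            ClusterSet(ids=[0, 1], coords=[[0, 95.0], [1, 0.0]])

    def test_euclidean_for_km_crs(self):
        cs = ClusterSet(ids=[0, 1], coords=[[0.0, 0.0], [3.0, 4.0]], crs="km")
        assert cs.distances[0, 1] == pytest.approx(5.0)


class TestExponentialCovariance:
    def test_closed_form_values(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        cov = exponential_covariance(d, 1.0, 0.5)
        assert cov[0, 0] == pytest.approx(1.0)
        assert cov[0, 1] == pytest.approx(math.exp(-1.0), rel=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_positive_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        cs = ClusterSet(ids=np.arange(8), coords=rng.uniform(0, 200, (8, 2)), crs="km")
        cov = exponential_covariance(cs.distances, 1.7, 0.08)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10

    def test_limits(self):
        cs = ClusterSet(ids=np.arange(4), coords=np.random.default_rng(2).uniform(0, 50, (4, 2)), crs="km")
        near_iid = exponential_covariance(cs.distances, 2.0, 1e3)
        np.testing.assert_allclose(near_iid, 4.0 * np.eye(4), atol=1e-8)
        near_const = exponential_covariance(cs.distances, 2.0, 1e-8)
        np.testing.assert_allclose(near_const, 4.0 * np.ones((4, 4)), atol=1e-5)

    def test_asymmetric_distances_rejected(self):
        with pytest.raises(ValueError):
            exponential_covariance(np.array([[0.0, 1.0], [2.0, 0.0]]), 1.0, 0.1)


class TestLikelihood:
    def test_eta_zero(self):
        y = np.array([0, 1, 1, 0, 1, 0])
        assert bernoulli_loglik(np.zeros(6), y).sum() == pytest.approx(-6 * math.log(2))

    def test_extreme_eta_saturates(self):
        assert bernoulli_loglik(np.array([50.0]), np.array([1]))[0] == pytest.approx(0.0, abs=1e-20)
        assert np.isfinite(bernoulli_loglik(np.array([-800.0]), np.array([1]))[0])

    def test_nonfinite_eta_rejected(self):
        with pytest.raises(ValueError):
            bernoulli_loglik(np.array([np.nan]), np.array([1]))

    def test_matches_brute_force_bernoulli_product(self):
        tab = _table(6, seed=3)
        schema = _schema()
        d = build_design(tab, schema)
        params = Parameters(beta0=0.3, beta=np.array([0.02]),
                            gamma={"wealth": np.array([0.0, 0.1, -0.2, 0.3, 0.15])},
                            u=np.array([0.1, -0.2, 0.05]))
        eta = linear_predictor(params, d)
        ll = log_likelihood(params, d)
        brute = 0.0
        for i in range(6):
            p = 1.0 / (1.0 + math.exp(-eta[i]))
            brute += math.log(p if d.y[i] == 1 else 1.0 - p)
        assert ll == pytest.approx(brute, abs=1e-12)


class TestPriors:
    def _params(self, J=4):
        rng = np.random.default_rng(4)
        return Parameters(
            beta0=0.4, beta=np.array([0.1, -0.3]),
            gamma={"g": np.array([0.0, 0.25])},
            sigma_beta=1.2, sigma_gamma=0.8, sigma_u=0.5,
            u=rng.normal(0, 0.4, J), sigma_s=1.1, phi=0.2,
            s=rng.normal(0, 1.0, J),
            mu_x={"x": 2.0}, sigma_x={"x": 0.7},
            eta_z={"g": np.array([0.0, -0.4])}, mu_z={"g": np.array([-0.3])},
            sigma_z={"g": 1.5})

    def test_out_of_support_is_minus_inf(self):
        p = self._params()
        p.sigma_s = 11.0
        d = np.zeros((4, 4))
        assert log_prior(p, PriorSpec(), distances=d) == -math.inf

    def test_field_at_mode(self):
        cs = ClusterSet(ids=np.arange(3), coords=[[0, 0], [20, 0], [0, 45]], crs="km")
        p = Parameters(beta0=0.0, beta=np.empty(0), gamma={}, u=None,
                       sigma_s=1.3, phi=0.1, s=np.zeros(3))
        lp = log_prior(p, PriorSpec(), distances=cs.distances)
        cov = exponential_covariance(cs.distances, 1.3, 0.1)
        cov[np.diag_indices_from(cov)] += 1e-10 * 1.3 ** 2
        expected = -0.5 * math.log(np.linalg.det(2 * math.pi * cov))
        # the only non-constant term left is the MV-normal at its mode
        assert lp - norm.logpdf(0.0, scale=10.0) == pytest.approx(expected, abs=1e-8)

    def test_matches_independent_density_sum(self):
        rng = np.random.default_rng(5)
        cs = ClusterSet(ids=np.arange(4), coords=rng.uniform(0, 100, (4, 2)), crs="km")
        p = self._params(J=4)
        lp = log_prior(p, PriorSpec(), distances=cs.distances)

        cov = exponential_covariance(cs.distances, p.sigma_s, p.phi)
        cov[np.diag_indices_from(cov)] += 1e-10 * p.sigma_s ** 2
        oracle = (norm.logpdf(p.beta0, scale=10.0)
                  + norm.logpdf(p.beta, scale=p.sigma_beta).sum()
                  + norm.logpdf(p.gamma["g"][1:], scale=p.sigma_gamma).sum()
                  + norm.logpdf(p.u, scale=p.sigma_u).sum()
                  + multivariate_normal.logpdf(p.s, mean=np.zeros(4), cov=cov)
                  + norm.logpdf(p.mu_x["x"], scale=math.sqrt(1000.0))
                  + norm.logpdf(p.eta_z["g"][1], loc=p.mu_z["g"][0], scale=p.sigma_z["g"])
                  + norm.logpdf(p.mu_z["g"][0], scale=math.sqrt(1000.0)))
        assert lp == pytest.approx(oracle, abs=1e-8)

    def test_posterior_finite_on_interior(self):
        tab = _table(20, seed=6)
        schema = _schema()
        d = build_design(tab, schema)
        p = Parameters(beta0=0.1, beta=np.array([0.01]),
                       gamma={"wealth": np.array([0.0, 0.1, 0.0, -0.1, 0.2])},
                       u=np.zeros(3))
        total = log_likelihood(p, d) + log_prior(p, PriorSpec(), spatial=False)
        assert np.isfinite(total)


class TestImputationDensities:
    def test_softmax_closed_forms(self):
        np.testing.assert_allclose(softmax(np.array([0.0, 0.0])), [0.5, 0.5])
        np.testing.assert_allclose(softmax(np.array([0.0, 1.0, 2.0])),
                                   [0.0900, 0.2447, 0.6652], atol=5e-5)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-30, 30), min_size=2, max_size=6))
    def test_softmax_normalizes(self, eta):
        assert softmax(np.array(eta)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_logdensity_matches_oracle(self):
        tab = _table(12, seed=7)
        schema = _schema()
        d = build_design(tab, schema)
        p = Parameters(beta0=0.0, beta=np.array([0.0]),
                       gamma={"wealth": np.zeros(5)},
                       mu_x={"age": 30.0}, sigma_x={"age": 18.0},
                       eta_z={"wealth": np.array([0.0, 0.2, -0.1, 0.3, 0.05])})
        ld = imputation_logdensity(p, d)
        raw_age = d.X[:, 0] + d.x_centers[0]
        pi = softmax(p.eta_z["wealth"])
        codes = d.codes["wealth"]
        oracle = norm.logpdf(raw_age, loc=30.0, scale=18.0).sum() + \
            np.log(pi[codes[codes >= 0]]).sum()
        assert ld == pytest.approx(oracle, abs=1e-10)
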