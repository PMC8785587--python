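"""Posterior sampling for the geostatistical logistic model.

Two models share one sampler:

* Model 1 — exchangeable cluster effects ``u`` only.
* Model 2 — spatial field ``s`` (exponential-covariance GRF) plus ``u``.

The scheme is Metropolis-within-Gibbs: univariate adaptive random-walk
Metropolis on the fixed effects, parallel per-cluster MH for ``u``,
elliptical slice sampling for ``s`` under its MV-normal prior, random-walk
updates on log/logit-transformed scale parameters, and whitened joint
rescaling moves for (sigma_s, s) and (sigma_u, u) that avoid the notorious
slow mixing of centered parameterisations.  Missing covariates are imputed
inside the chain: continuous cells by independence MH from their normal
sub-model, categorical cells exactly from the discrete full conditional.

Step sizes adapt by Robbins-Monro during burn-in only (targets 0.44 for
univariate moves) and are frozen afterwards, preserving detailed balance of
the retained draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular

from .model import (ClusterSet, CovariateSchema, Design, PriorSpec, build_design,
                    covariance_cholesky, softmax)

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "fit",
    "summarize_fixed_effects",
    "convergence_diagnostics",
]

_UNIV_TARGET = 0.44


@dataclass
class McmcConfig:
    """Chain settings. Defaults follow the study protocol: 40,000 iterations
    with the first 20,000 discarded.  Desk-scale work uses far fewer."""

    n_iterations: int = 40_000
    burn_in: int = 20_000
    thinning: int = 1
    seed: int = 0
    adapt: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must be in [0, n_iterations)")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning


@dataclass
class PosteriorSamples:
    """Post-burn-in draws of every model parameter.

    ``draws`` maps parameter names to arrays with the draw index first:
    ``coef`` (T, P), ``s``/``u`` (T, J), scalars (T,).  ``loglik_obs`` holds
    per-draw per-observation log Pr(y_ij | theta) for the validation module.
    ``imputed`` maps covariate names to per-draw imputed cell values.
    """

    model: int
    coef_names: list
    draws: dict
    loglik_obs: Optional[np.ndarray]
    imputed: dict
    cluster_ids: np.ndarray
    schema: CovariateSchema
    acceptance: dict = field(default_factory=dict)
    config: Optional[McmcConfig] = None

    @property
    def n_draws(self) -> int:
        return self.draws["coef"].shape[0]

    def coef(self, name: str) -> np.ndarray:
        return self.draws["coef"][:, self.coef_names.index(name)]


# ---------------------------------------------------------------------------
# adaptive step helper
# ---------------------------------------------------------------------------

class _Step:
    """Robbins-Monro tuned log step size (scalar or vector)."""

    def __init__(self, size, target=_UNIV_TARGET):
        self.log_step = np.log(size) if np.ndim(size) else math.log(size)
        self.target = target
        self.count = 0
        self.accepted = 0.0
        self.proposed = 0

    @property
    def step(self):
        return np.exp(self.log_step)

    def adapt(self, alpha):
        self.count += 1
        self.log_step = self.log_step + (alpha - self.target) / self.count ** 0.6

    def record(self, alpha):
        self.proposed += 1
        self.accepted += float(np.mean(alpha))

    @property
    def rate(self):
        return self.accepted / max(self.proposed, 1)


def _bern_ll(eta, sign):
    return -np.logaddexp(0.0, -sign * eta)


def _alpha(log_ratio):
    return math.exp(min(0.0, log_ratio))


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def fit(table: pd.DataFrame, clusters: ClusterSet, schema: CovariateSchema,
        priors: Optional[PriorSpec] = None, mcmc: Optional[McmcConfig] = None,
        spatial: bool = True, store_loglik: bool = True,
        verbose: bool = False) -> PosteriorSamples:
    """Run one MCMC chain and return the retained posterior draws.

    ``spatial=False`` fits Model 1 (no ``s``, ``sigma_s`` or ``phi`` in the
    state); ``spatial=True`` fits Model 2.  Reproducible given
    ``mcmc.seed``: all randomness flows from one generator.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    design = build_design(table, schema, clusters)
    y = design.y
    n = design.n
    if y.min() == y.max():
        raise ValueError("outcome is constant; the model is not identifiable")
    J = len(clusters)
    if J < 2:
        raise ValueError("need at least 2 clusters")
    clus = design.cluster_index
    sign = (2.0 * y - 1.0).astype(float)
    rng = np.random.default_rng(mcmc.seed)

    # ---- coefficient layout ------------------------------------------------
    Q = design.X.shape[1]
    coef_names = design.coef_names
    cat_slots = []  # (cov_name, category_code) per contrast coefficient
    for cov in schema.categorical:
        cat_slots += [(cov.name, k) for k in range(1, cov.n_categories)]
    P = 1 + Q + len(cat_slots)

    # ---- state -------------------------------------------------------------
    th = np.zeros(P)
    pbar = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    th[0] = math.log(pbar / (1 - pbar))
    sigma_beta, sigma_gamma = 1.0, 1.0
    sigma_u = 0.5
    u = np.zeros(J)
    if spatial:
        sigma_s = 0.5
        phi = priors.phi_lower + 0.1 * (priors.phi_upper - priors.phi_lower)
        cholR = _corr_chol(clusters.distances, phi)
        s = np.zeros(J)
    else:
        sigma_s = phi = None
        cholR = None
        s = None

    # imputation sub-models only exist for covariates with missing cells
    imp_cont = []   # dicts per continuous covariate with missingness
    for q, name in enumerate(design.x_names):
        miss = design.x_missing[:, q]
        obs_raw = design.X[~miss, q] + design.x_centers[q]
        if miss.any():
            imp_cont.append({"q": q, "name": name, "idx": np.flatnonzero(miss),
                             "mu": float(obs_raw.mean()),
                             "sd": float(max(obs_raw.std(ddof=1), 1e-3))})
    imp_cat = []
    codes = {k: v.copy() for k, v in design.codes.items()}
    for cov in schema.categorical:
        miss = design.cat_missing[cov.name]
        if not miss.any():
            continue
        K = cov.n_categories
        obs_counts = np.bincount(codes[cov.name][~miss], minlength=K).astype(float) + 0.5
        p0 = obs_counts / obs_counts.sum()
        eta0 = np.log(p0 / p0[0])
        # initialize missing codes from the observed frequencies
        idx = np.flatnonzero(miss)
        codes[cov.name][idx] = rng.choice(K, size=len(idx), p=p0)
        imp_cat.append({"name": cov.name, "idx": idx, "K": K,
                        "eta": eta0, "mu": eta0[1:].copy(), "sd": 1.0})
    X = design.X.copy()  # imputed cells overwritten in place

    def slot_value(name, k):
        return th[1 + Q + cat_slots.index((name, k))]

    def gamma_vec(name):
        K = schema[name].n_categories
        g = np.zeros(K)
        for k in range(1, K):
            g[k] = th[1 + Q + cat_slots.index((name, k))]
        return g

    def full_eta():
        e = np.full(n, th[0])
        if Q:
            e += X @ th[1:1 + Q]
        for j, (name, k) in enumerate(cat_slots):
            e += np.where(codes[name] == k, th[1 + Q + j], 0.0)
        re = u.copy()
        if spatial:
            re = re + s
        return e + re[clus]

    eta = full_eta()
    ll = _bern_ll(eta, sign)

    # ---- adaptive steps ----------------------------------------------------
    steps = {f"coef{c}": _Step(0.1) for c in range(P)}
    steps["u"] = _Step(np.full(J, 0.5))
    for key in ("sigma_u", "sigma_u_scale", "sigma_beta", "sigma_gamma"):
        steps[key] = _Step(0.5)
    if spatial:
        for key in ("phi", "sigma_s", "sigma_s_scale"):
            steps[key] = _Step(0.5)
    for item in imp_cont:
        steps[f"mu_x:{item['name']}"] = _Step(0.2)
        steps[f"sigma_x:{item['name']}"] = _Step(0.2)
    for item in imp_cat:
        for k in range(1, item["K"]):
            steps[f"eta_z:{item['name']}:{k}"] = _Step(0.3)
        steps[f"mu_z:{item['name']}"] = _Step(0.5)
        steps[f"sigma_z:{item['name']}"] = _Step(0.5)

    # ---- storage -----------------------------------------------------------
    T = mcmc.n_retained
    out = {
        "coef": np.empty((T, P)),
        "sigma_beta": np.empty(T), "sigma_gamma": np.empty(T),
        "sigma_u": np.empty(T), "u": np.empty((T, J)),
    }
    if spatial:
        out.update({"sigma_s": np.empty(T), "phi": np.empty(T), "s": np.empty((T, J))})
    loglik_obs = np.empty((T, n), dtype=np.float32) if store_loglik else None
    imputed = {}
    for item in imp_cont:
        imputed[item["name"]] = np.empty((T, len(item["idx"])), dtype=np.float32)
        out[f"mu_x:{item['name']}"] = np.empty(T)
        out[f"sigma_x:{item['name']}"] = np.empty(T)
    for item in imp_cat:
        imputed[item["name"]] = np.empty((T, len(item["idx"])), dtype=np.int16)
        out[f"eta_z:{item['name']}"] = np.empty((T, item["K"] - 1))
        out[f"mu_z:{item['name']}"] = np.empty((T, item["K"] - 1))
        out[f"sigma_z:{item['name']}"] = np.empty(T)

    sq2pi = 0.5 * math.log(2.0 * math.pi)

    def norm_lp(x, sd):
        return -0.5 * (x / sd) ** 2 - math.log(sd) - sq2pi

    def mvn_quad(vec):
        w = solve_triangular(cholR, vec, lower=True)
        return float(w @ w)

    logdetR = None

    def s_prior_lp(vec, sig):
        return -J * math.log(sig) - logdetR - 0.5 * mvn_quad(vec) / sig ** 2 - J * sq2pi

    if spatial:
        logdetR = float(np.log(np.diag(cholR)).sum())

    # ---- iterations --------------------------------------------------------
    keep = 0
    for it in range(mcmc.n_iterations):
        adapting = mcmc.adapt and it < mcmc.burn_in

        # fixed effects, one coordinate at a time with incremental eta
        for c in range(P):
            st = steps[f"coef{c}"]
            eps = st.step * rng.standard_normal()
            if c == 0:
                rows = slice(None)
                d_eta = eps
                lp_delta = norm_lp(th[0] + eps, priors.intercept_sd) - norm_lp(th[0], priors.intercept_sd)
            elif c <= Q:
                rows = slice(None)
                d_eta = eps * X[:, c - 1]
                lp_delta = norm_lp(th[c] + eps, sigma_beta) - norm_lp(th[c], sigma_beta)
            else:
                name, k = cat_slots[c - 1 - Q]
                rows = codes[name] == k
                d_eta = eps
                lp_delta = norm_lp(th[c] + eps, sigma_gamma) - norm_lp(th[c], sigma_gamma)
            eta_new = eta[rows] + d_eta
            ll_new = _bern_ll(eta_new, sign[rows])
            log_ratio = float(ll_new.sum() - ll[rows].sum()) + lp_delta
            a = _alpha(log_ratio)
            st.record(a)
            if adapting:
                st.adapt(a)
            if rng.random() < a:
                th[c] += eps
                eta[rows] = eta_new
                ll[rows] = ll_new

        # parallel per-cluster update of u
        st = steps["u"]
        eps = st.step * rng.standard_normal(J)
        eta_new = eta + eps[clus]
        ll_new = _bern_ll(eta_new, sign)
        d_clus = np.bincount(clus, weights=ll_new - ll, minlength=J)
        d_prior = norm_lp(u + eps, sigma_u) - norm_lp(u, sigma_u)
        log_r = d_clus + d_prior
        a_vec = np.exp(np.minimum(0.0, log_r))
        st.record(a_vec)
        if adapting:
            st.adapt(a_vec)
        acc = rng.random(J) < a_vec
        if acc.any():
            u = np.where(acc, u + eps, u)
            rows_acc = acc[clus]
            eta[rows_acc] = eta_new[rows_acc]
            ll[rows_acc] = ll_new[rows_acc]

        # sigma_u: plain conditional move, then whitened joint rescale
        st = steps["sigma_u"]
        eps = st.step * rng.standard_normal()
        prop = sigma_u * math.exp(eps)
        if prop < priors.sd_upper_unstructured:
            Su = float(u @ u)
            log_r = (-J * math.log(prop) - 0.5 * Su / prop ** 2) - \
                    (-J * math.log(sigma_u) - 0.5 * Su / sigma_u ** 2) + eps
            a = _alpha(log_r)
            if rng.random() < a:
                sigma_u = prop
        else:
            a = 0.0
        st.record(a)
        if adapting:
            st.adapt(a)

        st = steps["sigma_u_scale"]
        eps = st.step * rng.standard_normal()
        prop = sigma_u * math.exp(eps)
        if prop < priors.sd_upper_unstructured:
            u_new = u * math.exp(eps)
            eta_new = eta + (u_new - u)[clus]
            ll_new = _bern_ll(eta_new, sign)
            log_r = float(ll_new.sum() - ll.sum()) + eps
            a = _alpha(log_r)
            if rng.random() < a:
                sigma_u, u, eta, ll = prop, u_new, eta_new, ll_new
        else:
            a = 0.0
        st.record(a)
        if adapting:
            st.adapt(a)

        if spatial:
            # phi on the logit scale of its uniform support
            st = steps["phi"]
            lo, hi = priors.phi_lower, priors.phi_upper
            z = math.log(phi - lo) - math.log(hi - phi)
            z_new = z + st.step * rng.standard_normal()
            phi_new = (lo + hi * math.exp(z_new)) / (1.0 + math.exp(z_new))
            cholR_new = _corr_chol(clusters.distances, phi_new)
            logdetR_new = float(np.log(np.diag(cholR_new)).sum())
            w_new = solve_triangular(cholR_new, s, lower=True)
            lp_new = -logdetR_new - 0.5 * float(w_new @ w_new) / sigma_s ** 2
            lp_old = -logdetR - 0.5 * mvn_quad(s) / sigma_s ** 2
            jac = (math.log(phi_new - lo) + math.log(hi - phi_new)) - \
                  (math.log(phi - lo) + math.log(hi - phi))
            a = _alpha(lp_new - lp_old + jac)
            st.record(a)
            if adapting:
                st.adapt(a)
            if rng.random() < a:
                phi, cholR, logdetR = phi_new, cholR_new, logdetR_new

            # sigma_s: conditional move given s
            st = steps["sigma_s"]
            eps = st.step * rng.standard_normal()
            prop = sigma_s * math.exp(eps)
            if prop < priors.sd_upper_spatial:
                qd = mvn_quad(s)
                log_r = (-J * math.log(prop) - 0.5 * qd / prop ** 2) - \
                        (-J * math.log(sigma_s) - 0.5 * qd / sigma_s ** 2) + eps
                a = _alpha(log_r)
                if rng.random() < a:
                    sigma_s = prop
            else:
                a = 0.0
            st.record(a)
            if adapting:
                st.adapt(a)

            # whitened joint rescale of (sigma_s, s)
            st = steps["sigma_s_scale"]
            eps = st.step * rng.standard_normal()
            prop = sigma_s * math.exp(eps)
            if prop < priors.sd_upper_spatial:
                s_new = s * math.exp(eps)
                eta_new = eta + (s_new - s)[clus]
                ll_new = _bern_ll(eta_new, sign)
                log_r = float(ll_new.sum() - ll.sum()) + eps
                a = _alpha(log_r)
                if rng.random() < a:
                    sigma_s, s, eta, ll = prop, s_new, eta_new, ll_new
            else:
                a = 0.0
            st.record(a)
            if adapting:
                st.adapt(a)

            # elliptical slice sample s under MV-normal(0, sigma_s^2 R)
            nu = sigma_s * (cholR @ rng.standard_normal(J))
            eta_base = eta - s[clus]
            log_y = float(ll.sum()) + math.log(rng.random())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            t_lo, t_hi = theta - 2.0 * math.pi, theta
            while True:
                s_prop = s * math.cos(theta) + nu * math.sin(theta)
                eta_prop = eta_base + s_prop[clus]
                ll_prop = _bern_ll(eta_prop, sign)
                if float(ll_prop.sum()) > log_y:
                    s, eta, ll = s_prop, eta_prop, ll_prop
                    break
                if theta < 0.0:
                    t_lo = theta
                else:
                    t_hi = theta
                theta = rng.uniform(t_lo, t_hi)
                if t_hi - t_lo < 1e-12:  # numerical corner: keep current state
                    eta = eta_base + s[clus]
                    ll = _bern_ll(eta, sign)
                    break

        # hierarchical coefficient SDs
        beta_block = th[1:1 + Q]
        for key, vals, upper in (("sigma_beta", beta_block, priors.sd_upper_beta),
                                 ("sigma_gamma", th[1 + Q:], priors.sd_upper_gamma)):
            st = steps[key]
            cur = sigma_beta if key == "sigma_beta" else sigma_gamma
            eps = st.step * rng.standard_normal()
            prop = cur * math.exp(eps)
            if prop < upper and len(vals):
                S2 = float(vals @ vals)
                m = len(vals)
                log_r = (-m * math.log(prop) - 0.5 * S2 / prop ** 2) - \
                        (-m * math.log(cur) - 0.5 * S2 / cur ** 2) + eps
                a = _alpha(log_r)
                if rng.random() < a:
                    if key == "sigma_beta":
                        sigma_beta = prop
                    else:
                        sigma_gamma = prop
            elif prop < upper:
                # no coefficients in the block: target is the U(0, upper) prior
                a = _alpha(eps)
                if rng.random() < a:
                    if key == "sigma_beta":
                        sigma_beta = prop
                    else:
                        sigma_gamma = prop
            else:
                a = 0.0
            st.record(a)
            if adapting:
                st.adapt(a)

        # ---- within-chain imputation --------------------------------------
        mean_sd = 1.0 / math.sqrt(priors.impute_mean_precision)
        for item in imp_cont:
            q, name, idx = item["q"], item["name"], item["idx"]
            raw = X[:, q] + design.x_centers[q]
            n_all, S1, S2 = len(raw), float(raw.sum()), float(raw @ raw)

            def col_lp(mu, sd):
                return -n_all * math.log(sd) - 0.5 * (S2 - 2 * mu * S1 + n_all * mu * mu) / sd ** 2

            st = steps[f"mu_x:{name}"]
            eps = st.step * rng.standard_normal()
            prop = item["mu"] + eps
            log_r = col_lp(prop, item["sd"]) - col_lp(item["mu"], item["sd"]) + \
                    float(norm_lp(prop, mean_sd) - norm_lp(item["mu"], mean_sd))
            a = _alpha(log_r)
            st.record(a)
            if adapting:
                st.adapt(a)
            if rng.random() < a:
                item["mu"] = prop

            st = steps[f"sigma_x:{name}"]
            eps = st.step * rng.standard_normal()
            prop = item["sd"] * math.exp(eps)
            if prop < priors.sd_upper_impute:
                log_r = col_lp(item["mu"], prop) - col_lp(item["mu"], item["sd"]) + eps
                a = _alpha(log_r)
                if rng.random() < a:
                    item["sd"] = prop
            else:
                a = 0.0
            st.record(a)
            if adapting:
                st.adapt(a)

            # missing cells: independence proposal from the sub-model
            prop_raw = rng.normal(item["mu"], item["sd"], size=len(idx))
            b_q = th[1 + q]
            d_eta = b_q * (prop_raw - design.x_centers[q] - X[idx, q])
            eta_new = eta[idx] + d_eta
            ll_new = _bern_ll(eta_new, sign[idx])
            a_vec = np.exp(np.minimum(0.0, ll_new - ll[idx]))
            acc = rng.random(len(idx)) < a_vec
            if acc.any():
                rows = idx[acc]
                X[rows, q] = prop_raw[acc] - design.x_centers[q]
                eta[rows] = eta_new[acc]
                ll[rows] = ll_new[acc]

        for item in imp_cat:
            name, idx, K = item["name"], item["idx"], item["K"]
            cnt = np.bincount(codes[name], minlength=K).astype(float)
            eta_z = item["eta"]

            def cat_lp(ez):
                m = ez.max()
                return float(cnt @ ez) - cnt.sum() * (m + math.log(np.exp(ez - m).sum()))

            for k in range(1, K):
                st = steps[f"eta_z:{name}:{k}"]
                eps = st.step * rng.standard_normal()
                ez_new = eta_z.copy()
                ez_new[k] += eps
                log_r = cat_lp(ez_new) - cat_lp(eta_z) + \
                    float(norm_lp(ez_new[k] - item["mu"][k - 1], item["sd"]) -
                          norm_lp(eta_z[k] - item["mu"][k - 1], item["sd"]))
                a = _alpha(log_r)
                st.record(a)
                if adapting:
                    st.adapt(a)
                if rng.random() < a:
                    eta_z = ez_new
            item["eta"] = eta_z

            st = steps[f"mu_z:{name}"]
            eps = st.step * rng.standard_normal(K - 1)
            prop = item["mu"] + eps
            log_r = float((norm_lp(eta_z[1:] - prop, item["sd"]) + norm_lp(prop, mean_sd) -
                           norm_lp(eta_z[1:] - item["mu"], item["sd"]) - norm_lp(item["mu"], mean_sd)).sum())
            a = _alpha(log_r)
            st.record(a)
            if adapting:
                st.adapt(a)
            if rng.random() < a:
                item["mu"] = prop

            st = steps[f"sigma_z:{name}"]
            eps = st.step * rng.standard_normal()
            prop = item["sd"] * math.exp(eps)
            if prop < priors.sd_upper_impute:
                log_r = float((norm_lp(eta_z[1:] - item["mu"], prop) -
                               norm_lp(eta_z[1:] - item["mu"], item["sd"])).sum()) + eps
                a = _alpha(log_r)
                if rng.random() < a:
                    item["sd"] = prop
            else:
                a = 0.0
            st.record(a)
            if adapting:
                st.adapt(a)

            # missing cells: exact draw from the discrete full conditional
            g = gamma_vec(name)
            logpi = eta_z - (eta_z.max() + math.log(np.exp(eta_z - eta_z.max()).sum()))
            eta_no = eta[idx] - g[codes[name][idx]]
            cand = eta_no[:, None] + g[None, :]
            logw = logpi[None, :] + _bern_ll(cand, sign[idx][:, None])
            gum = -np.log(-np.log(rng.random(logw.shape)))
            new_codes = np.argmax(logw + gum, axis=1)
            codes[name][idx] = new_codes
            eta[idx] = eta_no + g[new_codes]
            ll[idx] = _bern_ll(eta[idx], sign[idx])

        # periodic full recompute guards against incremental drift
        if (it + 1) % 512 == 0:
            eta = full_eta()
            ll = _bern_ll(eta, sign)

        # ---- store ---------------------------------------------------------
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0 and keep < T:
            out["coef"][keep] = th
            out["sigma_beta"][keep] = sigma_beta
            out["sigma_gamma"][keep] = sigma_gamma
            out["sigma_u"][keep] = sigma_u
            out["u"][keep] = u
            if spatial:
                out["sigma_s"][keep] = sigma_s
                out["phi"][keep] = phi
                out["s"][keep] = s
            if store_loglik:
                loglik_obs[keep] = ll
            for item in imp_cont:
                imputed[item["name"]][keep] = X[item["idx"], item["q"]] + design.x_centers[item["q"]]
                out[f"mu_x:{item['name']}"][keep] = item["mu"]
                out[f"sigma_x:{item['name']}"][keep] = item["sd"]
            for item in imp_cat:
                imputed[item["name"]][keep] = codes[item["name"]][item["idx"]]
                out[f"eta_z:{item['name']}"][keep] = item["eta"][1:]
                out[f"mu_z:{item['name']}"][keep] = item["mu"]
                out[f"sigma_z:{item['name']}"][keep] = item["sd"]
            keep += 1

        if verbose and (it + 1) % 1000 == 0:
            print(f"iter {it + 1}/{mcmc.n_iterations}  loglik {float(ll.sum()):.1f}")

    acceptance = {k: v.rate for k, v in steps.items()}
    return PosteriorSamples(model=2 if spatial else 1, coef_names=coef_names, draws=out,
                            loglik_obs=loglik_obs, imputed=imputed,
                            cluster_ids=np.asarray(clusters.ids), schema=schema,
                            acceptance=acceptance, config=mcmc)


def _corr_chol(d: np.ndarray, phi: float, jitter: float = 1e-10) -> np.ndarray:
    R = np.exp(-phi * d)
    R[np.diag_indices_from(R)] += jitter
    return np.linalg.cholesky(R)


# ---------------------------------------------------------------------------
# summaries & diagnostics
# ---------------------------------------------------------------------------

def summarize_fixed_effects(samples: PosteriorSamples) -> pd.DataFrame:
    """Adjusted odds-ratio table: posterior mean of exp(coefficient) with the
    (2.5%, 97.5%) quantile interval of exp(coefficient); reference categories
    shown with OR 1.000.  Continuous effects are per unit on the centered
    scale."""
    if samples.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    coef = samples.draws["coef"]
    rows = []

    def add(label, draws, kind, reference=False):
        if reference:
            rows.append({"term": label, "kind": kind, "odds_ratio": 1.0,
                         "ci_low": 1.0, "ci_high": 1.0, "reference": True})
        else:
            ex = np.exp(draws)
            lo, hi = np.quantile(ex, (0.025, 0.975))
            rows.append({"term": label, "kind": kind, "odds_ratio": float(ex.mean()),
                         "ci_low": float(lo), "ci_high": float(hi), "reference": False})

    names = samples.coef_names
    add("(Intercept)", coef[:, 0], "intercept")
    i = 1
    for cov in samples.schema.continuous:
        add(f"{cov.name} (per unit, centered)", coef[:, i], "continuous")
        i += 1
    for cov in samples.schema.categorical:
        add(f"{cov.name}[{cov.reference}]", None, "categorical", reference=True)
        for cat in cov.categories[1:]:
            add(names[i], coef[:, i], "categorical")
            i += 1
    return pd.DataFrame(rows)


def convergence_diagnostics(chains, min_ess: float = 400.0,
                            rhat_limit: float = 1.1) -> pd.DataFrame:
    """Split R-hat and effective sample size per scalar parameter.

    ``chains`` is either a list of :class:`PosteriorSamples` (multi-chain) or
    a dict mapping parameter names to (n_chains, n_draws) arrays.  A
    parameter exceeding ``rhat_limit`` triggers a warning, not an error — the
    report still carries the numbers.
    """
    import arviz as az

    if isinstance(chains, PosteriorSamples):
        chains = [chains]
    if isinstance(chains, dict):
        data = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in chains.items()}
    else:
        data = {}
        ref = chains[0]
        for j, nm in enumerate(ref.coef_names):
            data[nm] = np.stack([c.draws["coef"][:, j] for c in chains])
        for key in ("sigma_beta", "sigma_gamma", "sigma_u", "sigma_s", "phi"):
            if key in ref.draws:
                data[key] = np.stack([c.draws[key] for c in chains])
    idata = az.from_dict(posterior={k: v for k, v in data.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for k in data:
        r = float(rhat[k].values)
        e = float(ess[k].values)
        rows.append({"parameter": k, "rhat": r, "ess": e,
                     "converged": bool((r < rhat_limit or math.isnan(r)) and e > min_ess)})
        if np.isfinite(r) and r > rhat_limit:
            warnings.warn(f"R-hat {r:.3f} > {rhat_limit} for parameter {k!r}: "
                          "chains have not mixed")
    return pd.DataFrame(rows)
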