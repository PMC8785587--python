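"""Core data model for Bayesian geostatistical logistic regression.

The model analysed throughout this package is a cluster-survey logistic
regression with a latent Gaussian random field::

    y_ij ~ Bernoulli(p_ij)
    logit(p_ij) = beta0 + sum_q beta_q * X_iq + sum_l gamma_l * Z_il + s_j + u_j

where ``i`` indexes children and ``j`` their survey cluster.  ``s`` is a
zero-mean Gaussian random field over cluster locations with isotropic
exponential covariance ``sigma_s^2 * exp(-phi * d)`` (``d`` in km), and
``u_j ~ N(0, sigma_u^2)`` is exchangeable cluster noise.  Continuous
covariates are centered on their observed means; categorical covariates use
corner constraints (reference category coefficient pinned to 0).

This module owns the covariate schema, design construction, distances,
covariance, likelihood, priors, and the covariate imputation sub-model
densities shared by the two fitted models (with and without ``s``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import solve_triangular

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "Covariate",
    "CovariateSchema",
    "PriorSpec",
    "ClusterSet",
    "Parameters",
    "Design",
    "build_design",
    "haversine_km",
    "pairwise_distances",
    "exponential_covariance",
    "covariance_cholesky",
    "bernoulli_loglik",
    "linear_predictor",
    "log_likelihood",
    "log_prior",
    "imputation_logdensity",
    "softmax",
]


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

@dataclass
class Covariate:
    """One covariate in the schema.

    For categorical covariates ``categories`` is the ordered category list
    with the reference (lowest-risk) category first.  ``probs`` / ``mean`` /
    ``sd`` are the generative marginals used by the synthetic-data module;
    they are optional for fitting real data.
    """

    name: str
    kind: str  # "continuous" | "categorical"
    categories: Optional[list] = None
    center: bool = True
    mean: Optional[float] = None
    sd: Optional[float] = None
    probs: Optional[list] = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if not self.categories or len(self.categories) < 2:
                raise ValueError(f"categorical covariate {self.name!r} needs >= 2 categories")
            if self.probs is not None:
                p = np.asarray(self.probs, dtype=float)
                if len(p) != len(self.categories):
                    raise ValueError(f"{self.name!r}: probs length != number of categories")
                if abs(p.sum() - 1.0) > 1e-6:
                    raise ValueError(f"{self.name!r}: category probabilities sum to {p.sum():.6f}, not 1")

    @property
    def reference(self):
        return self.categories[0] if self.categories else None

    @property
    def n_categories(self) -> int:
        return len(self.categories) if self.categories else 0


@dataclass
class CovariateSchema:
    """Ordered collection of covariates with unique names."""

    covariates: list

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")

    def __iter__(self):
        return iter(self.covariates)

    def __getitem__(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [c.name for c in self.covariates]

    @property
    def continuous(self) -> list:
        return [c for c in self.covariates if c.kind == "continuous"]

    @property
    def categorical(self) -> list:
        return [c for c in self.covariates if c.kind == "categorical"]

    # -- round-trippable file contract -------------------------------------
    def to_dict(self) -> dict:
        return {"covariates": [
            {k: v for k, v in asdict(c).items() if v is not None and not (k == "center" and c.kind == "categorical")}
            for c in self.covariates
        ]}

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSchema":
        return cls([Covariate(**c) for c in d["covariates"]])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CovariateSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PriorSpec:
    """Prior hyperparameters.

    Coefficient priors are hierarchical normals ``beta_q ~ N(0, sigma_beta^2)``
    with ``sigma_beta ~ U(0, sd_upper_beta)`` (one SD shared across continuous
    coefficients, one across categorical contrasts).  Spatial SD and decay get
    ``sigma_s ~ U(0, 10)`` and ``phi ~ U(phi_lower, phi_upper)`` per km.
    Imputation means get vague normals (precision 0.001, i.e. variance 1000,
    the BUGS-style (mean, precision) parameterisation) and imputation SDs
    ``U(0, 10)``.
    """

    sd_upper_beta: float = 10.0
    sd_upper_gamma: float = 10.0
    sd_upper_spatial: float = 10.0
    sd_upper_unstructured: float = 10.0
    phi_lower: float = 0.0
    phi_upper: float = 1.0
    impute_mean_precision: float = 0.001
    sd_upper_impute: float = 10.0
    intercept_sd: float = 10.0

    def __post_init__(self) -> None:
        for name in ("sd_upper_beta", "sd_upper_gamma", "sd_upper_spatial",
                     "sd_upper_unstructured", "sd_upper_impute"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.phi_upper <= self.phi_lower:
            raise ValueError("phi_upper must exceed phi_lower")
        if self.impute_mean_precision <= 0:
            raise ValueError("impute_mean_precision must be > 0")


# ---------------------------------------------------------------------------
# clusters & distances
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between (lon, lat) points in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class ClusterSet:
    """Survey clusters: ids, coordinates, and a derived km distance matrix.

    ``crs`` is ``"lonlat"`` (degrees, distances via haversine) or ``"km"``
    (planar coordinates in km, Euclidean distances).
    """

    ids: np.ndarray
    coords: np.ndarray
    crs: str = "lonlat"
    _distances: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (J, 2)")
        if len(self.ids) != len(self.coords):
            raise ValueError("ids and coords length mismatch")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("cluster ids must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite cluster coordinates")
        if self.crs not in ("lonlat", "km"):
            raise ValueError(f"unknown crs {self.crs!r}")
        if self.crs == "lonlat" and np.any(np.abs(self.coords[:, 1]) > 90.0):
            raise ValueError("latitude outside [-90, 90]")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def distances(self) -> np.ndarray:
        if self._distances is None:
            self._distances = pairwise_distances(self)
        return self._distances

    def index_of(self, cluster_ids: Sequence) -> np.ndarray:
        """Map cluster ids to 0-based positions; unknown id raises KeyError."""
        lookup = {cid: k for k, cid in enumerate(self.ids.tolist())}
        try:
            return np.array([lookup[c] for c in cluster_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown cluster id {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        a, b = ("lon", "lat") if self.crs == "lonlat" else ("x_km", "y_km")
        return pd.DataFrame({"cluster_id": self.ids, a: self.coords[:, 0], b: self.coords[:, 1]})


def pairwise_distances(clusters: ClusterSet) -> np.ndarray:
    """J x J inter-cluster distance matrix in km."""
    c = clusters.coords
    if clusters.crs == "lonlat":
        d = haversine_km(c[:, 0][:, None], c[:, 1][:, None], c[None, :, 0], c[None, :, 1])
    else:
        diff = c[:, None, :] - c[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)  # enforce exact symmetry


def exponential_covariance(d: np.ndarray, sigma_s: float, phi: float) -> np.ndarray:
    """Sigma_jk = sigma_s^2 * exp(-phi * d_jk) for a valid distance matrix."""
    d = np.asarray(d, dtype=float)
    if sigma_s < 0:
        raise ValueError("sigma_s must be >= 0")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("d must be a symmetric square distance matrix")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distance entries")
    return sigma_s ** 2 * np.exp(-phi * d)


def covariance_cholesky(d: np.ndarray, sigma_s: float, phi: float, jitter: float = 1e-10) -> np.ndarray:
    """Lower Cholesky factor of the exponential covariance with diagonal jitter.

    The jitter (``1e-10 * sigma_s^2``) keeps near-duplicate locations
    numerically positive definite.
    """
    cov = exponential_covariance(d, sigma_s, phi)
    cov[np.diag_indices_from(cov)] += jitter * max(sigma_s ** 2, 1.0)
    return np.linalg.cholesky(cov)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Prepared model inputs.

    Continuous covariates live in ``X`` (centered on observed means, missing
    cells hold the placeholder 0 = the mean, overwritten by imputation draws
    during sampling).  Categorical covariates are stored as integer codes
    into each covariate's category list, -1 for missing.
    """

    y: np.ndarray
    cluster_index: np.ndarray
    X: np.ndarray                     # (n, Q), centered
    x_missing: np.ndarray             # (n, Q) bool
    x_centers: np.ndarray             # (Q,)
    x_names: list
    codes: dict                       # name -> (n,) int, -1 missing
    cat_missing: dict                 # name -> (n,) bool
    schema: CovariateSchema

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def coef_names(self) -> list:
        names = ["(Intercept)"] + list(self.x_names)
        for c in self.schema.categorical:
            names += [f"{c.name}[{cat}]" for cat in c.categories[1:]]
        return names

    def indicator_matrix(self, codes: Optional[dict] = None):
        """K-1 dummy expansion of the categorical block (reference omitted)."""
        codes = codes if codes is not None else self.codes
        cols, names = [], []
        for c in self.schema.categorical:
            code = codes[c.name]
            for k, cat in enumerate(c.categories[1:], start=1):
                cols.append((code == k).astype(float))
                names.append(f"{c.name}[{cat}]")
        Z = np.column_stack(cols) if cols else np.empty((self.n, 0))
        return Z, names

    def decode_categories(self, name: str, codes: Optional[np.ndarray] = None) -> np.ndarray:
        """Inverse of the coding: integer codes back to category labels."""
        cov = self.schema[name]
        code = self.codes[name] if codes is None else codes
        out = np.empty(len(code), dtype=object)
        valid = code >= 0
        out[valid] = np.asarray(cov.categories, dtype=object)[code[valid]]
        out[~valid] = None
        return out


def build_design(table: pd.DataFrame, schema: CovariateSchema,
                 clusters: Optional[ClusterSet] = None) -> Design:
    """Build the design from a child table.

    ``table`` must carry ``y``, ``cluster_id`` and every schema covariate.
    Rows with missing ``y`` are rejected (only children with valid
    anthropometry enter the analysis).
    """
    if "y" not in table or "cluster_id" not in table:
        raise ValueError("child table requires 'y' and 'cluster_id' columns")
    y_raw = table["y"]
    if y_raw.isna().any():
        raise ValueError("missing outcome values are not allowed; drop those rows at load")
    y = y_raw.to_numpy()
    if not np.isin(y, (0, 1)).all():
        bad = int(np.flatnonzero(~np.isin(y, (0, 1)))[0])
        raise ValueError(f"outcome must be 0/1; offending row {bad}")
    y = y.astype(np.int8)

    if clusters is not None:
        cluster_index = clusters.index_of(table["cluster_id"].tolist())
    else:
        _, cluster_index = np.unique(table["cluster_id"].to_numpy(), return_inverse=True)

    x_cols, x_missing, centers, x_names = [], [], [], []
    for cov in schema.continuous:
        if cov.name not in table:
            raise ValueError(f"covariate column {cov.name!r} missing from table")
        col = pd.to_numeric(table[cov.name], errors="coerce").to_numpy(dtype=float)
        miss = ~np.isfinite(col)
        if miss.all():
            raise ValueError(f"covariate {cov.name!r} has no observed values")
        center = float(np.mean(col[~miss])) if cov.center else 0.0
        out = col - center
        out[miss] = 0.0  # placeholder at the (centered) mean
        x_cols.append(out)
        x_missing.append(miss)
        centers.append(center)
        x_names.append(cov.name)
    X = np.column_stack(x_cols) if x_cols else np.empty((len(y), 0))
    Xm = np.column_stack(x_missing) if x_missing else np.zeros((len(y), 0), dtype=bool)

    codes, cat_missing = {}, {}
    for cov in schema.categorical:
        if cov.name not in table:
            raise ValueError(f"covariate column {cov.name!r} missing from table")
        raw = table[cov.name]
        lookup = {cat: k for k, cat in enumerate(cov.categories)}
        code = np.full(len(raw), -1, dtype=np.int64)
        for i, v in enumerate(raw.tolist()):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            if v not in lookup:
                raise ValueError(f"unknown category {v!r} for covariate {cov.name!r} at row {i}")
            code[i] = lookup[v]
        codes[cov.name] = code
        cat_missing[cov.name] = code < 0

    return Design(y=y, cluster_index=np.asarray(cluster_index, dtype=np.intp), X=X,
                  x_missing=Xm, x_centers=np.asarray(centers, dtype=float),
                  x_names=x_names, codes=codes, cat_missing=cat_missing, schema=schema)


# ---------------------------------------------------------------------------
# parameters, likelihood, priors
# ---------------------------------------------------------------------------

@dataclass
class Parameters:
    """One point in parameter space (all symbols of the model)."""

    beta0: float
    beta: np.ndarray                     # (Q,) continuous effects
    gamma: dict                          # name -> (K,) with gamma[0] == 0
    sigma_beta: float = 1.0
    sigma_gamma: float = 1.0
    sigma_u: float = 1.0
    u: Optional[np.ndarray] = None       # (J,)
    sigma_s: Optional[float] = None
    phi: Optional[float] = None
    s: Optional[np.ndarray] = None       # (J,)
    mu_x: dict = field(default_factory=dict)      # name -> float
    sigma_x: dict = field(default_factory=dict)
    eta_z: dict = field(default_factory=dict)     # name -> (K,) with eta[0] == 0
    mu_z: dict = field(default_factory=dict)      # name -> (K-1,)
    sigma_z: dict = field(default_factory=dict)


def softmax(eta: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    eta = np.asarray(eta, dtype=float)
    m = eta.max(axis=-1, keepdims=True)
    e = np.exp(eta - m)
    return e / e.sum(axis=-1, keepdims=True)


def bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-observation log Pr(y | eta), stable for extreme eta."""
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    sign = 2.0 * np.asarray(y) - 1.0
    return -np.logaddexp(0.0, -sign * eta)


def linear_predictor(params: Parameters, design: Design) -> np.ndarray:
    """eta_ij = beta0 + X beta + Z gamma + s_j + u_j with current imputations."""
    eta = np.full(design.n, params.beta0, dtype=float)
    if design.X.shape[1]:
        eta += design.X @ np.asarray(params.beta, dtype=float)
    for cov in design.schema.categorical:
        g = np.asarray(params.gamma[cov.name], dtype=float)
        code = design.codes[cov.name]
        contrib = np.where(code >= 0, g[np.clip(code, 0, None)], 0.0)
        eta += contrib
    n_clusters = int(design.cluster_index.max()) + 1 if design.n else 0
    for vec in (params.u, params.s):
        if vec is not None:
            n_clusters = max(n_clusters, len(vec))
    re = np.zeros(n_clusters)
    if params.u is not None:
        re = re + np.asarray(params.u, dtype=float)
    if params.s is not None:
        re = re + np.asarray(params.s, dtype=float)
    eta += re[design.cluster_index]
    return eta


def log_likelihood(params: Parameters, design: Design) -> float:
    """Bernoulli log-likelihood of the full table at ``params``."""
    return float(bernoulli_loglik(linear_predictor(params, design), design.y).sum())


def _norm_logpdf(x, sd) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * math.log(2.0 * math.pi)


def mvn_logpdf_chol(x: np.ndarray, L: np.ndarray) -> float:
    """MV-normal(0, LL') log-density."""
    w = solve_triangular(L, np.asarray(x, dtype=float), lower=True)
    return float(-0.5 * w @ w - np.log(np.diag(L)).sum() - 0.5 * len(x) * math.log(2.0 * math.pi))


def log_prior(params: Parameters, priors: PriorSpec, distances: Optional[np.ndarray] = None,
              spatial: bool = True) -> float:
    """Joint log-prior; -inf outside the uniform supports.

    Uniform SD priors contribute a constant (taken as 0) inside support.
    The spatial block needs ``distances`` when ``spatial`` and s is present.
    """
    lp = 0.0
    # support checks
    for val, hi in ((params.sigma_beta, priors.sd_upper_beta),
                    (params.sigma_gamma, priors.sd_upper_gamma),
                    (params.sigma_u, priors.sd_upper_unstructured)):
        if not (0.0 < val < hi):
            return -math.inf
    lp += float(_norm_logpdf(params.beta0, priors.intercept_sd))
    if len(np.atleast_1d(params.beta)):
        lp += float(_norm_logpdf(params.beta, params.sigma_beta).sum())
    for g in params.gamma.values():
        g = np.asarray(g, dtype=float)
        if g[0] != 0.0:
            return -math.inf
        lp += float(_norm_logpdf(g[1:], params.sigma_gamma).sum())
    if params.u is not None:
        lp += float(_norm_logpdf(params.u, params.sigma_u).sum())
    if spatial and params.s is not None:
        if not (0.0 < params.sigma_s < priors.sd_upper_spatial):
            return -math.inf
        if not (priors.phi_lower < params.phi < priors.phi_upper):
            return -math.inf
        if distances is None:
            raise ValueError("distances required for the spatial prior")
        L = covariance_cholesky(distances, params.sigma_s, params.phi)
        lp += mvn_logpdf_chol(params.s, L)
    # imputation-model parameter priors
    mean_sd = 1.0 / math.sqrt(priors.impute_mean_precision)
    for name, mu in params.mu_x.items():
        sx = params.sigma_x[name]
        if not (0.0 < sx < priors.sd_upper_impute):
            return -math.inf
        lp += float(_norm_logpdf(mu, mean_sd))
    for name, eta in params.eta_z.items():
        eta = np.asarray(eta, dtype=float)
        if eta[0] != 0.0:
            return -math.inf
        sz = params.sigma_z.get(name, 1.0)
        if not (0.0 < sz < priors.sd_upper_impute):
            return -math.inf
        mu_z = np.asarray(params.mu_z.get(name, np.zeros(len(eta) - 1)), dtype=float)
        lp += float(_norm_logpdf(eta[1:] - mu_z, sz).sum())
        lp += float(_norm_logpdf(mu_z, mean_sd).sum())
    return lp


def imputation_logdensity(params: Parameters, design: Design) -> float:
    """Log-density of the covariate sub-models at observed + imputed values.

    Continuous: X_i ~ N(mu_X, sigma_X^2) on the raw (uncentered) scale.
    Categorical: Z_i ~ Multinomial(1, pi) with pi = softmax(eta_Z),
    eta_Z1 = 0 pinned at the base category.
    """
    ld = 0.0
    for q, name in enumerate(design.x_names):
        if name not in params.mu_x:
            continue
        raw = design.X[:, q] + design.x_centers[q]
        ld += float(_norm_logpdf(raw - params.mu_x[name], params.sigma_x[name]).sum())
    for cov in design.schema.categorical:
        if cov.name not in params.eta_z:
            continue
        eta = np.asarray(params.eta_z[cov.name], dtype=float)
        logpi = eta - np.log(np.exp(eta - eta.max()).sum()) - eta.max()
        code = design.codes[cov.name]
        ld += float(logpi[code[code >= 0]].sum())
    return ld
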