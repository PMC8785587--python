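"""DHS-like cluster-survey simulator with known ground truth.

Emulates the structure of a national anthropometric cluster survey:
geo-located clusters, a handful of measured children per cluster, a latent
spatial risk field with exponential covariance plus exchangeable cluster
noise, logistic outcomes, and covariates drawn from normal / multinomial
marginals with configurable MCAR missingness (the under-two feeding
covariates are ~60% missing by design, since they are only collected for
children below two years).

Defaults mirror the 2015 Rwanda survey scale: ~500 clusters inside a
Rwanda-sized bounding box, 4-12 children per cluster, 38% baseline
prevalence, and marginals / effect sizes taken from the study population
the package is modelled on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .model import (ClusterSet, Covariate, CovariateSchema, covariance_cholesky)

__all__ = [
    "SyntheticConfig",
    "TrueParameters",
    "default_schema",
    "sample_cluster_locations",
    "sample_gaussian_field",
    "sample_covariates",
    "apply_mcar_missingness",
    "sample_outcomes",
    "simulate",
]

#: Rwanda-like extent (lon_min, lat_min, lon_max, lat_max), degrees.
RWANDA_BBOX = (28.85, -2.85, 30.9, -1.05)


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def default_schema() -> CovariateSchema:
    """Covariate schema of the study population, with generative marginals.

    Category order puts the lowest-risk (reference) category first; the
    ``probs``/``mean``/``sd`` entries are the population marginals used by
    the generator.
    """
    return CovariateSchema([
        Covariate("age_months", "continuous", mean=28.5, sd=17.0),
        Covariate("birthweight_kg", "continuous", mean=3.4, sd=0.5),
        Covariate("birth_interval_months", "continuous", mean=44.0, sd=25.0),
        Covariate("sex", "categorical", categories=["Female", "Male"], probs=[0.492, 0.508]),
        Covariate("exclusive_breastfeeding", "categorical", categories=["Yes", "No"], probs=[0.252, 0.748]),
        Covariate("diarrhoea", "categorical", categories=["No", "Yes"], probs=[0.871, 0.129]),
        Covariate("deworming", "categorical", categories=["Yes", "No"], probs=[0.737, 0.263]),
        Covariate("dietary_diversity", "categorical", categories=["Yes", "No"], probs=[0.215, 0.785]),
        Covariate("mother_education", "categorical",
                  categories=["Secondary+", "Primary", "None"], probs=[0.129, 0.727, 0.144]),
        Covariate("mother_bmi", "categorical",
                  categories=["Underweight", "Normal", "Overweight"], probs=[0.048, 0.726, 0.226]),
        Covariate("sanitation", "categorical", categories=["Improved", "Non-improved"], probs=[0.700, 0.300]),
        Covariate("flooring", "categorical", categories=["Good", "Poor"], probs=[0.216, 0.784]),
        Covariate("cooking_fuel", "categorical", categories=["Good/medium", "Poor"], probs=[0.152, 0.848]),
        Covariate("water_source", "categorical", categories=["Improved", "Non-improved"], probs=[0.716, 0.284]),
        Covariate("wealth_index", "categorical",
                  categories=["Richest", "Richer", "Middle", "Poorer", "Poorest"],
                  probs=[0.167, 0.170, 0.195, 0.220, 0.248]),
        Covariate("residence", "categorical", categories=["Urban", "Rural"], probs=[0.164, 0.836]),
    ])


def _default_effects(schema: CovariateSchema) -> Tuple[np.ndarray, dict]:
    """Adjusted odds ratios of the study, on the log scale, as true effects."""
    or_cont = {"age_months": 1.015, "birthweight_kg": 0.961, "birth_interval_months": 1.000}
    or_cat = {
        "sex": [1.320], "exclusive_breastfeeding": [1.241], "diarrhoea": [1.181],
        "deworming": [0.762], "dietary_diversity": [0.931],
        "mother_education": [1.142, 1.154], "mother_bmi": [1.011, 0.823],
        "sanitation": [1.061], "flooring": [1.224], "cooking_fuel": [1.063],
        "water_source": [1.134], "wealth_index": [0.893, 1.012, 1.151, 1.240],
        "residence": [1.143],
    }
    beta = np.array([math.log(or_cont.get(c.name, 1.0)) for c in schema.continuous])
    gamma = {}
    for c in schema.categorical:
        ors = or_cat.get(c.name, [1.0] * (c.n_categories - 1))
        gamma[c.name] = np.array([0.0] + [math.log(v) for v in ors])
    return beta, gamma


def default_missing_rates() -> dict:
    """Observed missingness of the study table (under-2 covariates ~60%)."""
    return {
        "exclusive_breastfeeding": 0.614, "dietary_diversity": 0.591,
        "birthweight_kg": 0.074, "birth_interval_months": 0.280,
        "mother_bmi": 0.109, "sanitation": 0.009, "flooring": 0.008,
        "cooking_fuel": 0.008, "water_source": 0.008, "deworming": 0.001,
    }


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults are the survey-scale stated world."""

    n_clusters: int = 500
    children_per_cluster: Tuple[int, int] = (4, 12)
    bbox: Tuple[float, float, float, float] = RWANDA_BBOX
    crs: str = "lonlat"
    # logit(0.38) minus the mean categorical effect of the default schema
    # (0.720), so the default world's overall prevalence is the survey's 38%
    beta0: float = logit(0.38) - 0.7203306982361755
    beta: Optional[np.ndarray] = None          # defaults to study effects
    gamma: Optional[dict] = None
    sigma_s: float = 0.8
    phi: float = 0.05                          # per km
    sigma_u: float = 0.3
    covariate_schema: CovariateSchema = field(default_factory=default_schema)
    missing_rates: dict = field(default_factory=default_missing_rates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2 (a single point is not a field)")
        if self.sigma_s < 0 or self.sigma_u < 0:
            raise ValueError("sigma_s and sigma_u must be >= 0")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        lo, hi = self.children_per_cluster
        if not (1 <= lo <= hi):
            raise ValueError("children_per_cluster must be a valid integer range")
        for name, rate in self.missing_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"missing rate for {name!r} outside [0, 1]")
            if name == "y":
                raise ValueError("the outcome may not be masked")
        if self.beta is None:
            self.beta, g = _default_effects(self.covariate_schema)
            if self.gamma is None:
                self.gamma = g
        if self.gamma is None:
            self.gamma = {c.name: np.zeros(c.n_categories) for c in self.covariate_schema.categorical}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta"] = np.asarray(self.beta, dtype=float).tolist()
        d["gamma"] = {k: np.asarray(v, dtype=float).tolist() for k, v in self.gamma.items()}
        d["covariate_schema"] = self.covariate_schema.to_dict()
        d["children_per_cluster"] = list(self.children_per_cluster)
        d["bbox"] = list(self.bbox)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["covariate_schema"] = CovariateSchema.from_dict(d["covariate_schema"])
        d["children_per_cluster"] = tuple(d["children_per_cluster"])
        d["bbox"] = tuple(d["bbox"])
        d["beta"] = np.asarray(d["beta"], dtype=float)
        d["gamma"] = {k: np.asarray(v, dtype=float) for k, v in d["gamma"].items()}
        return cls(**d)


@dataclass
class TrueParameters:
    """Realized ground truth of one simulated survey."""

    beta0: float
    beta: np.ndarray
    gamma: dict
    sigma_s: float
    phi: float
    sigma_u: float
    s: np.ndarray
    u: np.ndarray

    def to_dict(self) -> dict:
        return {
            "beta0": float(self.beta0),
            "beta": np.asarray(self.beta, dtype=float).tolist(),
            "gamma": {k: np.asarray(v, dtype=float).tolist() for k, v in self.gamma.items()},
            "sigma_s": float(self.sigma_s), "phi": float(self.phi), "sigma_u": float(self.sigma_u),
            "s": np.asarray(self.s, dtype=float).tolist(),
            "u": np.asarray(self.u, dtype=float).tolist(),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# sampling operations
# ---------------------------------------------------------------------------

def sample_cluster_locations(n_clusters: int, bbox, seed=0, crs: str = "lonlat",
                             boundary=None, rng: Optional[np.random.Generator] = None) -> ClusterSet:
    """Uniform cluster locations in a bounding box, optional polygon rejection."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    x0, y0, x1, y1 = bbox
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate bounding box")
    rng = np.random.default_rng(seed) if rng is None else rng
    pts = np.empty((0, 2))
    while len(pts) < n_clusters:
        draw = rng.uniform((x0, y0), (x1, y1), size=(max(n_clusters, 64), 2))
        if boundary is not None:
            from shapely import points as _shp_points
            keep = boundary.contains(_shp_points(draw))
            draw = draw[np.asarray(keep)]
        pts = np.vstack([pts, draw])
    pts = pts[:n_clusters]
    ids = np.array([f"c{k:04d}" for k in range(n_clusters)])
    return ClusterSet(ids=ids, coords=pts, crs=crs)


def sample_gaussian_field(clusters: ClusterSet, sigma_s: float, phi: float,
                          seed=0, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One draw of the zero-mean GRF with covariance sigma_s^2 exp(-phi d)."""
    rng = np.random.default_rng(seed) if rng is None else rng
    z = rng.standard_normal(len(clusters))
    if sigma_s == 0.0:
        return np.zeros(len(clusters))
    L = covariance_cholesky(clusters.distances, sigma_s, phi)
    return L @ z


def sample_covariates(clusters: ClusterSet, children_per_cluster, schema: CovariateSchema,
                      seed=0, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Complete (pre-masking) child table from the schema's marginals."""
    rng = np.random.default_rng(seed) if rng is None else rng
    lo, hi = children_per_cluster
    sizes = rng.integers(lo, hi + 1, size=len(clusters))
    cluster_col = np.repeat(clusters.ids, sizes)
    n = int(sizes.sum())
    data = {"child_id": np.arange(n), "cluster_id": cluster_col}
    for cov in schema:
        if cov.kind == "continuous":
            if cov.mean is None or cov.sd is None:
                raise ValueError(f"{cov.name!r}: generator needs mean and sd")
            data[cov.name] = rng.normal(cov.mean, cov.sd, size=n)
        else:
            if cov.probs is None:
                raise ValueError(f"{cov.name!r}: generator needs category probabilities")
            p = np.asarray(cov.probs, dtype=float)
            if abs(p.sum() - 1.0) > 1e-6:
                raise ValueError(f"{cov.name!r}: category probabilities must sum to 1")
            codes = rng.choice(len(p), size=n, p=p / p.sum())
            data[cov.name] = np.asarray(cov.categories, dtype=object)[codes]
    return pd.DataFrame(data)


def sample_outcomes(table: pd.DataFrame, clusters: ClusterSet, true_params: TrueParameters,
                    seed=0, rng: Optional[np.random.Generator] = None,
                    schema: Optional[CovariateSchema] = None) -> pd.DataFrame:
    """Bernoulli outcomes from the linear predictor at the true parameters.

    Continuous covariates enter centered on their sample means, matching the
    reporting convention of the fitted model, so ``beta0`` is the logit
    prevalence of the average child.
    """
    schema = schema if schema is not None else default_schema()
    rng = np.random.default_rng(seed) if rng is None else rng
    n = len(table)
    eta = np.full(n, true_params.beta0, dtype=float)
    for q, cov in enumerate(schema.continuous):
        col = table[cov.name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError("outcomes must be generated before masking")
        eta += true_params.beta[q] * (col - col.mean() if cov.center else col)
    for cov in schema.categorical:
        g = np.asarray(true_params.gamma[cov.name], dtype=float)
        lookup = {cat: k for k, cat in enumerate(cov.categories)}
        codes = np.array([lookup[v] for v in table[cov.name]])
        eta += g[codes]
    re = true_params.s + true_params.u
    eta += re[clusters.index_of(table["cluster_id"].tolist())]
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    p = 1.0 / (1.0 + np.exp(-eta))
    out = table.copy()
    out.insert(2, "y", (rng.random(n) < p).astype(np.int8))
    return out


def apply_mcar_missingness(table: pd.DataFrame, missing_rates: dict,
                           seed=0, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Independently mask covariate cells completely at random."""
    rng = np.random.default_rng(seed) if rng is None else rng
    out = table.copy()
    for name, rate in missing_rates.items():
        if name in ("y", "cluster_id", "child_id"):
            raise ValueError(f"column {name!r} may not be masked")
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"missing rate for {name!r} outside [0, 1]")
        if name not in out:
            raise KeyError(f"no covariate column {name!r}")
        mask = rng.random(len(out)) < rate
        if out[name].dtype.kind in "fi":
            out[name] = out[name].astype(float)
            out.loc[mask, name] = np.nan
        else:
            out[name] = out[name].astype(object)
            out.loc[mask, name] = None
    return out


def simulate(config: SyntheticConfig):
    """Full survey draw: (child table with MCAR gaps, clusters, ground truth).

    All randomness flows from ``config.seed`` through named sub-streams, so
    identical configs give byte-identical tables.
    """
    root = np.random.SeedSequence(config.seed)
    keys = ("locations", "field", "noise", "covariates", "outcomes", "missing")
    streams = dict(zip(keys, (np.random.default_rng(s) for s in root.spawn(len(keys)))))

    clusters = sample_cluster_locations(config.n_clusters, config.bbox, crs=config.crs,
                                        rng=streams["locations"])
    s = sample_gaussian_field(clusters, config.sigma_s, config.phi, rng=streams["field"])
    u = streams["noise"].normal(0.0, config.sigma_u, size=len(clusters)) if config.sigma_u > 0 \
        else np.zeros(len(clusters))
    truth = TrueParameters(beta0=config.beta0, beta=np.asarray(config.beta, dtype=float),
                           gamma={k: np.asarray(v, dtype=float) for k, v in config.gamma.items()},
                           sigma_s=config.sigma_s, phi=config.phi, sigma_u=config.sigma_u,
                           s=s, u=u)
    table = sample_covariates(clusters, config.children_per_cluster, config.covariate_schema,
                              rng=streams["covariates"])
    table = sample_outcomes(table, clusters, truth, rng=streams["outcomes"],
                            schema=config.covariate_schema)
    table = apply_mcar_missingness(table, config.missing_rates, rng=streams["missing"])
    return table, clusters, truth
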