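import math

import numpy as np
import pytest

import geoprev as gp
from geoprev.model import Covariate, CovariateSchema


def small_schema() -> CovariateSchema:
    """Compact schema: two continuous + two categorical covariates."""
    return CovariateSchema([
        Covariate("x1", "continuous", mean=0.0, sd=1.0),
        Covariate("x2", "continuous", mean=2.0, sd=0.5),
        Covariate("g", "categorical", categories=["a", "b"], probs=[0.5, 0.5]),
        Covariate("h", "categorical", categories=["p", "q", "r"], probs=[0.4, 0.35, 0.25]),
    ])


def small_world(seed=7, n_clusters=30, children=(8, 12), missing=None,
                beta=(0.30, -0.50), gamma_g=0.405, sigma_s=0.6, phi=0.08, sigma_u=0.3):
    missing = {"x2": 0.15, "h": 0.2} if missing is None else missing
    schema = small_schema()
    cfg = gp.SyntheticConfig(
        n_clusters=n_clusters, children_per_cluster=children,
        beta0=math.log(0.35 / 0.65), beta=np.asarray(beta, dtype=float),
        gamma={"g": np.array([0.0, gamma_g]), "h": np.array([0.0, 0.26, -0.36])},
        sigma_s=sigma_s, phi=phi, sigma_u=sigma_u,
        covariate_schema=schema, missing_rates=missing, seed=seed)
    table, clusters, truth = gp.simulate(cfg)
    return cfg, table, clusters, truth


@pytest.fixture(scope="session")
def demo_fit():
    """One moderately sized Model 2 fit shared across read-only tests."""
    cfg, table, clusters, truth = small_world(seed=7)
    samples = gp.fit(table, clusters, cfg.covariate_schema,
                     mcmc=gp.McmcConfig(n_iterations=2500, burn_in=1000, seed=8),
                     spatial=True)
    return {"config": cfg, "table": table, "clusters": clusters, "truth": truth,
            "samples": samples}
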