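"""Model checking and comparison: CPO, B-p values, the scaled-CPO outlier
screen, and PsML as a pseudo Bayes factor between the non-spatial and
spatial models.
"""

import math

import numpy as np

import geoprev as gp
from geoprev.model import Covariate, CovariateSchema

schema = CovariateSchema([Covariate("x1", "continuous", mean=0, sd=1)])
config = gp.SyntheticConfig(n_clusters=100, children_per_cluster=(3, 5),
                            bbox=(0, 0, 100, 100), crs="km",
                            beta0=math.log(0.35 / 0.65), beta=np.array([0.3]),
                            gamma={}, sigma_s=1.0, phi=0.05, sigma_u=0.1,
                            covariate_schema=schema, missing_rates={}, seed=11)
table, clusters, _ = gp.simulate(config)

reports = {}
for model, spatial in ((1, False), (2, True)):
    samples = gp.fit(table, clusters, schema,
                     mcmc=gp.McmcConfig(n_iterations=4000, burn_in=2000, seed=model),
                     spatial=spatial)
    reports[model] = gp.validation_report(samples)
    s = reports[model].summary()
    print(f"model {model}: PsML {s['psml']:.1f}, CPO range "
          f"({s['cpo_min']:.2f}, {s['cpo_max']:.2f}), B-p range "
          f"({s['bp_min']:.2f}, {s['bp_max']:.2f}), "
          f"min scaled CPO {s['min_scaled_cpo']:.3f}, flagged {s['n_flagged']}")

diff = reports[2].psml - reports[1].psml
better = 2 if diff > 0 else 1
print(f"\nPsML difference (model 2 - model 1): {diff:+.1f} -> model {better} preferred")
# Larger PsML is better; no scaled CPO below 0.001 means no observation is
# an outlier with respect to either model.
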