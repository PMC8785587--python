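"""Descriptive layer: crosstab unadjusted odds ratios and the
multicollinearity screen.

The crosstab OR works identically on counts and on column percentages
(totals cancel), so a published two-way percentage table is enough to
recover its odds ratios.
"""

import numpy as np

import geoprev as gp

# column percentages (non-stunted, stunted) by child sex, reference first
sex_pct = np.array([[53.1, 42.9],   # Female (reference)
                    [46.9, 57.1]])  # Male
out = gp.crosstab_odds_ratio(sex_pct, categories=["Female", "Male"], kind="percent")
print(f"unadjusted OR male vs female: {out.odds_ratio[1]:.2f}")

# full descriptive table on a simulated survey
config = gp.SyntheticConfig(n_clusters=150, children_per_cluster=(6, 10), seed=7)
table, clusters, _ = gp.simulate(config)
t1 = gp.table_one(table, config.covariate_schema)
print("\ncategorical rows (first 6):")
cols = ["covariate", "category", "pct_non_stunted", "pct_stunted", "n", "odds_ratio"]
print(t1.dropna(subset=["pct_stunted"])[cols].head(6).to_string(index=False,
                                                               float_format="%.2f"))

flags = gp.multicollinearity_screen(table, schema=config.covariate_schema)
print(f"\ncovariate pairs with |r| > 0.7: {flags or 'none'}")
# Independently generated covariates should never be flagged; a flag here
# would mean two covariates carry the same information.
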