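"""Statistical layers: hypergeometric enrichment, simple correlation, and
the stepwise-AIC covariance model with known true coefficients."""

import numpy as np

import translatome_kit as tk
from translatome_kit.stats import default_model_spec

# Enrichment: 40 of 1000 genes carry a trait; a 100-gene subset shows 12.
# The p-value is P(N > 12) under the hypergeometric law (strictly greater).
p = tk.hypergeometric_enrichment(n1=100, n2=1000, m=40, n_obs=12)
print(f"enrichment p-value (12 of 100 vs 40 of 1000): {p:.2e}")

# Simple correlation between two features of the synthetic world.
features, response, true_coefs = tk.ancova_dataset(n=814, seed=3)
r, pv = tk.pearson_correlation(np.log(features["mrna_half_life"]),
                               np.log(response))
print(f"Pearson r(log half-life, log response) = {r:.2f} (p = {pv:.1e})")

# Covariance model: log response on centered/reduced covariates with
# bidirectional stepwise AIC selection. True nonzero effects include
# mRNA half-life -0.38 and CDS length +0.24; chromosome position, GRAVY
# and aromaticity are null.
fit = tk.fit_covariance_model(
    features.drop(columns="protein_level"), response,
    default_model_spec("ribosome_occupancy"),
)
print(f"selected {len(fit.selected)} covariates, "
      f"adjusted R^2 = {fit.adj_r2:.2f} (n = {fit.n_used})")
for name in fit.selected:
    truth = true_coefs.get(name, 0.0)
    print(f"  {name:28s} beta = {fit.coefficients[name]:+.2f} "
          f"(true {truth:+.2f}, p = {fit.p_values[name]:.1e})")
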