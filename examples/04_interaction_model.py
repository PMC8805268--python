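"""Spike-and-slab interaction model on gene summaries.

Planted check of the sampler itself: 20 standard-normal gene scores, a
single product interaction between two of them explaining ~10% of trait
variance, no main effects. The pair must emerge with the top interaction
PIP while null pairs stay near zero.
"""

import numpy as np

from dkpc import ModelConfig, fit, select_effects
from dkpc.containers import GeneSummary, PhenotypeVector

rng = np.random.default_rng(5)
n, p = 500, 20
sample_ids = [f"s{i:04d}" for i in range(n)]
x = rng.standard_normal((n, p))
summaries = [
    GeneSummary(f"gene{j:03d}", sample_ids, x[:, j], float(n)) for j in range(p)
]

term = x[:, 3] * x[:, 11]
term = (term - term.mean()) / term.std()
effect = np.sqrt(0.1 / 0.9)  # marginal R^2 of the pair ~= 0.1
y = PhenotypeVector(sample_ids, effect * term + rng.standard_normal(n), "corrected")

cfg = ModelConfig(k=10, d=2, n_iter=2000, n_burn=1000, thin=5, seed=5)
posterior = fit(summaries, y, cfg)

genes, pairs = select_effects(posterior, threshold=0.0)
print(f"retained draws: {posterior.n_retained}; "
      f"sigma^2 posterior mean {posterior.sigma2_trace.mean():.3f} (truth 1.0)")
print("genes with marginal PIP > 0:")
for gene, pip in genes[:5]:
    print(f"  {gene}: {pip:.3f}")
print("gene pairs with interaction PIP > 0 (planted: gene003 x gene011):")
for g1, g2, pip in pairs[:5]:
    print(f"  {g1} x {g2}: {pip:.3f}")
print(f"Geweke z for sigma^2 trace: {posterior.diagnostics['geweke_sigma2']:.2f}")
# A PIP is the fraction of retained Gibbs draws in which an effect was in
# the model; the planted pair should sit at or near 1.0 here, and the
# product-inclusion rule guarantees pair PIP <= both marginal PIPs.
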