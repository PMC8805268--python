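# dkpc — gene-level epistasis detection via diffusion-kernel principal components

Statistical epistasis — the dependence of one locus's phenotypic
contribution on the genotype at another — is notoriously hard to detect
from GWAS data: hundreds of thousands of SNPs give billions of pairs,
multiple-testing correction is crushing, and SNP-level hits replicate
poorly. `dkpc` implements a gene-level workflow for this problem, aimed at
statistical geneticists who already have post-QC genotypes and a SNP-to-gene
map (e.g. from eQTL annotation):

1. **Within-gene synergy networks.** For SNPs A, B and the (binned,
   population-structure-corrected) trait C, the bivariate synergy
   `Syn(A;B;C) = I(A,B;C) − I(A;C) − I(B;C)` measures what the pair carries
   about the trait beyond its parts. Per gene, the SNP×SNP synergy matrix
   defines a weighted graph; MRNET-style incremental search
   (`s_j = u_j − r_j`, relevance minus redundancy) yields reportable network
   statistics (density, mean distance, transitivity).
2. **Diffusion-kernel gene summaries.** The synergy graph's Laplacian L
   (synergies off-diagonal, rows summing to zero) generates diffusion
   kernels `K_L = e^{βL}`, averaged over β = 0, 0.1, …, 10. The n×n sandwich
   kernel `K = G K_L Gᵀ` blends genotypes with trait-informed SNP structure;
   after double centering, its first kernel principal component gives one
   score per individual per gene. With β = 0 this reduces exactly to the
   classical first PC of the gene's genotypes.
3. **Spike-and-slab interaction model.** Gene scores enter a Bayesian
   semi-parametric regression `Y ~ Normal(Σ_h f^(h)(X), σ²)` whose additive
   functions contain natural-spline main terms and product interaction
   terms, with point-mass-at-zero spikes and Gaussian slabs on the
   coefficients. Gene and gene-pair effects are ranked by Posterior
   Inclusion Probability (PIP) — the fraction of retained Gibbs draws
   including the effect — instead of multiplicity-corrected p-values, and
   assembled into a gene-level epistasis network (GraphML / TSV / gene-list
   exports).

A first-class synthetic-data generator (LD-correlated genotypes in gene
blocks, planted main/product/XOR-penetrance effects, PC-aligned
confounding, missingness) makes every stage testable offline, with ground
truth recorded. See `docs/methods.md` for the model details, defaults and
known limitations — including a structural one: single-SNP interactions are
attenuated by first-PC gene summarization, which the benchmarks quantify
rather than hide.

## Worked example

`examples/04_interaction_model.py` plants one product interaction between
two of 20 gene scores (marginal R² ≈ 0.1, n = 500) and fits the model:

```text
retained draws: 200; sigma^2 posterior mean 1.067 (truth 1.0)
genes with marginal PIP > 0:
  gene003: 1.000
  gene011: 1.000
  gene004: 0.145
  gene015: 0.140
  gene012: 0.120
gene pairs with interaction PIP > 0 (planted: gene003 x gene011):
  gene003 x gene011: 1.000
  gene014 x gene015: 0.035
  gene010 x gene013: 0.005
Geweke z for sigma^2 trace: -0.00
```

The planted pair is included in every retained draw (PIP 1.0) while null
pairs stay at chance level; the residual-variance estimate matches the
simulation truth. The other scripts in `examples/` walk the remaining
capabilities: study simulation (01), synergy networks and their statistics
(02), kernel summaries and the β = 0 → classical-PCA limit (03), and the
whole pipeline through to the exported epistasis network (05).

The same stages are scriptable from a shell (`dkpc simulate | impute |
correct | synergy | network | kernel | fit | report | run`), reading and
writing plain TSV/YAML/GraphML throughout.

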