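# Methods

`dkpc` detects gene-level epistasis from GWAS SNP data in three stages:
phenotype-informed **within-gene SNP networks**, **diffusion-kernel
principal-component gene summaries**, and a **spike-and-slab Bayesian
interaction model** on those summaries. This note records the model, the
parameters that matter, the numerical choices, what the synthetic generator
does and does not emulate, and the known limitations.

## Pre-processing

Genotypes are additively coded dosages in {0, 1, 2} with missing calls.
Missing genotypes are filled by k-nearest-neighbour imputation (default
k = 10): the distance between two samples is the Euclidean distance over the
SNPs observed in both, divided by the number of such shared SNPs so that
samples with different missingness patterns are comparable; the imputed
value is the mode of the SNP over the k nearest samples that are themselves
observed at that SNP (all of them if fewer than k exist). Ties in the mode
break toward the smaller genotype and ties in distance toward the earlier
sample, making imputation fully deterministic and idempotent. By default
neighbour distances use all SNPs; `knn_impute_by_gene` (CLI
`impute --gene-map`) restricts them to each gene's own SNPs, treating every
gene file as an independent imputation problem.

The phenotype — case/control or quantitative — is residualised on an
intercept plus the top `n_pcs` principal components of the column-centered
genotype matrix (default 7). PCs are computed from the analysis matrix
itself; a user-supplied covariate matrix can replace them. Beware of small
panels: with only a handful of genes the top genotype PCs coincide with the
per-gene LD factors and the correction will strip genuine gene-aligned
signal. The correction is meant for genome-scale panels where the leading
PCs capture ancestry, not individual genes; `n_pcs=0` reduces to centering.

SNPs are partitioned into per-gene blocks through a many-to-many SNP-to-gene
map (a SNP mapped to several genes enters each block); genes with fewer than
`min_snps` (default 3) mapped SNPs are dropped with a log message.

## Within-gene synergy networks

The corrected trait is discretized — equal-width bins over
`[min(y), max(y)]` with the cube-root rule `n_bins = round(n^(1/3))` by
default, the maximum value assigned to the top bin; a 1-d k-means mode is
available as an alternative, and binary raw traits pass through unbinned.
Constant traits are rejected (zero-width bins).

For SNPs A, B and the binned trait C, all information quantities are
plug-in (maximum-likelihood) estimates in bits:

    H(C)      = sum_c p(c) log2 1/p(c)
    H(C|A)    = sum_{a,c} p(a,c) log2 1/p(c|a)
    I(A;C)    = H(C) - H(C|A)
    Syn(A;B;C)= I(A,B;C) - I(A;C) - I(B;C)

with the joint predictor (A, B) coded as the Cartesian product of genotype
levels (up to 9 cells). Positive synergy: the pair is jointly more
informative than additively; negative: redundancy, the typical signature of
LD. No bias correction is applied — plug-in estimates keep the independent
counting oracles exact, and downstream structure is invariant to the log
base (a base change rescales every synergy by a constant, leaving MRMR
rankings unchanged). Entropy sums run over sorted cell counts so results are
independent of label coding at machine precision, which makes
`Syn(A;B;C) == Syn(B;A;C)` hold bit-exactly.

The synergy matrix (zero diagonal, symmetric) defines a weighted SNP graph
per gene. For reporting, a network is inferred with the MRNET rule: each SNP
in turn is the target, the others are greedily ranked by the
relevance-minus-redundancy score `s_j = W[j, target] - mean_{k in S} W[j, k]`
(ties to the lower index), the undirected edge weight is the maximum of the
two directional selection-time scores, and only strictly positive weights
are kept. Isolated nodes are retained. Reported statistics: density
`2|E| / m(m-1)`, mean unweighted geodesic distance over connected ordered
pairs, and global transitivity (3 x triangles / connected triples); the
latter two are flagged `nan` when undefined rather than raised. Negative
synergies enter the scores unclipped; only final edge scores are
thresholded. Note that under this rule a uniformly positive synergy matrix
keeps only first-selection edges (later scores are exactly zero): the
inferred graph is a reporting device, not the kernel input.

## Diffusion-kernel gene summaries

Per gene, the Laplacian puts synergies off-diagonal and negative row sums on
the diagonal (rows sum to zero), and the diffusion kernel is the matrix
exponential `K_L = exp(beta L)`, computed by symmetric eigendecomposition —
exact for symmetric L and reusable across the whole beta grid (one
decomposition, then spectral maps; O(m^3 + |grid| m) instead of |grid|
exponentials). `K_L` is symmetric positive definite for every real beta and
any weight signs, so negative synergies need no repair. beta = 0 is
special-cased to the exact identity.

Because a single diffusion strength is unlikely to suit every gene, the
kernel used is the elementwise average of `exp(beta L)` over beta = 0, 0.1,
..., 10.0 (101 values) — averaging lets each gene's own spectrum decide how
much diffusion matters. The n x n between-individual kernel is the sandwich
`K = G K_L G^T` with G the raw 0/1/2 genotype block by default; a
`standardize` flag centers and unit-scales the columns first. Raw is the
default because the subsequent double centering `K' = H K H`,
`H = I - 11^T/n`, removes sample-mean effects either way. The gene summary is the first kernel principal component of
`K'`: scores `sqrt(lambda_1) v_1`, so the score norm equals the root
eigenvalue; the sign is fixed by making the largest-magnitude score
positive. Kernels up to n = 512 use a dense symmetric eigensolver, larger
ones a truncated Lanczos solver asked only for the top eigenpair. A
non-positive leading eigenvalue raises an error naming the gene.

Two limits anchor the construction: with the {0} grid the summary equals
the classical first PC of the gene's genotypes (verified to 1e-8), and a
zero synergy matrix gives the identity kernel for any grid. An optional
mode (`use_mrnet_nodes`) restricts each gene's kernel to the non-isolated
nodes of its MRNET graph; the default uses the full synergy matrix.

## Interaction model

With one summary score per gene per individual, epistasis detection becomes
a variable-selection problem over p gene variables. The response model is a
sum of k additive functions

    Y_i ~ Normal(f(X_i), sigma^2),  f = sum_{h=1..k} f^(h),
    f^(h) = sum_j Xt_j b_j^(h) + sum_{j1<j2} (Xt_j1 * Xt_j2) b_j1j2^(h)

where `Xt_j` is a natural cubic spline basis (d functions, default d = 2;
d = 1 is the linear model) evaluated at the standardized scores, knots at
evenly spaced quantiles, and interaction blocks are elementwise products of
the two genes' basis columns (d^2 columns per pair). Gene j participates in
function h through a binary indicator zeta_jh; the coefficients of a term
are spiked to zero unless every gene in the term is active (the product
structure), so strong heredity holds by construction and pair inclusion
implies both marginal inclusions. A heredity indicator additionally zeroes
configurations where one function's nonempty active set is nested in
another's, removing redundant functions.

Priors: `zeta_jh ~ Bernoulli(tau_h)` with `tau_h ~ Beta(1, p)` (sparsity
scales with dimension); slab = zero-mean Gaussian with diagonal covariance
`v I`; `sigma^2 ~ InvGamma(1e-3, 1e-3)`. The slab variance is empirical
Bayes — the mean squared active coefficient, refreshed each sweep — floored
at `max(1e-6, 0.1 * sigma^2)`. The sigma^2-proportional floor matters: with
an absolute floor alone the slab can collapse, the marginal-likelihood
ratio for inclusion tends to 1 and selection becomes prior-driven; 0.1
matches the scale of standardized coefficients whose terms explain up to
roughly 10% of trait variance, the regime gene-level effects occupy.

Sampling: indicators are updated by Gibbs with the function's coefficients
integrated out analytically (the active design enters only through its Gram
matrix, whose eigendecomposition is cached per active set — every
marginal-likelihood evaluation is then vectorized spectral arithmetic).
Because a pure interaction offers no fit gain to either gene alone,
single-indicator moves mix poorly into it; each function also receives
joint pair-flip Metropolis proposals (default 10 per sweep), which leave
the posterior invariant and make pure interactions reachable. Coefficients,
tau_h, sigma^2 and the slab scale are then drawn from their conditionals.
Default schedule: 10 000 sweeps, 5 000 burn-in, thinning 5 (the recovery
benchmarks below use 2 000/1 000/5); k = 10 functions.

The sampler canonicalizes gene order internally (sorted by gene id, results
reported in input order), so permuting the input summaries permutes every
PIP identically under the same seed — a property a sequential scan cannot
otherwise have. All randomness flows from one integer seed;
runs are bit-reproducible.

Marginal PIP(j) = fraction of retained draws with gene j active in any
function; interaction PIP(j1, j2) = fraction with both active in a common
function. With finite chains "PIP > 0" means "included in at least one
retained draw"; `select_effects(strict=True)` instead requires a minimum
number of inclusion events. The sigma^2 trace is stored and a Geweke
z-score reported (warning only). The gene-level epistasis network has genes
as nodes (marginal PIP attribute) and pairs with interaction PIP above
threshold as edges; exports are GraphML, PIP-sorted TSV and a plain gene
list.

## Synthetic studies

The generator emulates post-QC GWAS data at desk scale. Within each gene,
two haplotypes per sample are drawn from a latent Gaussian with AR(rho)
correlation across the gene's SNPs and thresholded at each SNP's MAF
quantile (MAF ~ Uniform over `maf_range`); the genotype is the haplotype
sum. One knob (`ld_rho`, default 0.5) controls within-gene LD; `ld_rho = 0`
gives Hardy-Weinberg genotypes. Defaults: n = 500 samples, 20 genes x 8
SNPs, MAF 0.1-0.4, unit noise, and 0.062% missing completely at random (the
rate typical of post-QC call sets). The phenotype is a sum of standardized
causal terms — a centered causal-SNP genotype (main effect), a centered
genotype product (product epistasis), or a centered exactly-one-carrier
indicator (XOR-like penetrance, which creates pairwise synergy with almost
no marginal signal) — plus an optional confounder proportional to the first
genotype PC and Gaussian noise. Standardizing each term makes effect sizes
interpretable: an effect e contributes e^2 to the trait variance, so a
target marginal R^2 maps to `e = sqrt(R2/(1-R2)) * noise_sd`. Causal SNPs
are drawn uniformly within the named genes and recorded in a truth
registry. What the generator does not emulate: recombination maps, between-
gene LD, demography, genotyping-batch artifacts, case/control ascertainment
(a liability-threshold binarization is available for exercising the
correction step). Passing recovery tests therefore demonstrate the method's
behaviour under clean LD-block architectures, not performance on real
cohort structure.

## Recovery benchmarks and a structural limitation

Two seed-fixed benchmarks (n = 500, p = 20, 2 000-sweep chains, five seeds)
accompany the package. Planting a product interaction **directly on the
summaries** at marginal R^2 ~ 0.1 is recovered as the top interaction PIP
in at least 4/5 seeds, and under all-null configurations no interaction PIP
exceeds ~0.015 — the sampler itself is calibrated and powerful at this
signal size.

Planting the same interaction **on single causal SNPs** and running the
whole pipeline is a different matter, and the package is explicit about it:
the signal reaching the model is the product of two first-kPC summaries,
each an imperfect proxy for its causal SNP (|corr| ~ 0.4-0.6 at AR(0.5)
LD), and the interaction R^2 attenuates multiplicatively, by roughly
`corr_A^2 * corr_B^2`. Measured summary-level pair R^2 is 0.0001-0.01 —
below the chance maximum over the 190 null pairs (~0.02 at n = 500) — and
it saturates near 0.01 even when the SNP-level effect is made to dominate
the trait, because the first kPC cannot be forced onto a single SNP.
Single-SNP product epistasis between genes is therefore essentially
invisible to gene-level first-component summaries at these sample sizes;
signals distributed over a gene's SNPs (or tagged by strong within-gene LD)
are the regime where the summarization helps. This is a structural property
of gene-level dimension reduction, not a sampler defect, and is consistent
with interaction PIPs on real data being small. The end-to-end benchmark is
shipped as-is (and reported by `scripts/acceptance.py` as
`end_to_end_recovery_top_pair_rate`) rather than re-parameterized to pass.

## Numerical and engineering choices

- Missing sentinel -1 internally; `NA`/`-9` accepted on input.
- Distances, modes and all tie-breaks are deterministic; the whole pipeline
  is bit-reproducible under a seed, across runs on the same platform.
- Matrix exponentials via `eigh`; symmetry re-enforced after every
  sandwich/centering product to suppress drift.
- Kernel centering warns and no-ops on an already centered kernel.
- Equal-width binning assigns the maximum exactly to the top bin;
  `digitize` on interior edges avoids empty-edge pathologies.
- The spline basis is the truncated-power natural cubic basis; basis
  columns are standardized. The basis is not unique — tests compare fitted
  subspaces, not raw columns.
- The shipped benchmarks run at n = 500 samples, 20 genes x 8 SNPs and
  2 000-sweep chains with five fixed seeds; unit tests use smaller sizes
  (n <= 500, p <= 8 genes, chains of a few hundred sweeps).

## Known limitations

- First-component summaries only; cross-validated component counts are an
  extension point, not implemented.
- beta grid fixed, not tuned per gene.
- Normal response model only (binary traits are residualised first, as in
  the workflow this implements).
- PIPs from finite chains are lower-bounded by 1/retained draws; "PIP > 0"
  selections are chain-length dependent.
- The attenuation limitation described above: gene-level summaries trade
  single-SNP sensitivity for dimension reduction.
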