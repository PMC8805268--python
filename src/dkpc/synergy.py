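"""Information-theoretic synergy between SNP pairs and a discretized trait.

The bivariate synergy of SNPs A and B with respect to phenotype C is

    Syn(A;B;C) = I(A,B;C) - [I(A;C) + I(B;C)]

i.e. the information the SNP pair carries jointly about the trait beyond the
sum of their individual information gains. Positive synergy means the pair is
more informative together (epistasis-like signal); negative synergy means
redundancy (e.g. SNPs in strong LD). All quantities are plug-in
(maximum-likelihood) estimates from empirical frequencies, in bits by
default.
"""

from __future__ import annotations

import numpy as np

from .containers import DiscretePhenotype, GeneBlock, PhenotypeVector, SynergyMatrix
from .errors import ParameterError

__all__ = [
    "discretize_equal_width",
    "discretize_kmeans",
    "discretize",
    "entropy",
    "conditional_entropy",
    "information_gain",
    "synergy",
    "synergy_matrix",
]


def _auto_bins(n: int) -> int:
    return max(2, int(round(n ** (1.0 / 3.0))))


def discretize_equal_width(
    y: PhenotypeVector, n_bins: int | str = "auto"
) -> DiscretePhenotype:
    """Bin a corrected phenotype into equal-width intervals.

    Bin edges partition ``[min(y), max(y)]`` into ``n_bins`` intervals of
    equal width; the maximum value is assigned to the last bin. ``"auto"``
    uses the cube-root rule ``round(n ** (1/3))``.
    """
    v = np.asarray(y.values, float)
    n = v.size
    b = _auto_bins(n) if n_bins == "auto" else int(n_bins)
    if b < 2 or n < b:
        raise ParameterError(f"need n >= n_bins >= 2, got n={n}, n_bins={b}")
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise ParameterError("constant phenotype cannot be binned (zero-width bins)")
    edges = np.linspace(lo, hi, b + 1)
    labels = np.minimum(np.digitize(v, edges[1:-1], right=False) + 1, b)
    return DiscretePhenotype(list(y.sample_ids), labels, b, edges)


def discretize_kmeans(
    y: PhenotypeVector, n_bins: int | str = "auto", seed: int = 0
) -> DiscretePhenotype:
    """Alternative binning: 1-d k-means clusters, relabelled in value order.

    Bin "edges" are the midpoints between sorted cluster centres, so the
    result is expressible as interval binning as well.
    """
    from sklearn.cluster import KMeans

    v = np.asarray(y.values, float)
    n = v.size
    b = _auto_bins(n) if n_bins == "auto" else int(n_bins)
    if b < 2 or n < b:
        raise ParameterError(f"need n >= n_bins >= 2, got n={n}, n_bins={b}")
    if float(v.max()) <= float(v.min()):
        raise ParameterError("constant phenotype cannot be binned")
    km = KMeans(n_clusters=b, n_init=10, random_state=seed).fit(v.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    relabel = np.empty(b, dtype=int)
    relabel[order] = np.arange(1, b + 1)
    labels = relabel[km.labels_]
    mids = (centers[order][1:] + centers[order][:-1]) / 2.0
    edges = np.concatenate([[v.min()], mids, [v.max()]])
    return DiscretePhenotype(list(y.sample_ids), labels, b, edges)


def discretize(
    y: PhenotypeVector, n_bins: int | str = "auto", method: str = "equal_width", seed: int = 0
) -> DiscretePhenotype:
    """Dispatch on binning method; binary raw traits pass through unbinned."""
    if y.is_binary:
        labels = y.values.astype(int) + 1
        return DiscretePhenotype(list(y.sample_ids), labels, 2, np.array([-0.5, 0.5, 1.5]))
    if method == "equal_width":
        return discretize_equal_width(y, n_bins)
    if method == "kmeans":
        return discretize_kmeans(y, n_bins, seed=seed)
    raise ParameterError(f"unknown discretization method {method!r}")


def _as_codes(x: np.ndarray) -> np.ndarray:
    _, codes = np.unique(np.asarray(x), return_inverse=True)
    return codes


def _joint_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ca, cb = _as_codes(a), _as_codes(b)
    return ca * (cb.max() + 1) + cb


def entropy(labels: np.ndarray, base: float = 2.0) -> float:
    """Plug-in entropy H = sum_c p(c) log(1/p(c)) of a discrete vector."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ParameterError("entropy of an empty vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    # sorted counts -> summation order independent of label coding, so
    # e.g. Syn(A;B;C) == Syn(B;A;C) holds bit-exactly
    p = np.sort(counts) / labels.size
    return float(-(p * (np.log(p) / np.log(base))).sum())


def conditional_entropy(labels: np.ndarray, given: np.ndarray, base: float = 2.0) -> float:
    """Plug-in conditional entropy H(C|A) = sum_{a,c} p(a,c) log(1/p(c|a))."""
    labels, given = np.asarray(labels), np.asarray(given)
    if labels.size != given.size:
        raise ParameterError("length mismatch between labels and conditioning vector")
    # H(C|A) = H(A,C) - H(A); empty cells contribute 0 in both terms
    return entropy(_joint_codes(given, labels), base) - entropy(given, base)


def information_gain(x, c: np.ndarray, base: float = 2.0) -> float:
    """Mutual information I(X;C) = H(C) - H(C|X).

    ``x`` may be a single discrete vector or a pair ``(a, b)`` of vectors, in
    which case the joint variable is their Cartesian product (up to 9 levels
    for two SNPs).
    """
    if isinstance(x, (tuple, list)) and len(x) == 2 and np.ndim(x[0]) == 1:
        x = _joint_codes(np.asarray(x[0]), np.asarray(x[1]))
    x = np.asarray(x)
    c = np.asarray(c)
    if x.size != c.size:
        raise ParameterError("length mismatch between predictor and phenotype")
    return entropy(c, base) - conditional_entropy(c, x, base)


def synergy(a: np.ndarray, b: np.ndarray, c: np.ndarray, base: float = 2.0) -> float:
    """Bivariate synergy Syn(A;B;C) = I(A,B;C) - I(A;C) - I(B;C)."""
    return (
        information_gain((a, b), c, base)
        - information_gain(a, c, base)
        - information_gain(b, c, base)
    )


def synergy_matrix(
    block: GeneBlock, c: DiscretePhenotype, base: float = 2.0
) -> SynergyMatrix:
    """All pairwise synergies within a gene block (symmetric, zero diagonal)."""
    if block.sample_ids != c.sample_ids:
        raise ParameterError("gene block and phenotype are not aligned on samples")
    m = block.n_snps
    labels = c.labels
    # precompute per-SNP codes and single-SNP information gains
    cols = [block.values[:, j] for j in range(m)]
    gains = np.array([information_gain(col, labels, base) for col in cols])
    w = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            joint = information_gain((cols[i], cols[j]), labels, base)
            w[i, j] = w[j, i] = joint - gains[i] - gains[j]
    return SynergyMatrix(gene_id=block.gene_id, snp_ids=list(block.snp_ids), values=w)
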