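"""Diffusion kernels on synergy graphs and kernel-PCA gene summaries.

For a gene with m SNPs and synergy matrix W, the graph Laplacian is

    L_ij = W_ij (i != j),   L_ii = -sum_{l != i} W_il

and the diffusion kernel is the matrix exponential K_L = exp(beta * L),
averaged over a grid of diffusion strengths beta (default 0, 0.1, ..., 10;
101 values). The n x n between-individual "sandwich" kernel K = G K_L G^T
combines raw genotypes G with the within-gene synergy structure; after
double centering, its leading eigenpair gives one score per individual — the
gene summary. With beta = 0, K_L is the identity and the summary reduces to
the classical first principal component of the gene's genotype block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import eigsh

from .containers import GeneBlock, GeneSummary, SynergyMatrix
from .errors import DegenerateKernelError, ParameterError

__all__ = [
    "DEFAULT_BETA_GRID",
    "LaplacianMatrix",
    "DiffusionKernel",
    "SampleKernel",
    "graph_laplacian",
    "diffusion_kernel",
    "averaged_kernel",
    "sandwich_kernel",
    "center_kernel",
    "first_kpc",
    "gene_summary",
]

#: beta = 0, 0.1, ..., 10.0 — the 101-point diffusion-strength grid.
DEFAULT_BETA_GRID: np.ndarray = np.round(np.arange(0, 101) * 0.1, 10)


@dataclass
class LaplacianMatrix:
    """Synergy-graph Laplacian (off-diagonal = synergies, rows sum to 0)."""

    gene_id: str
    snp_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.allclose(self.values, self.values.T, atol=1e-10, rtol=0):
            raise ValueError("Laplacian must be symmetric")
        rs = np.abs(self.values.sum(axis=1)).max(initial=0.0)
        if rs > 1e-8:
            raise ValueError(f"Laplacian rows must sum to 0 (max |sum| = {rs:g})")


@dataclass
class DiffusionKernel:
    """SNP x SNP diffusion kernel (grid-averaged matrix exponential)."""

    gene_id: str
    snp_ids: list[str]
    values: np.ndarray
    beta_grid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.allclose(self.values, self.values.T, atol=1e-10, rtol=0):
            raise ValueError("diffusion kernel must be symmetric")


@dataclass
class SampleKernel:
    """n x n between-individual kernel for one gene."""

    gene_id: str
    sample_ids: list[str]
    values: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("sample kernel shape mismatch")


def graph_laplacian(s: SynergyMatrix) -> LaplacianMatrix:
    """Laplacian with synergies off-diagonal and negative row sums on it."""
    w = s.values
    lap = w.copy()
    np.fill_diagonal(lap, 0.0)
    lap[np.diag_indices_from(lap)] = -lap.sum(axis=1)
    return LaplacianMatrix(gene_id=s.gene_id, snp_ids=list(s.snp_ids), values=lap)


def _spectral_exp(lap: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """Mean of exp(beta * L) over betas via one symmetric eigendecomposition."""
    eigval, eigvec = np.linalg.eigh(lap)
    mean_spectrum = np.exp(np.outer(betas, eigval)).mean(axis=0)
    k = (eigvec * mean_spectrum) @ eigvec.T
    return (k + k.T) / 2.0


def diffusion_kernel(L: LaplacianMatrix, beta: float) -> DiffusionKernel:
    """K_L = exp(beta * L); symmetric positive definite for any real beta."""
    if beta < 0:
        raise ParameterError("beta must be >= 0")
    if beta == 0:  # exp(0) is the identity, exactly
        return DiffusionKernel(
            L.gene_id, list(L.snp_ids), np.eye(len(L.snp_ids)), np.array([0.0])
        )
    k = _spectral_exp(L.values, np.array([float(beta)]))
    if not np.isfinite(k).all():
        raise ParameterError("non-finite entries in diffusion kernel")
    return DiffusionKernel(L.gene_id, list(L.snp_ids), k, np.array([float(beta)]))


def averaged_kernel(
    L: LaplacianMatrix, grid: np.ndarray = DEFAULT_BETA_GRID
) -> DiffusionKernel:
    """Elementwise mean of exp(beta * L) over the beta grid.

    A single eigendecomposition of L is reused across the grid (all the
    exponentials share eigenvectors), so the cost is O(m^3 + |grid| m).
    """
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ParameterError("beta grid is empty")
    if (grid < 0).any():
        raise ParameterError("beta values must be >= 0")
    if np.unique(grid).size == 1:  # degenerate grid: identical to a single kernel
        single = diffusion_kernel(L, float(grid[0]))
        return DiffusionKernel(L.gene_id, list(L.snp_ids), single.values, grid)
    k = _spectral_exp(L.values, grid)
    if not np.isfinite(k).all():
        raise ParameterError("non-finite entries in averaged diffusion kernel")
    return DiffusionKernel(L.gene_id, list(L.snp_ids), k, grid)


def sandwich_kernel(
    block: GeneBlock, kl: DiffusionKernel, standardize: bool = False
) -> SampleKernel:
    """K = G K_L G^T: gene-level similarity between individuals.

    ``standardize`` centers and unit-scales each genotype column first
    (constant columns are left centered only); by default G enters raw —
    the downstream kernel centering removes sample-mean effects either way.
    """
    if block.snp_ids != kl.snp_ids:
        raise ParameterError(
            f"SNP order of gene block and kernel differ for {block.gene_id}"
        )
    g = block.values.astype(float)
    if standardize:
        g -= g.mean(axis=0)
        sd = g.std(axis=0)
        sd[sd == 0] = 1.0
        g /= sd
    k = g @ kl.values @ g.T
    return SampleKernel(block.gene_id, list(block.sample_ids), (k + k.T) / 2.0)


def center_kernel(k: SampleKernel, tol: float = 1e-8) -> SampleKernel:
    """Double centering K' = H K H with H = I - (1/n) 11^T."""
    v = k.values
    if k.centered or (
        np.abs(v.sum(axis=0)).max() < tol and np.abs(v.sum(axis=1)).max() < tol
    ):
        warnings.warn(f"kernel for {k.gene_id} is already centered; no-op")
        return SampleKernel(k.gene_id, list(k.sample_ids), v.copy(), centered=True)
    row = v.mean(axis=1, keepdims=True)
    col = v.mean(axis=0, keepdims=True)
    centered = v - row - col + v.mean()
    centered = (centered + centered.T) / 2.0
    return SampleKernel(k.gene_id, list(k.sample_ids), centered, centered=True)


def first_kpc(k: SampleKernel, dense_threshold: int = 512) -> GeneSummary:
    """Leading eigenpair of the centered kernel as the gene summary.

    Scores are ``sqrt(lambda_1) * v_1`` (kernel-PCA projection convention:
    the score vector's norm equals the root eigenvalue). The sign is fixed so
    that the largest-magnitude score is positive. Small kernels use a dense
    symmetric eigensolver; larger ones a truncated Lanczos solver asking only
    for the top eigenpair.
    """
    if not k.centered:
        raise ParameterError(f"kernel for {k.gene_id} must be centered first")
    n = len(k.sample_ids)
    if n <= dense_threshold:
        eigval, eigvec = np.linalg.eigh(k.values)
        lam, vec = float(eigval[-1]), eigvec[:, -1]
    else:
        eigval, eigvec = eigsh(k.values, k=1, which="LA")
        lam, vec = float(eigval[0]), eigvec[:, 0]
    if lam <= 0:
        raise DegenerateKernelError(
            f"gene {k.gene_id}: centered kernel has no positive eigenvalue"
        )
    scores = np.sqrt(lam) * vec
    if scores[np.argmax(np.abs(scores))] < 0:
        scores = -scores
    return GeneSummary(k.gene_id, list(k.sample_ids), scores, lam)


def gene_summary(
    block: GeneBlock,
    s: SynergyMatrix,
    beta_grid: np.ndarray = DEFAULT_BETA_GRID,
    standardize: bool = False,
) -> GeneSummary:
    """Full per-gene chain: Laplacian -> averaged kernel -> sandwich ->
    centering -> first kernel principal component."""
    lap = graph_laplacian(s)
    kl = averaged_kernel(lap, beta_grid)
    kern = sandwich_kernel(block, kl, standardize=standardize)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero synergy genes pre-center cleanly
        kern = center_kernel(kern)
    return first_kpc(kern)
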