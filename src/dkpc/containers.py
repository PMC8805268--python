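"""Core data containers shared across the pipeline stages.

Conventions used throughout:

* genotypes are additively coded (0/1/2 copies of the minor allele) and held
  as ``int8`` with :data:`MISSING` (``-1``) as the internal missing sentinel;
* samples are rows, SNPs are columns, and identifier lists are kept in the
  same order as the array axes they describe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Internal sentinel for a missing genotype call.
MISSING: int = -1


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} are not unique")
    return ids


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive genotype matrix.

    ``values[i, j]`` is the 0/1/2 minor-allele dosage of sample
    ``sample_ids[i]`` at SNP ``snp_ids[j]``, or :data:`MISSING`.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        self.snp_ids = _check_unique(self.snp_ids, "snp_ids")
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"genotype array shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype {self.values[i, j]} for sample "
                f"{self.sample_ids[i]!r} at SNP {self.snp_ids[j]!r}; "
                "expected 0, 1, 2 or missing"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def has_missing(self) -> bool:
        return bool((self.values == MISSING).any())

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING


@dataclass
class SnpGeneMap:
    """SNP-to-gene assignment table (many-to-many).

    Wraps a DataFrame with columns ``snp`` and ``gene`` and optional
    ``chrom``/``pos`` (1-based) columns, e.g. an eQTL mapping exported from
    an annotation tool.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table)
        if not {"snp", "gene"}.issubset(t.columns):
            raise ValueError("SNP-gene map requires 'snp' and 'gene' columns")
        t = t.drop_duplicates(subset=["snp", "gene"]).reset_index(drop=True)
        if (t["gene"].astype(str).str.len() == 0).any():
            raise ValueError("empty gene_id in SNP-gene map")
        self.table = t

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].astype(str).unique())

    def snps_for_gene(self, gene_id: str) -> list[str]:
        sel = self.table.loc[self.table["gene"] == gene_id, "snp"]
        return [str(s) for s in sel]


@dataclass
class PhenotypeVector:
    """Phenotype values aligned with a sample-id list.

    ``kind`` is ``"raw"`` (as collected: case/control 0/1 or quantitative)
    or ``"corrected"`` (residual after population-structure correction).
    """

    sample_ids: list[str]
    values: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.sample_ids):
            raise ValueError("phenotype length does not match sample_ids")
        if self.kind not in ("raw", "corrected"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "corrected" and not np.isfinite(self.values).all():
            raise ValueError("corrected phenotype contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def is_binary(self) -> bool:
        vals = np.unique(self.values[np.isfinite(self.values)])
        return vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()


@dataclass
class GeneBlock:
    """Complete genotype submatrix for the SNPs mapped to one gene."""

    gene_id: str
    snp_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = _check_unique(self.snp_ids, f"SNPs of {self.gene_id}")
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("gene block shape mismatch")
        if (self.values == MISSING).any():
            raise ValueError(f"gene block {self.gene_id} contains missing genotypes")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class DiscretePhenotype:
    """Binned phenotype: integer labels 1..n_bins plus the bin edges."""

    sample_ids: list[str]
    labels: np.ndarray
    n_bins: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.labels.size != len(self.sample_ids):
            raise ValueError("label length does not match sample_ids")
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.n_bins:
            raise ValueError("labels outside 1..n_bins")
        if self.bin_edges.size and np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")


@dataclass
class SynergyMatrix:
    """Symmetric SNP x SNP bivariate-synergy matrix for one gene (bits)."""

    gene_id: str
    snp_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.snp_ids)
        if self.values.shape != (m, m):
            raise ValueError("synergy matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("synergy matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("synergy matrix diagonal must be zero")
        if not np.isfinite(self.values).all():
            raise ValueError("synergy matrix contains non-finite entries")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class GeneSummary:
    """First kernel principal component of a gene: one score per sample."""

    gene_id: str
    sample_ids: list[str]
    scores: np.ndarray
    eigenvalue: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size != len(self.sample_ids):
            raise ValueError("score length does not match sample_ids")
        if self.eigenvalue < 0:
            raise ValueError("leading eigenvalue must be non-negative")


def summaries_to_frame(summaries: Sequence[GeneSummary]) -> pd.DataFrame:
    """Stack gene summaries into a samples x genes score matrix."""
    if not summaries:
        raise ValueError("no gene summaries given")
    ref = summaries[0].sample_ids
    for s in summaries:
        if s.sample_ids != ref:
            raise ValueError("gene summaries are not aligned on samples")
    return pd.DataFrame(
        {s.gene_id: s.scores for s in summaries}, index=pd.Index(ref, name="sample")
    )


__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SnpGeneMap",
    "PhenotypeVector",
    "GeneBlock",
    "DiscretePhenotype",
    "SynergyMatrix",
    "GeneSummary",
    "summaries_to_frame",
]
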