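"""Genotype/phenotype input-output, kNN imputation, population-structure
correction and per-gene partitioning.

Supported genotype formats are PLINK ``--recode A`` RAW (whitespace
delimited, additive coding, six leading pedigree columns) and a plain TSV
with a header row of SNP ids and the sample id in the first column. Missing
calls are ``NA`` (or ``-9``) on disk and :data:`~dkpc.containers.MISSING`
internally.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GeneBlock, GenotypeMatrix, PhenotypeVector, SnpGeneMap
from .errors import FormatError, ImputationError, ParameterError

logger = logging.getLogger(__name__)

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
_NA_STRINGS = {"NA", "-9", "nan", ""}


def _parse_cell(cell: str, row: str, col: str) -> int:
    if cell in _NA_STRINGS:
        return MISSING
    if cell in ("0", "1", "2"):
        return int(cell)
    raise FormatError(
        f"invalid genotype {cell!r} for sample {row!r} at SNP {col!r}; "
        "expected 0, 1, 2 or NA"
    )


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read an additive-coded genotype matrix.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"plink_raw"`` for PLINK ``--recode A`` output or ``"tsv"`` for a
        tab-separated samples x SNPs table (first column = sample id).
    """
    path = Path(path)
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        if list(df.columns[:6]) != _RAW_META:
            raise FormatError(
                f"{path} is not PLINK RAW: header must start with "
                + " ".join(_RAW_META)
            )
        sample_ids = df["IID"].tolist()
        snp_cols = list(df.columns[6:])
        # "<snpid>_<counted allele>" -> "<snpid>"
        snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
        body = df[snp_cols]
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise FormatError(f"{path}: TSV needs a sample column and >=1 SNP column")
        sample_ids = df.iloc[:, 0].tolist()
        snp_ids = list(df.columns[1:])
        body = df.iloc[:, 1:]
    else:
        raise ParameterError(f"unknown genotype format {format!r}")

    values = np.empty(body.shape, dtype=np.int8)
    arr = body.to_numpy(dtype=str)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            values[i, j] = _parse_cell(arr[i, j].strip(), sample_ids[i], snp_ids[j])
    return GenotypeMatrix(sample_ids=sample_ids, snp_ids=snp_ids, values=values)


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect read back by :func:`read_genotypes`."""
    df = pd.DataFrame(g.values.astype(object), columns=g.snp_ids)
    df = df.mask(df == MISSING, "NA")
    df.insert(0, "sample", g.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def write_genotypes_plink_raw(g: GenotypeMatrix, path: str | Path, allele: str = "A") -> None:
    """Write the PLINK RAW dialect (pedigree columns filled with placeholders)."""
    with open(path, "w") as fh:
        header = _RAW_META + [f"{s}_{allele}" for s in g.snp_ids]
        fh.write(" ".join(header) + "\n")
        for i, sid in enumerate(g.sample_ids):
            row = [sid, sid, "0", "0", "0", "-9"]
            row += ["NA" if v == MISSING else str(int(v)) for v in g.values[i]]
            fh.write(" ".join(row) + "\n")


def read_snp_gene_map(path: str | Path) -> SnpGeneMap:
    """Read a SNP-to-gene map TSV with columns ``snp``, ``gene``[, chrom, pos]."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "gene": str})
    return SnpGeneMap(df)


def write_snp_gene_map(m: SnpGeneMap, path: str | Path) -> None:
    m.table.to_csv(path, sep="\t", index=False)


def read_phenotype(path: str | Path, kind: str = "raw") -> PhenotypeVector:
    """Read a phenotype TSV with columns ``sample`` and ``value``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if not {"sample", "value"}.issubset(df.columns):
        raise FormatError(f"{path}: phenotype TSV needs 'sample' and 'value' columns")
    return PhenotypeVector(df["sample"].tolist(), df["value"].to_numpy(float), kind=kind)


def write_phenotype(y: PhenotypeVector, path: str | Path) -> None:
    pd.DataFrame({"sample": y.sample_ids, "value": y.values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# kNN imputation


def _masked_distances(values: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances over mutually observed SNPs.

    Squared distance is averaged over the shared (both-observed) SNP count so
    samples with different missingness patterns are comparable. Pairs with no
    shared SNP get distance +inf.
    """
    obs = (values != MISSING).astype(float)
    x = np.where(values == MISSING, 0, values).astype(float)
    x2 = x * x
    shared = obs @ obs.T
    d2 = x2 @ obs.T + obs @ x2.T - 2.0 * (x @ x.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(shared > 0, d2 / shared, np.inf)
    np.clip(d2, 0.0, None, out=d2)  # guard tiny negatives from cancellation
    return np.sqrt(d2)


def knn_impute(g: GenotypeMatrix, k: int = 10) -> GenotypeMatrix:
    """Fill missing genotypes with the k-nearest-neighbour mode.

    The value imputed for sample *i* at SNP *j* is the most frequent genotype
    of SNP *j* among the ``k`` samples closest to *i* (Euclidean distance over
    SNPs observed in both samples, normalised by the shared-SNP count;
    neighbours must themselves be observed at SNP *j*). Ties in the mode are
    broken toward the smaller genotype; ties in distance by sample order.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    n = g.n_samples
    if k > n - 1:
        raise ParameterError(f"k={k} exceeds n-1={n - 1} candidate neighbours")
    if not g.has_missing:
        return GenotypeMatrix(list(g.sample_ids), list(g.snp_ids), g.values.copy())
    mask = g.missing_mask()
    if mask.all(axis=1).any():
        i = int(np.flatnonzero(mask.all(axis=1))[0])
        raise ImputationError(f"sample {g.sample_ids[i]!r} has no observed genotype")
    if mask.all(axis=0).any():
        j = int(np.flatnonzero(mask.all(axis=0))[0])
        raise ImputationError(f"SNP {g.snp_ids[j]!r} is missing in every sample")

    dist = _masked_distances(g.values)
    out = g.values.copy()
    for j in np.flatnonzero(mask.any(axis=0)):
        observed = np.flatnonzero(~mask[:, j])
        for i in np.flatnonzero(mask[:, j]):
            cand = observed[observed != i]
            # stable sort on distance keeps sample order on ties
            order = cand[np.argsort(dist[i, cand], kind="stable")]
            nearest = order[:k]
            counts = np.bincount(out[nearest, j], minlength=3)
            out[i, j] = int(np.argmax(counts))  # argmax -> smaller value on ties
    return GenotypeMatrix(list(g.sample_ids), list(g.snp_ids), out)


def knn_impute_by_gene(
    g: GenotypeMatrix, m: SnpGeneMap, k: int = 10
) -> GenotypeMatrix:
    """kNN imputation with neighbour distances restricted to within-gene SNPs.

    Each gene's SNP columns are imputed as an independent submatrix, so a
    sample's neighbours are determined only by the SNPs of that gene.
    SNPs not present in the map fall back to all-SNP distances. For a SNP
    mapped to several genes the first gene (alphabetically) is used.
    """
    out = g.values.copy()
    seen: set[str] = set()
    for gene in m.genes:
        cols = [j for j, s in enumerate(g.snp_ids)
                if s in set(m.snps_for_gene(gene)) and s not in seen]
        if not cols:
            continue
        seen.update(g.snp_ids[j] for j in cols)
        sub = GenotypeMatrix(
            list(g.sample_ids), [g.snp_ids[j] for j in cols], g.values[:, cols]
        )
        if sub.has_missing:
            out[:, cols] = knn_impute(sub, k=k).values
    rest = [j for j, s in enumerate(g.snp_ids) if s not in seen]
    if rest and (g.values[:, rest] == MISSING).any():
        full = knn_impute(g, k=k)
        out[:, rest] = full.values[:, rest]
    return GenotypeMatrix(list(g.sample_ids), list(g.snp_ids), out)


# ---------------------------------------------------------------------------
# population-structure correction


def genotype_pcs(g: GenotypeMatrix, n_pcs: int) -> np.ndarray:
    """Principal-component scores (n x n_pcs) of the column-centered genotypes."""
    if g.has_missing:
        raise ParameterError("genotype matrix must be complete (impute first)")
    if not 0 <= n_pcs < min(g.n_samples, g.n_snps):
        raise ParameterError(
            f"n_pcs={n_pcs} must satisfy 0 <= n_pcs < min(n, p)="
            f"{min(g.n_samples, g.n_snps)}"
        )
    if n_pcs == 0:
        return np.empty((g.n_samples, 0))
    x = g.values.astype(float)
    x -= x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def correct_phenotype(
    y: PhenotypeVector,
    g: GenotypeMatrix,
    n_pcs: int = 7,
    covariates: np.ndarray | None = None,
) -> PhenotypeVector:
    """Residualise the phenotype on top genotype principal components.

    Regresses ``y`` on an intercept plus the top ``n_pcs`` PCs of the
    column-centered genotype matrix (or on user-supplied ``covariates``
    instead) and returns the residuals as a ``corrected`` phenotype.
    """
    if y.kind != "raw":
        raise ParameterError("phenotype is already corrected")
    if y.sample_ids != g.sample_ids:
        raise ParameterError("phenotype and genotypes are not aligned on samples")
    pcs = genotype_pcs(g, n_pcs) if covariates is None else np.asarray(covariates, float)
    design = np.column_stack([np.ones(y.n_samples), pcs])
    coef, _, rank, _ = np.linalg.lstsq(design, y.values, rcond=None)
    if rank < design.shape[1]:
        raise ParameterError(
            f"design with {design.shape[1] - 1} PCs is rank deficient; "
            "use fewer principal components"
        )
    resid = y.values - design @ coef
    return PhenotypeVector(list(y.sample_ids), resid, kind="corrected")


# ---------------------------------------------------------------------------
# per-gene partitioning


def partition_by_gene(
    g: GenotypeMatrix, m: SnpGeneMap, min_snps: int = 3
) -> list[GeneBlock]:
    """Split the genotype matrix into per-gene blocks.

    Genes with fewer than ``min_snps`` mapped SNPs present in ``g`` are
    logged and dropped; SNPs mapped to several genes appear in each of their
    genes' blocks. SNP order within a block follows the matrix column order.
    """
    if g.has_missing:
        raise ParameterError("genotype matrix must be complete (impute first)")
    col = {s: j for j, s in enumerate(g.snp_ids)}
    blocks: list[GeneBlock] = []
    any_overlap = False
    for gene in m.genes:
        idx = sorted(col[s] for s in set(m.snps_for_gene(gene)) if s in col)
        if idx:
            any_overlap = True
        if len(idx) < min_snps:
            logger.info(
                "dropping gene %s: %d mapped SNP(s) present, need >= %d",
                gene, len(idx), min_snps,
            )
            continue
        blocks.append(
            GeneBlock(
                gene_id=gene,
                snp_ids=[g.snp_ids[j] for j in idx],
                sample_ids=list(g.sample_ids),
                values=g.values[:, idx],
            )
        )
    if not any_overlap:
        raise ParameterError("no SNP in the map is present in the genotype matrix")
    return blocks


__all__ = [
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_plink_raw",
    "read_snp_gene_map",
    "write_snp_gene_map",
    "read_phenotype",
    "write_phenotype",
    "knn_impute",
    "knn_impute_by_gene",
    "genotype_pcs",
    "correct_phenotype",
    "partition_by_gene",
]
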