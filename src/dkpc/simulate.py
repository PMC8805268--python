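"""Synthetic GWAS studies with known ground truth.

Genotypes come from a latent-Gaussian haplotype model: within each gene, two
haplotypes per sample are drawn from an AR(rho) correlated Gaussian and
thresholded at each SNP's minor-allele-frequency quantile, so one knob
(``ld_rho``) controls within-gene linkage disequilibrium and the additive
genotype is the haplotype sum in {0, 1, 2}. The phenotype is a linear
combination of unit-variance causal terms — centered main-effect genotypes,
centered genotype products (product epistasis), or a centered
exactly-one-carrier indicator (XOR-like penetrance, which produces pairwise
synergy with almost no marginal signal) — plus a population-structure
confounder proportional to the first genotype PC and Gaussian noise.
Missing calls are masked completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .containers import MISSING, GenotypeMatrix, PhenotypeVector, SnpGeneMap
from .errors import ParameterError
from . import io as _io

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_phenotype",
    "inject_missingness",
    "simulate_study",
    "write_study",
]


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults describe the desk-scale testbed used throughout: 500 samples,
    20 genes of 8 SNPs, moderate within-gene LD (AR rho = 0.5), common
    variants (MAF 0.1-0.4), unit noise, and the low completely-at-random
    missingness typical of post-QC GWAS calls (0.062%).
    """

    n: int = 500
    n_genes: int = 20
    snps_per_gene: int | tuple[int, int] = 8
    maf_range: tuple[float, float] = (0.1, 0.4)
    ld_rho: float = 0.5
    main_effects: list[tuple[str, float]] = field(default_factory=list)
    epistasis_pairs: list[tuple[str, str, str, float]] = field(default_factory=list)
    confounder_sd: float = 0.0
    noise_sd: float = 1.0
    missing_rate: float = 0.00062
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.05 < lo <= hi < 0.5):
            raise ParameterError("maf_range must lie inside (0.05, 0.5)")
        if not 0 <= self.ld_rho < 1:
            raise ParameterError("ld_rho must be in [0, 1)")
        if not 0 <= self.missing_rate <= 0.5:
            raise ParameterError("missing_rate must be in [0, 0.5]")
        for _, _, model, _ in self.epistasis_pairs:
            if model not in ("product", "xor_penetrance"):
                raise ParameterError(f"unknown epistasis model {model!r}")

    def gene_ids(self) -> list[str]:
        return [f"gene{i:03d}" for i in range(self.n_genes)]


@dataclass
class SimulatedStudy:
    """Generated study plus its ground-truth effect registry."""

    genotypes: GenotypeMatrix
    map: SnpGeneMap
    phenotype: PhenotypeVector
    truth: dict


def _gene_sizes(cfg: SimulationConfig, rng: np.random.Generator) -> list[int]:
    if isinstance(cfg.snps_per_gene, int):
        return [cfg.snps_per_gene] * cfg.n_genes
    lo, hi = cfg.snps_per_gene
    return [int(v) for v in rng.integers(lo, hi + 1, size=cfg.n_genes)]


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SnpGeneMap]:
    """Draw LD-correlated genotypes grouped into genes, plus the gene map."""
    rng = np.random.default_rng(cfg.seed)
    sizes = _gene_sizes(cfg, rng)
    sample_ids = [f"s{i:05d}" for i in range(cfg.n)]
    cols, snp_ids, rows = [], [], []
    for gene, m in zip(cfg.gene_ids(), sizes):
        mafs = rng.uniform(*cfg.maf_range, size=m)
        if cfg.ld_rho > 0:
            cov = cfg.ld_rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
            chol = np.linalg.cholesky(cov)
        else:
            chol = np.eye(m)
        thresh = norm.ppf(mafs)
        geno = np.zeros((cfg.n, m), dtype=np.int8)
        for _hap in range(2):
            z = rng.standard_normal((cfg.n, m)) @ chol.T
            geno += (z < thresh).astype(np.int8)
        cols.append(geno)
        for i in range(m):
            sid = f"{gene}_snp{i:02d}"
            snp_ids.append(sid)
            rows.append({"snp": sid, "gene": gene})
    g = GenotypeMatrix(sample_ids, snp_ids, np.hstack(cols))
    return g, SnpGeneMap(pd.DataFrame(rows))


def _standardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    sd = v.std()
    if sd == 0:
        raise ParameterError("causal term is constant; pick another SNP or MAF range")
    return v / sd


def simulate_phenotype(
    g: GenotypeMatrix, snp_map: SnpGeneMap, cfg: SimulationConfig
) -> tuple[PhenotypeVector, dict]:
    """Build the quantitative trait from planted effects; returns truth too.

    Each causal term is standardized to unit variance, so an effect size e
    contributes e^2 to the trait variance and the marginal R^2 of a term is
    e^2 / var(y).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    col = {s: j for j, s in enumerate(g.snp_ids)}
    values = g.values.astype(float)

    def draw_causal(gene: str) -> str:
        snps = [s for s in snp_map.snps_for_gene(gene) if s in col]
        if not snps:
            raise ParameterError(f"gene {gene!r} absent from genotype matrix")
        return snps[int(rng.integers(len(snps)))]

    y = np.zeros(g.n_samples)
    truth: dict = {"main_effects": [], "epistasis_pairs": []}
    for gene, eff in cfg.main_effects:
        snp = draw_causal(gene)
        y += eff * _standardize(values[:, col[snp]])
        truth["main_effects"].append({"gene": gene, "snp": snp, "effect": float(eff)})
    for g1, g2, model, eff in cfg.epistasis_pairs:
        s1, s2 = draw_causal(g1), draw_causal(g2)
        a, b = values[:, col[s1]], values[:, col[s2]]
        if model == "product":
            term = a * b
        else:  # xor_penetrance: exactly one of the two loci carries a variant
            term = ((a > 0) ^ (b > 0)).astype(float)
        y += eff * _standardize(term)
        truth["epistasis_pairs"].append(
            {"gene1": g1, "gene2": g2, "snp1": s1, "snp2": s2,
             "model": model, "effect": float(eff)}
        )
    if cfg.confounder_sd > 0:
        pc1 = _io.genotype_pcs(g, 1)[:, 0]
        y += cfg.confounder_sd * _standardize(pc1)
    y += cfg.noise_sd * rng.standard_normal(g.n_samples)
    return PhenotypeVector(list(g.sample_ids), y, kind="raw"), truth


def inject_missingness(g: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Mask each genotype call independently with probability ``rate``."""
    if not 0 <= rate <= 0.5:
        raise ParameterError("rate must be in [0, 0.5]")
    if rate == 0:
        return GenotypeMatrix(list(g.sample_ids), list(g.snp_ids), g.values.copy())
    rng = np.random.default_rng(seed)
    mask = rng.random(g.values.shape) < rate
    vals = g.values.copy()
    vals[mask] = MISSING
    return GenotypeMatrix(list(g.sample_ids), list(g.snp_ids), vals)


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Genotypes + phenotype + missingness + truth registry in one call."""
    g, snp_map = simulate_genotypes(cfg)
    y, truth = simulate_phenotype(g, snp_map, cfg)
    g = inject_missingness(g, cfg.missing_rate, cfg.seed + 2)
    truth["config"] = {
        "n": cfg.n, "n_genes": cfg.n_genes, "ld_rho": cfg.ld_rho,
        "noise_sd": cfg.noise_sd, "confounder_sd": cfg.confounder_sd,
        "missing_rate": cfg.missing_rate, "seed": cfg.seed,
    }
    return SimulatedStudy(genotypes=g, map=snp_map, phenotype=y, truth=truth)


def write_study(study: SimulatedStudy, out_dir: str | Path, plink: bool = False) -> None:
    """Write genotypes (TSV and optionally PLINK RAW), map, phenotype, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_genotypes_tsv(study.genotypes, out / "genotypes.tsv")
    if plink:
        _io.write_genotypes_plink_raw(study.genotypes, out / "genotypes.raw")
    _io.write_snp_gene_map(study.map, out / "snp_gene_map.tsv")
    _io.write_phenotype(study.phenotype, out / "phenotype.tsv")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(study.truth, fh, sort_keys=False)
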