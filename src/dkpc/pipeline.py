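"""End-to-end orchestration: genotypes + map + phenotype -> posterior.

The stages mirror the analysis workflow: impute missing genotypes (kNN,
k = 10), residualise the trait on the top genotype principal components
(7 by default), partition SNPs into gene blocks (>= 3 SNPs), bin the
corrected trait (equal width, cube-root rule), compute per-gene synergy
matrices, build grid-averaged diffusion kernels and kernel-PCA gene
summaries, and fit the spike-and-slab interaction model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io, kernels, model, network, synergy
from .containers import (
    GeneSummary,
    GenotypeMatrix,
    PhenotypeVector,
    SnpGeneMap,
    summaries_to_frame,
)
from .model import ModelConfig, PosteriorSummary
from .network import GeneGraph, NetworkProperties

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "compute_gene_summaries", "run_pipeline"]


@dataclass
class PipelineConfig:
    knn_k: int = 10
    n_pcs: int = 7
    min_snps: int = 3
    n_bins: int | str = "auto"
    binning: str = "equal_width"
    beta_grid: np.ndarray = field(
        default_factory=lambda: kernels.DEFAULT_BETA_GRID.copy()
    )
    use_mrnet_nodes: bool = False
    standardize_genotypes: bool = False
    model: ModelConfig = field(default_factory=ModelConfig)


@dataclass
class PipelineResult:
    summaries: list[GeneSummary]
    summary_frame: pd.DataFrame
    synergy_matrices: dict
    graphs: dict[str, GeneGraph]
    properties: dict[str, NetworkProperties]
    posterior: PosteriorSummary
    corrected: PhenotypeVector


def compute_gene_summaries(
    g: GenotypeMatrix,
    snp_map: SnpGeneMap,
    y: PhenotypeVector,
    cfg: PipelineConfig | None = None,
) -> tuple[list[GeneSummary], dict, PhenotypeVector]:
    """Run the pipeline up to the gene summaries.

    Returns (summaries, synergy matrices by gene, corrected phenotype).
    """
    cfg = cfg or PipelineConfig()
    if g.has_missing:
        g = io.knn_impute(g, k=cfg.knn_k)
    y_corr = io.correct_phenotype(y, g, n_pcs=cfg.n_pcs) if y.kind == "raw" else y
    blocks = io.partition_by_gene(g, snp_map, min_snps=cfg.min_snps)
    disc = synergy.discretize(y_corr, n_bins=cfg.n_bins, method=cfg.binning)
    summaries, syn_mats = [], {}
    for block in blocks:
        s = synergy.synergy_matrix(block, disc)
        syn_mats[block.gene_id] = s
        if cfg.use_mrnet_nodes:
            graph = network.infer_network(s)
            keep = sorted({i for e in graph.edges for i in e[:2]})
            if len(keep) >= 2:
                sub_ids = [block.snp_ids[i] for i in keep]
                block = type(block)(
                    gene_id=block.gene_id,
                    snp_ids=sub_ids,
                    sample_ids=block.sample_ids,
                    values=block.values[:, keep],
                )
                s = type(s)(s.gene_id, sub_ids, s.values[np.ix_(keep, keep)])
        summaries.append(
            kernels.gene_summary(
                block, s, beta_grid=cfg.beta_grid,
                standardize=cfg.standardize_genotypes,
            )
        )
    logger.info("computed %d gene summaries", len(summaries))
    return summaries, syn_mats, y_corr


def run_pipeline(
    g: GenotypeMatrix,
    snp_map: SnpGeneMap,
    y: PhenotypeVector,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Full chain through the interaction model and network statistics."""
    cfg = cfg or PipelineConfig()
    summaries, syn_mats, y_corr = compute_gene_summaries(g, snp_map, y, cfg)
    graphs = {gid: network.infer_network(s) for gid, s in syn_mats.items()}
    props = {gid: network.network_properties(gr) for gid, gr in graphs.items()}
    posterior = model.fit(summaries, y_corr, cfg.model)
    return PipelineResult(
        summaries=summaries,
        summary_frame=summaries_to_frame(summaries),
        synergy_matrices=syn_mats,
        graphs=graphs,
        properties=props,
        posterior=posterior,
        corrected=y_corr,
    )
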