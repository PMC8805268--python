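"""Within-gene SNP network inference from synergy matrices.

Each SNP is used in turn as a target; the remaining SNPs are ranked by a
greedy maximum-relevance-minimum-redundancy (MRMR) score

    s_j = u_j - r_j,   u_j = W[j, target],   r_j = mean_{k in S} W[j, k]

where S is the set already selected. The MRNET rule symmetrizes the two
directional scores of an edge by taking their maximum and keeps edges with a
strictly positive score. Density, mean shortest-path distance and global
transitivity summarise each inferred network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .containers import SynergyMatrix
from .errors import ParameterError

__all__ = [
    "GeneGraph",
    "NetworkProperties",
    "mrmr_rank",
    "infer_network",
    "network_properties",
    "write_edge_list",
    "write_graphml",
]


@dataclass
class GeneGraph:
    """Undirected positive-weight SNP graph for one gene."""

    gene_id: str
    snp_ids: list[str]
    edges: list[tuple[int, int, float]]  # (i, j, weight), i < j, weight > 0

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        for i, j, w in self.edges:
            if i == j:
                raise ValueError("self-loop in gene graph")
            if not (0 <= i < m and 0 <= j < m):
                raise ValueError("edge endpoint outside node set")
            if w <= 0:
                raise ValueError("edge weights must be strictly positive")

    @property
    def n_nodes(self) -> int:
        return len(self.snp_ids)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.snp_ids)
        for i, j, w in self.edges:
            g.add_edge(self.snp_ids[i], self.snp_ids[j], weight=w)
        return g


@dataclass
class NetworkProperties:
    """Density, mean geodesic distance and transitivity of a gene graph.

    ``mean_distance``/``transitivity`` are ``nan`` when undefined (no
    connected pair / no connected triple).
    """

    density: float
    mean_distance: float
    transitivity: float


def mrmr_rank(s: SynergyMatrix, target: int) -> list[tuple[int, float]]:
    """Greedy MRMR ranking of all non-target SNPs for one target SNP.

    Returns the m-1 other nodes in selection order with the score each had
    at selection time. Ties are broken toward the lower node index.
    """
    w = s.values
    m = s.n_snps
    if m < 2:
        raise ParameterError("need at least 2 SNPs to rank")
    if not 0 <= target < m:
        raise ParameterError(f"target {target} out of range 0..{m - 1}")
    remaining = [j for j in range(m) if j != target]
    selected: list[int] = []
    out: list[tuple[int, float]] = []
    redundancy_sum = np.zeros(m)
    while remaining:
        if not selected:
            scores = [w[j, target] for j in remaining]
        else:
            scores = [
                w[j, target] - redundancy_sum[j] / len(selected) for j in remaining
            ]
        best = int(np.argmax(scores))  # argmax -> lowest index on ties
        j = remaining.pop(best)
        out.append((j, float(scores[best])))
        selected.append(j)
        for r in remaining:
            redundancy_sum[r] += w[r, j]
    return out


def infer_network(s: SynergyMatrix) -> GeneGraph:
    """MRNET-style network: max of the two directional MRMR edge scores.

    The directed score of edge (j -> target) is j's selection-time MRMR score
    when ranking for ``target``; the undirected weight is the maximum of the
    two directions and edges with weight <= 0 are removed. Isolated nodes are
    retained.
    """
    m = s.n_snps
    directed = np.full((m, m), -np.inf)
    for target in range(m):
        for j, score in mrmr_rank(s, target):
            directed[j, target] = score
    edges = []
    for i in range(m):
        for j in range(i + 1, m):
            wgt = max(directed[i, j], directed[j, i])
            if wgt > 0:
                edges.append((i, j, float(wgt)))
    return GeneGraph(gene_id=s.gene_id, snp_ids=list(s.snp_ids), edges=edges)


def network_properties(g: GeneGraph) -> NetworkProperties:
    """Density, mean unweighted geodesic distance and global transitivity."""
    m = g.n_nodes
    if m < 2:
        raise ParameterError("need at least 2 nodes")
    nxg = g.to_networkx()
    density = 2.0 * nxg.number_of_edges() / (m * (m - 1))
    total, pairs = 0.0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(nxg):
        for d in lengths.values():
            if d > 0:
                total += d
                pairs += 1
    mean_distance = total / pairs if pairs else math.nan
    triangles = sum(nx.triangles(nxg).values()) / 3
    triples = sum(d * (d - 1) / 2 for _, d in nxg.degree())
    transitivity = 3.0 * triangles / triples if triples else math.nan
    return NetworkProperties(density, mean_distance, transitivity)


def write_edge_list(g: GeneGraph, path) -> None:
    """TSV edge list: snp_i, snp_j, weight."""
    with open(path, "w") as fh:
        fh.write("snp_i\tsnp_j\tweight\n")
        for i, j, w in g.edges:
            fh.write(f"{g.snp_ids[i]}\t{g.snp_ids[j]}\t{w:.10g}\n")


def write_graphml(g: GeneGraph, path) -> None:
    nx.write_graphml(g.to_networkx(), path)
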