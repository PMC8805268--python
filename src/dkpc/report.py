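"""Gene-level statistical epistasis network assembly and export."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .errors import ParameterError
from .model import PosteriorSummary, select_effects

__all__ = ["EpistasisNetwork", "build_network", "export", "write_gene_list"]


@dataclass
class EpistasisNetwork:
    """Genes (with marginal PIP) joined by interaction-PIP edges."""

    nodes: list[tuple[str, float]]            # (gene, marginal pip)
    edges: list[tuple[str, str, float]]       # (gene1, gene2, interaction pip)

    def __post_init__(self) -> None:
        names = {g for g, _ in self.nodes}
        for g1, g2, _ in self.edges:
            if g1 == g2:
                raise ValueError("self-edge in epistasis network")
            if g1 not in names or g2 not in names:
                raise ValueError("edge endpoint missing from node set")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for gene, pip in self.nodes:
            g.add_node(gene, pip=float(pip))
        for g1, g2, pip in self.edges:
            g.add_edge(g1, g2, pip=float(pip))
        return g


def build_network(ps: PosteriorSummary, threshold: float = 0.0) -> EpistasisNetwork:
    """Network over genes appearing in any retained effect.

    Nodes are genes with marginal PIP above the threshold or involved in a
    retained pair; edges are pairs with interaction PIP above the threshold.
    Node attribute = marginal PIP.
    """
    genes, pairs = select_effects(ps, threshold=threshold)
    marg = dict(zip(ps.gene_ids, (float(v) for v in ps.marginal_pip)))
    names = {g for g, _ in genes}
    names.update(g for pair in pairs for g in pair[:2])
    nodes = sorted((g, marg[g]) for g in names)
    return EpistasisNetwork(nodes=nodes, edges=pairs)


def export(net: EpistasisNetwork, path: str | Path, fmt: str = "edge_tsv") -> None:
    """Write the network as GraphML or as a PIP-sorted TSV edge list."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif fmt == "edge_tsv":
        rows = sorted(net.edges, key=lambda t: (-t[2], t[0], t[1]))
        with open(path, "w") as fh:
            fh.write("gene1\tgene2\tpip\n")
            for g1, g2, pip in rows:
                fh.write(f"{g1}\t{g2}\t{pip:.6g}\n")
    else:
        raise ParameterError(f"unknown export format {fmt!r}")


def write_gene_list(net: EpistasisNetwork, path: str | Path) -> None:
    """One gene symbol per line — the search-term format of network
    annotation services."""
    with open(path, "w") as fh:
        for gene, _ in net.nodes:
            fh.write(gene + "\n")
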