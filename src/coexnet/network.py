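"""Hybrid network construction, module extraction and node scoring.

An edge joins genes i and j when either association measure clears its
threshold — ``pcc(i, j) > t_pcc  OR  mi(i, j) > t_mi`` (strict) — so the
network retains both linear and nonlinear relationships.  Modules are the
connected components large enough for centrality analysis.  Each retained
gene is scored by ``W = D * B``: raw degree D (local importance) times
betweenness centrality B (global importance), with B normalized within the
gene's component so values are comparable across modules and lie in [0, 1].
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationMatrix
from .errors import ValidationError

__all__ = [
    "CoexpressionNetwork",
    "NodeScore",
    "build_adjacency",
    "extract_modules",
    "degree_centrality",
    "betweenness_all",
    "score_nodes",
    "rank_genes",
    "write_sif",
    "write_graphml",
]


@dataclass
class CoexpressionNetwork:
    """An undirected simple graph over genes, with retained modules.

    ``modules`` is empty until :func:`extract_modules` is applied; after
    extraction the graph is restricted to nodes inside retained modules and
    ``modules`` holds the components, largest first.
    """

    graph: nx.Graph
    modules: tuple[frozenset[str], ...] = ()
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def module_of(self, gene: str) -> str | None:
        for idx, members in enumerate(self.modules, start=1):
            if gene in members:
                return f"M{idx}"
        return None


@dataclass(frozen=True)
class NodeScore:
    """Per-gene centrality record: W = degree x betweenness."""

    gene_id: str
    module_id: str
    degree: int
    betweenness: float
    weight: float


def build_adjacency(
    pcc: AssociationMatrix,
    mi: AssociationMatrix,
    t_pcc: float,
    t_mi: float,
) -> CoexpressionNetwork:
    """Hybrid adjacency: edge iff PCC > t_pcc or MI > t_mi (strict).

    Both matrices must carry identical gene ids in identical order.  The
    diagonal never yields self-loops.
    """
    if pcc.gene_ids != mi.gene_ids:
        raise ValidationError("PCC and MI matrices must share gene ids in the same order")
    mask = (pcc.values > t_pcc) | (mi.values > t_mi)
    np.fill_diagonal(mask, False)
    graph = nx.Graph()
    graph.add_nodes_from(pcc.gene_ids)
    ii, jj = np.nonzero(np.triu(mask, k=1))
    genes = pcc.gene_ids
    graph.add_edges_from((genes[i], genes[j]) for i, j in zip(ii, jj))
    return CoexpressionNetwork(
        graph=graph,
        provenance={"t_pcc": t_pcc, "t_mi": t_mi},
    )


def extract_modules(net: CoexpressionNetwork, min_module_size: int = 15) -> CoexpressionNetwork:
    """Keep connected components with at least ``min_module_size`` nodes.

    Returns a new network restricted to the retained nodes.  Modules are
    ordered by decreasing size, ties broken by smallest gene id, so module
    numbering is deterministic.
    """
    if min_module_size < 2:
        raise ValidationError("min_module_size must be >= 2")
    components = [
        frozenset(c)
        for c in nx.connected_components(net.graph)
        if len(c) >= min_module_size
    ]
    components.sort(key=lambda c: (-len(c), min(c)))
    keep = set().union(*components) if components else set()
    sub = net.graph.subgraph(keep).copy()
    provenance = dict(net.provenance)
    provenance["min_module_size"] = min_module_size
    return CoexpressionNetwork(graph=sub, modules=tuple(components), provenance=provenance)


def degree_centrality(net: CoexpressionNetwork, gene: str) -> int:
    """Raw incident-edge count of a gene (unnormalized degree)."""
    if gene not in net.graph:
        raise ValidationError(f"gene {gene!r} not in network")
    return int(net.graph.degree[gene])


def betweenness_all(net: CoexpressionNetwork) -> dict[str, float]:
    """Betweenness centrality of every node, normalized per component.

    For node x in a component of size n_c, B(x) is the sum over unordered
    pairs {i, j} (i != x != j) of the fraction of shortest i-j paths passing
    through x, divided by (n_c - 1)(n_c - 2) / 2.  Components of size <= 2
    contribute zeros.
    """
    result: dict[str, float] = {}
    for comp in nx.connected_components(net.graph):
        if len(comp) <= 2:
            result.update({g: 0.0 for g in comp})
            continue
        sub = net.graph.subgraph(comp)
        result.update(nx.betweenness_centrality(sub, normalized=True))
    return result


def score_nodes(net: CoexpressionNetwork) -> list[NodeScore]:
    """One W = D x B score per retained node; requires extracted modules."""
    if not net.modules and net.graph.number_of_nodes() > 0:
        raise ValidationError("extract modules before scoring nodes")
    betweenness = betweenness_all(net)
    scores = []
    for gene in net.graph.nodes:
        d = int(net.graph.degree[gene])
        b = betweenness[gene]
        scores.append(
            NodeScore(
                gene_id=gene,
                module_id=net.module_of(gene) or "",
                degree=d,
                betweenness=b,
                weight=d * b,
            )
        )
    return scores


def rank_genes(scores: list[NodeScore], top_k: int) -> pd.DataFrame:
    """Global ranking by W descending; ties by higher degree, then gene id."""
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    ordered = sorted(scores, key=lambda s: (-s.weight, -s.degree, s.gene_id))
    rows = [
        {
            "rank": r,
            "gene_id": s.gene_id,
            "module_id": s.module_id,
            "degree": s.degree,
            "betweenness": s.betweenness,
            "weight": s.weight,
        }
        for r, s in enumerate(ordered[:top_k], start=1)
    ]
    return pd.DataFrame(
        rows, columns=["rank", "gene_id", "module_id", "degree", "betweenness", "weight"]
    )


def write_sif(net: CoexpressionNetwork, path: str | os.PathLike, relation: str = "coexp") -> None:
    """Write edges as SIF (``geneA<TAB>coexp<TAB>geneB``); isolates as bare names."""
    with open(path, "w", encoding="utf-8") as handle:
        for a, b in sorted((sorted(e) for e in net.graph.edges)):
            handle.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(net.graph.nodes):
            if net.graph.degree[node] == 0:
                handle.write(f"{node}\n")


def write_graphml(net: CoexpressionNetwork, path: str | os.PathLike) -> None:
    """Write the network as GraphML with module membership as a node attribute."""
    graph = net.graph.copy()
    for gene in graph.nodes:
        graph.nodes[gene]["module"] = net.module_of(gene) or ""
    nx.write_graphml(graph, path)
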