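"""Curated knowledge-based interaction network and comparison utilities.

The knowledge network is an input artifact: a gene-gene edge table with a
confidence score, restricted to a curated list of pathway genes. No
database is queried at run time — frozen exports are the ground truth,
since interaction-database contents drift between versions. Comparison
with the co-expression network covers node overlap and hub (degree)
ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from protcoex.io import make_edge
from protcoex.network import WeightedNetwork

logger = logging.getLogger(__name__)


@dataclass
class KnowledgeNetwork:
    """Undirected gene network with per-edge confidence scores in [0, 1]."""

    graph: nx.Graph
    pathway_genes: frozenset[str] = frozenset()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_knowledge_network(
    edge_table: pd.DataFrame,
    pathway_genes: Iterable[str],
    min_score: float = 0.4,
) -> KnowledgeNetwork:
    """Filter an interaction edge table to pathway genes and a score floor.

    ``edge_table`` needs two gene columns and a score column (first three
    columns are used). Keeps edges with BOTH endpoints in
    ``pathway_genes`` and score >= ``min_score`` (0.4 is the usual
    medium-confidence convention). Gene symbols are uppercased; edges are
    canonicalized and duplicates keep the maximum score.
    """
    genes = frozenset(g.upper() for g in pathway_genes)
    if not genes:
        raise ValueError("pathway gene list must be nonempty")
    if edge_table.shape[1] < 3:
        raise ValueError("edge table needs gene_a, gene_b and score columns")
    g = nx.Graph()
    a_col, b_col, s_col = edge_table.columns[:3]
    for _, row in edge_table.iterrows():
        u, v = str(row[a_col]).upper(), str(row[b_col]).upper()
        score = float(row[s_col])
        if u == v or u not in genes or v not in genes or score < min_score:
            continue
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"confidence score {score} outside [0, 1] for edge {u}-{v}")
        if g.has_edge(u, v):
            g[u][v]["score"] = max(g[u][v]["score"], score)
        else:
            g.add_edge(u, v, score=score)
    if g.number_of_edges() == 0:
        logger.warning("knowledge network is empty after filtering")
    return KnowledgeNetwork(graph=g, pathway_genes=genes)


def map_protein_ids(nodes: Iterable[str], id_map: dict[str, str] | None) -> set[str]:
    """Map protein ids to uppercase gene symbols; unmapped ids are dropped."""
    if id_map is None:
        return {n.upper() for n in nodes}
    mapped = {id_map[n].upper() for n in nodes if n in id_map}
    n_unmapped = sum(1 for n in nodes if n not in id_map)
    if n_unmapped:
        logger.info("%d node(s) without a gene-symbol mapping dropped", n_unmapped)
    return mapped


def overlap_nodes(
    net_a: WeightedNetwork | KnowledgeNetwork,
    net_b: WeightedNetwork | KnowledgeNetwork,
    id_map: dict[str, str] | None = None,
) -> set[str]:
    """Nodes present in both networks after uppercase symbol normalization.

    ``id_map`` (protein id -> gene symbol) is applied to co-expression
    nodes when given.
    """

    def node_symbols(net) -> set[str]:
        nodes = net.graph.nodes
        if isinstance(net, WeightedNetwork):
            return map_protein_ids(nodes, id_map)
        return {n.upper() for n in nodes}

    shared = node_symbols(net_a) & node_symbols(net_b)
    logger.info("node overlap: %d shared nodes", len(shared))
    return shared


def degree_ranking(
    net: WeightedNetwork | KnowledgeNetwork, top_n: int = 20
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Hub list, degree histogram and median degree of a network.

    Returns (hubs, histogram, median): hubs is the top ``top_n`` nodes by
    degree (ties alphabetical; all nodes when top_n exceeds the node
    count); histogram maps degree -> node count and sums to the node
    count.
    """
    graph = net.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    degrees = pd.Series(dict(graph.degree()), name="degree").astype(int)
    hubs = (
        degrees.sort_index()
        .sort_values(ascending=False, kind="mergesort")
        .head(top_n)
        .rename_axis("node")
        .reset_index()
    )
    histogram = degrees.value_counts().sort_index()
    histogram.index.name = "degree"
    return hubs, histogram, float(np.median(degrees.to_numpy()))
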