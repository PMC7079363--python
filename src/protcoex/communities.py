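"""Edge-betweenness (Girvan-Newman) communities and module-level tests.

Community detection removes, one at a time, the edge with the highest
betweenness (recomputed after every removal), and selects among the
resulting nested partitions the one maximizing Newman-Girvan modularity

    Q = sum_c (e_c / m - (d_c / 2m)^2)

on the original, unweighted graph. Two backends are provided: the fast C
implementation in igraph (default) and a pure-Python reference
implementation with a fully specified canonical tie-break, used for small
graphs and for cross-checking.

Module-level analyses: size filtering, per-module hypergeometric
enrichment, and the fold-change reversal test — a two-tailed paired t-test
across a module's proteins comparing their median replicate-wise log2 fold
changes in the O19_vs_O1 contrast against those in O19_vs_O1CyA. A small p
means the module's hypoxia response differs with and without CyA, i.e. the
module is restored by the drug.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from protcoex.diffexp import parse_contrast
from protcoex.enrichment import hypergeometric_enrich
from protcoex.io import LOG2, AbundanceMatrix, GeneSetCollection
from protcoex.network import WeightedNetwork

logger = logging.getLogger(__name__)


@dataclass
class ModuleSet:
    """A community partition with the modularity of the selected cut."""

    partition: dict[str, int]          # node -> module id (ids by decreasing size)
    modularity: float
    backend: str = "igraph"
    reversal: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None

    @property
    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, mid in self.partition.items():
            out.setdefault(mid, []).append(node)
        return {mid: sorted(nodes) for mid, nodes in out.items()}

    def sizes(self) -> dict[int, int]:
        return {mid: len(nodes) for mid, nodes in self.modules.items()}


def _relabel_by_size(groups: list[set[str]]) -> dict[str, int]:
    """Module ids 0, 1, ... by decreasing size, ties by smallest member."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    return {node: mid for mid, group in enumerate(ordered) for node in group}


def _modularity(original: nx.Graph, communities: list[set[str]]) -> float:
    if original.number_of_edges() == 0:
        return 0.0
    return nx.algorithms.community.modularity(original, communities, weight=None)


def _girvan_newman_python(graph: nx.Graph) -> tuple[list[set[str]], float]:
    """Reference implementation with canonical (sorted-edge) tie-breaking."""
    working = nx.Graph(graph)
    best_partition = [set(c) for c in nx.connected_components(working)]
    best_q = _modularity(graph, best_partition)
    while working.number_of_edges() > 0:
        ebc = nx.edge_betweenness_centrality(working, normalized=False, weight=None)
        max_val = max(ebc.values())
        candidates = [tuple(sorted(e)) for e, v in ebc.items() if
                      math.isclose(v, max_val, rel_tol=1e-12, abs_tol=1e-12)]
        u, v = min(candidates)
        working.remove_edge(u, v)
        communities = [set(c) for c in nx.connected_components(working)]
        q = _modularity(graph, communities)
        if q > best_q + 1e-12:
            best_q = q
            best_partition = communities
    return best_partition, best_q


def _girvan_newman_igraph(graph: nx.Graph) -> tuple[list[set[str]], float]:
    import igraph as ig

    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = sorted((index[u], index[v]) if index[u] < index[v] else (index[v], index[u])
                   for u, v in graph.edges)
    g = ig.Graph(n=len(nodes), edges=edges)
    dendrogram = g.community_edge_betweenness(directed=False, weights=None)
    clustering = dendrogram.as_clustering()
    groups = [set(nodes[i] for i in cluster) for cluster in clustering]
    return groups, _modularity(graph, groups)


def girvan_newman(network: WeightedNetwork | nx.Graph, backend: str = "igraph") -> ModuleSet:
    """Partition a network by iterative removal of high-betweenness edges.

    Betweenness and modularity are computed on the unweighted graph. The
    partition maximizing modularity across the removal sequence is
    returned; with no edges, every node is its own singleton community.
    Deterministic for a given input and backend.
    """
    graph = network.graph if isinstance(network, WeightedNetwork) else network
    if graph.number_of_nodes() == 0:
        return ModuleSet(partition={}, modularity=0.0, backend=backend)
    if graph.number_of_edges() == 0:
        groups = [{n} for n in graph.nodes]
        return ModuleSet(partition=_relabel_by_size(groups), modularity=0.0, backend=backend)
    if backend == "python":
        groups, q = _girvan_newman_python(graph)
    elif backend == "igraph":
        groups, q = _girvan_newman_igraph(graph)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return ModuleSet(partition=_relabel_by_size(groups), modularity=q, backend=backend)


def filter_modules(moduleset: ModuleSet, min_size: int = 10) -> list[tuple[int, list[str]]]:
    """Modules with >= ``min_size`` members, largest first then by id."""
    items = [(mid, nodes) for mid, nodes in moduleset.modules.items() if len(nodes) >= min_size]
    return sorted(items, key=lambda kv: (-len(kv[1]), kv[0]))


def replicate_fold_changes(matrix: AbundanceMatrix, contrast: str) -> pd.Series:
    """Median over replicates of the replicate-paired log2 fold change.

    For contrast A_vs_B, replicate i contributes (value in A's replicate i)
    minus (value in B's replicate i); the per-protein statistic is the
    median of these paired differences across replicates.
    """
    if matrix.scale != LOG2:
        raise ValueError("replicate_fold_changes expects log2-scale values")
    cond_a, cond_b = parse_contrast(contrast, matrix.conditions)
    meta = matrix.sample_meta

    def by_replicate(cond: str) -> dict[int, str]:
        return {
            int(meta.loc[s, "replicate"]): s
            for s in matrix.sample_ids
            if meta.loc[s, "condition"] == cond
        }

    reps_a, reps_b = by_replicate(cond_a), by_replicate(cond_b)
    shared = sorted(set(reps_a) & set(reps_b))
    if not shared:
        raise ValueError(f"no shared replicate indices between {cond_a} and {cond_b}")
    diffs = np.column_stack(
        [
            matrix.values[reps_a[r]].to_numpy() - matrix.values[reps_b[r]].to_numpy()
            for r in shared
        ]
    )
    return pd.Series(np.median(diffs, axis=1), index=matrix.values.index, name=contrast)


def module_reversal_test(
    members: list[str],
    lfc_a: pd.Series,
    lfc_b: pd.Series,
    alpha: float = 0.05,
    paired: bool = True,
) -> tuple[float, bool, float]:
    """Two-tailed t-test of a module's fold changes across two contrasts.

    Compares the members' log2 fold changes in contrast A (O19_vs_O1)
    against contrast B (O19_vs_O1CyA); a paired test by default, since the
    same proteins appear in both contrasts (``paired=False`` switches to
    Welch). Returns (p, flag, t) with flag = (p <= alpha). With zero
    variance of the paired differences: p = 1 if all differences are zero,
    otherwise a hard error suggesting the unpaired fallback.
    """
    if len(members) < 2:
        raise ValueError("reversal test needs a module of size >= 2")
    a = lfc_a.loc[members].to_numpy(dtype=float)
    b = lfc_b.loc[members].to_numpy(dtype=float)
    if paired:
        d = a - b
        if np.allclose(d.std(ddof=0), 0.0):
            if np.allclose(d, 0.0):
                return 1.0, False, 0.0
            raise ValueError(
                "paired differences have zero variance but nonzero mean; "
                "use paired=False for the unpaired fallback"
            )
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p), bool(p <= alpha), float(t)


def run_reversal_tests(
    moduleset: ModuleSet,
    lfc_a: pd.Series,
    lfc_b: pd.Series,
    min_size: int = 10,
    alpha: float = 0.05,
    paired: bool = True,
) -> pd.DataFrame:
    """Reversal test for every module of >= ``min_size`` members."""
    rows = []
    for mid, members in filter_modules(moduleset, min_size=min_size):
        p, flag, t = module_reversal_test(members, lfc_a, lfc_b, alpha=alpha, paired=paired)
        rows.append({"module": mid, "size": len(members), "t": t, "p": p, "flag": flag})
    df = pd.DataFrame(rows, columns=["module", "size", "t", "p", "flag"])
    moduleset.reversal = df
    return df


def module_enrichment(
    moduleset: ModuleSet,
    collection: GeneSetCollection,
    universe,
    min_size: int = 10,
    alpha: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Top enriched gene set (p <= alpha) per module of >= ``min_size``.

    Reports the smallest-p set with p <= alpha per module ("none" if no set
    qualifies) together with -log10 p.
    """
    rows = []
    for mid, members in filter_modules(moduleset, min_size=min_size):
        table = hypergeometric_enrich(members, collection, universe, **kwargs)
        hit = table[table["p"] <= alpha]
        if len(hit):
            top = hit.iloc[0]
            rows.append(
                {
                    "module": mid,
                    "size": len(members),
                    "top_set": top["set_name"],
                    "p": float(top["p"]),
                    "neg_log10_p": float(-np.log10(top["p"])),
                }
            )
        else:
            rows.append(
                {"module": mid, "size": len(members), "top_set": "none",
                 "p": float("nan"), "neg_log10_p": float("nan")}
            )
    df = pd.DataFrame(rows, columns=["module", "size", "top_set", "p", "neg_log10_p"])
    moduleset.enrichment = df
    return df
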