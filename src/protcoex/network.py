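"""Permutation-thresholded absolute-Pearson co-expression network.

Edges between proteins are weighted by the absolute Pearson correlation of
their log2 abundance profiles across samples. Each candidate edge gets a
z-score against a permutation null built by independently permuting every
protein's values across samples (50 permutations by default), which breaks
inter-protein association while preserving each profile's marginal
distribution. An edge survives iff |z| >= z_min (default 1.5) AND
weight > w_min (default 0.5, strict because edges with weight <= 0.5 are
removed); nodes are the endpoints of surviving edges only.

Permuting all rows by one shared permutation would leave every correlation
unchanged, so the per-row-independent scheme is the only reading of
"permutation of sample labels" that produces a null at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from protcoex.io import LOG2, AbundanceMatrix, EdgeRecord, make_edge

logger = logging.getLogger(__name__)


@dataclass
class WeightedNetwork:
    """Undirected network whose edges carry weight (|r|) and z-score."""

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_records(self) -> set[EdgeRecord]:
        return {
            make_edge(u, v, d.get("weight", 1.0), d.get("zscore"))
            for u, v, d in self.graph.edges(data=True)
        }


def _standardize_rows(arr: np.ndarray) -> np.ndarray:
    """Center and scale rows to unit norm so that X @ X.T is the correlation."""
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    zero = norms[:, 0] == 0
    if zero.any():
        raise ValueError(
            f"constant profile for protein index {int(np.flatnonzero(zero)[0])}; "
            "apply cv_filter first"
        )
    return centered / norms


def pairwise_abs_pearson(matrix: AbundanceMatrix) -> tuple[list[str], np.ndarray]:
    """Absolute Pearson correlation for every protein pair.

    Returns the protein ids and a symmetric matrix W with W[i, j] = |r|
    between proteins i and j (the diagonal is not meaningful and set to 0).
    A constant profile is a hard error naming the protein.
    """
    if matrix.scale != LOG2:
        raise ValueError("pairwise_abs_pearson expects log2-scale values")
    if len(matrix.sample_ids) < 3:
        raise ValueError("need at least 3 samples for correlations")
    arr = matrix.values.to_numpy(dtype=float)
    const = arr.std(axis=1) == 0
    if const.any():
        offender = matrix.values.index[np.flatnonzero(const)[0]]
        raise ValueError(f"constant profile for protein {offender!r}; apply cv_filter first")
    X = _standardize_rows(arr)
    W = np.abs(X @ X.T)
    np.clip(W, 0.0, 1.0, out=W)
    np.fill_diagonal(W, 0.0)
    return list(matrix.values.index), W


def permute_rows(arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each row of ``arr`` across columns."""
    keys = rng.random(arr.shape)
    order = np.argsort(keys, axis=1)
    return np.take_along_axis(arr, order, axis=1)


def permutation_zscores(
    matrix: AbundanceMatrix, n_perm: int = 50, seed: int | None = None
) -> tuple[list[str], np.ndarray]:
    """Per-pair z-score of the observed |r| against its permutation null.

    For each of ``n_perm`` iterations every protein's values are permuted
    independently across samples and all pairwise |r| recomputed;
    z = (w_obs - mean_perm) / sd_perm with the sample sd (n_perm - 1
    denominator). Deterministic given ``seed`` (mandatory). A pair with
    sd_perm = 0 gets z = +inf if w_obs exceeds the permutation mean, else
    0, with a warning.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for permutation z-scores")
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    ids, W = pairwise_abs_pearson(matrix)
    rng = np.random.default_rng(seed)
    arr = matrix.values.to_numpy(dtype=float)
    total = np.zeros_like(W)
    total_sq = np.zeros_like(W)
    for _ in range(n_perm):
        Xp = _standardize_rows(permute_rows(arr, rng))
        Wp = np.abs(Xp @ Xp.T)
        total += Wp
        total_sq += Wp**2
    mean = total / n_perm
    var = (total_sq - n_perm * mean**2) / (n_perm - 1)
    np.clip(var, 0.0, None, out=var)
    sd = np.sqrt(var)
    np.fill_diagonal(sd, 1.0)  # diagonal is never an edge
    degenerate = sd == 0
    np.fill_diagonal(degenerate, False)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (W - mean) / sd
    if degenerate.any():
        logger.warning(
            "%d pair(s) with zero permutation sd", int(degenerate.sum()) // 2
        )
        Z[degenerate] = np.where(W[degenerate] > mean[degenerate], np.inf, 0.0)
    np.fill_diagonal(Z, 0.0)
    return ids, Z


def threshold_network(
    protein_ids: list[str],
    weights: np.ndarray,
    zscores: np.ndarray,
    z_min: float = 1.5,
    w_min: float = 0.5,
    provenance: dict | None = None,
) -> WeightedNetwork:
    """Apply the dual edge filter and drop isolated proteins.

    An edge (i, j) is retained iff |z| >= z_min AND w > w_min (strictly:
    edges with weight <= w_min are removed). The node set consists of the
    endpoints of retained edges only.
    """
    if weights.shape != zscores.shape or weights.shape[0] != len(protein_ids):
        raise ValueError("weights and zscores must cover the same protein pairs")
    keep = (np.abs(zscores) >= z_min) & (weights > w_min)
    iu = np.triu_indices(len(protein_ids), k=1)
    mask = keep[iu]
    g = nx.Graph()
    ii, jj = iu[0][mask], iu[1][mask]
    for i, j in zip(ii, jj):
        g.add_edge(
            protein_ids[i],
            protein_ids[j],
            weight=float(weights[i, j]),
            zscore=float(zscores[i, j]),
        )
    prov = dict(provenance or {})
    prov.update({"z_min": z_min, "w_min": w_min})
    logger.info(
        "thresholded network: %d nodes, %d edges (|z|>=%g, w>%g)",
        g.number_of_nodes(),
        g.number_of_edges(),
        z_min,
        w_min,
    )
    return WeightedNetwork(graph=g, provenance=prov)


def network_from_edges(edges, provenance: dict | None = None) -> WeightedNetwork:
    """Build a :class:`WeightedNetwork` from :class:`EdgeRecord` objects."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.node_a, e.node_b, weight=e.weight, zscore=e.zscore)
    return WeightedNetwork(graph=g, provenance=dict(provenance or {}))
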