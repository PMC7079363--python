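"""Hypergeometric over-representation of a query set in gene-set collections.

For a universe of N genes of which K belong to a set, and a query of n
genes with k of them in the set, the enrichment p-value is the inclusive
upper tail P(X >= k) of Hypergeometric(N, K, n) — identical to the
one-sided Fisher exact test of the corresponding 2x2 table. Results are
BH-adjusted across all sets tested.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from protcoex.io import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), inclusive of k."""
    if k <= max(0, n + K - N):
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_set_size: int = 3,
    max_set_size: int = 500,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every set of ``collection``.

    Identifiers are uppercased on both sides. Query members outside the
    universe are dropped with a warning; set sizes are counted within the
    universe and sets outside ``[min_set_size, max_set_size]`` are not
    tested. Returns a DataFrame sorted by p with columns set_name, k, n,
    K, N, p, p_adj, overlap.
    """
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValueError("universe must be nonempty")
    query_set = {g.upper() for g in query}
    outside = query_set - universe_set
    if outside:
        logger.warning("%d query member(s) outside the universe dropped", len(outside))
        query_set -= outside
    if not query_set:
        logger.warning("query is empty after intersecting with the universe")
        return pd.DataFrame(
            columns=["set_name", "k", "n", "K", "N", "p", "p_adj", "overlap"]
        )
    N = len(universe_set)
    n = len(query_set)
    rows = []
    for name, members in collection:
        in_universe = members & universe_set
        K = len(in_universe)
        if K < min_set_size or K > max_set_size:
            continue
        overlap = sorted(in_universe & query_set)
        k = len(overlap)
        rows.append(
            {
                "set_name": name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": hypergeom_upper_tail(k, N, K, n),
                "overlap": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "k", "n", "K", "N", "p", "p_adj", "overlap"]
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    return df[["set_name", "k", "n", "K", "N", "p", "p_adj", "overlap"]]


def enrich_de_proteins(
    de_set: Iterable[str],
    collection: GeneSetCollection,
    quantified: Iterable[str],
    restrict_universe_to_annotated: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """Pathway over-representation of the differential proteins.

    The universe defaults to the quantified proteins intersected with the
    union of collection members (the convention of enrichment tools that
    condition on annotated genes); pass
    ``restrict_universe_to_annotated=False`` to use all quantified
    proteins instead.
    """
    quantified_set = {g.upper() for g in quantified}
    if restrict_universe_to_annotated:
        universe = quantified_set & {g for g in collection.all_members}
    else:
        universe = quantified_set
    return hypergeometric_enrich(de_set, collection, universe, **kwargs)
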