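#!/usr/bin/env python
"""Compare the co-expression network with the curated knowledge network.

Builds the knowledge-based network from the synthetic curated interaction
table (edges restricted to the pathway gene list, confidence >= 0.4),
intersects its node set with the benchmark co-expression network, and
ranks hubs by degree in both. Writes the overlap list, hub tables and the
degree histogram of the co-expression network.
"""

import json
from pathlib import Path

import pandas as pd

from protcoex import build_knowledge_network, degree_ranking, overlap_nodes, read_edge_list
from protcoex.network import network_from_edges

DATA = Path("results/data")
NET = Path("results/network")
OUT = Path("results/knowledge")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    net = network_from_edges(read_edge_list(NET / "benchmark_edges.tsv"))
    edge_table = pd.read_csv(DATA / "knowledge_edges.tsv", sep="\t")
    pathway_genes = [
        ln.strip() for ln in (DATA / "pathway_genes.txt").read_text().splitlines()
        if ln.strip()
    ]
    knet = build_knowledge_network(edge_table, pathway_genes, min_score=0.4)
    print(f"knowledge network: {len(knet.nodes)} nodes, {knet.n_edges} edges "
          f"(from {len(pathway_genes)} pathway genes)")
    shared = overlap_nodes(net, knet)
    (OUT / "overlap_nodes.txt").write_text("\n".join(sorted(shared)) + "\n")
    print(f"nodes shared between co-expression and knowledge networks: {len(shared)}")

    hubs, hist, median = degree_ranking(net, top_n=20)
    hubs.to_csv(OUT / "coexpression_hubs.tsv", sep="\t", index=False)
    hist.rename("count").to_csv(OUT / "degree_histogram.tsv", sep="\t")
    print(f"co-expression degree: median {median:.0f}; "
          f"top hub {hubs.iloc[0]['node']} (degree {hubs.iloc[0]['degree']})")
    khubs, _, kmedian = degree_ranking(knet, top_n=20)
    khubs.to_csv(OUT / "knowledge_hubs.tsv", sep="\t", index=False)
    summary = {
        "knowledge_nodes": len(knet.nodes),
        "knowledge_edges": knet.n_edges,
        "overlap_nodes": len(shared),
        "coexpression_median_degree": median,
        "knowledge_median_degree": kmedian,
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
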