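#!/usr/bin/env python
"""Filter, transform and test the abundance table for differential proteins.

Reads the dataset written by 01_simulate.py, applies the low-abundance
filter (>= 1 count in every sample), log2-transforms, fits condition
means, moderates the variances empirically and tests the three contrasts
at the study thresholds (raw p <= 0.01, |log2FC| >= 0.5). Also classifies
"restored" proteins — differential under hypoxia and under CyA-vs-hypoxia
but indistinguishable from normoxia once CyA is added — and runs pathway
over-representation of the DE union. Tables land in results/diffexp/.
"""

import json
from pathlib import Path

from protcoex import (
    call_de,
    classify_restored,
    compute_contrast,
    enrich_de_proteins,
    filter_low_abundance,
    fit_condition_means,
    log2_transform,
    moderate_variances,
    qq_normality_check,
    read_abundance_table,
    read_gmt,
)
from protcoex.diffexp import CANONICAL_CONTRASTS

DATA = Path("results/data")
OUT = Path("results/diffexp")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = read_abundance_table(DATA / "abundance.tsv", DATA / "samples.tsv")
    filtered, report = filter_low_abundance(matrix)
    print(f"low-abundance filter: {report.n_input} -> {report.n_output} proteins")
    log2m = log2_transform(filtered)
    qq = qq_normality_check(log2m)
    qq.to_csv(OUT / "qq_normality.tsv", sep="\t", float_format="%.6g")
    print(f"log2 normality (Shapiro-Wilk): min per-sample p = {qq['p'].min():.3g}")

    mfit = moderate_variances(fit_condition_means(log2m))
    print(f"empirical-Bayes prior: d0 = {mfit.d0:.2f}, s0^2 = {mfit.s0_sq:.4f}")
    de_sets = {}
    for name in CANONICAL_CONTRASTS:
        res = compute_contrast(mfit, name)
        de_sets[name] = call_de(res)
        table = res.table.copy()
        table["de"] = table.index.isin(de_sets[name])
        table.index.name = "protein"
        table.to_csv(OUT / f"contrast_{name}.tsv", sep="\t", float_format="%.6g")
        print(f"contrast {name}: {len(de_sets[name])} DE proteins")
    contrasts = {n: compute_contrast(mfit, n) for n in CANONICAL_CONTRASTS}
    restored = classify_restored(contrasts)
    print(f"restored by CyA: {len(restored)} proteins")

    collection = read_gmt(DATA / "gene_sets.gmt")
    de_union = set().union(*de_sets.values())
    enrich = enrich_de_proteins(de_union, collection, log2m.protein_ids, min_set_size=3)
    enrich.to_csv(OUT / "de_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    top = enrich.iloc[0] if len(enrich) else None
    if top is not None:
        print(f"top enriched set for the DE union: {top['set_name']} (p = {top['p']:.2e})")
    summary = {
        "filter": report.to_dict(),
        "d0": mfit.d0, "s0_sq": mfit.s0_sq,
        "de_counts": {k: len(v) for k, v in de_sets.items()},
        "de_union": len(de_union),
        "restored": sorted(restored),
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
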