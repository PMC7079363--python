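# protcoex

Differential protein abundance and co-expression network analysis for a
three-condition TMT proteomics design: B cells grown at 19% O₂ (normoxia),
1% O₂ (hypoxia), and 1% O₂ + cyclosporine A (CyA). The scientific question
is which proteins and which co-expressed protein modules respond to
hypoxia, and which of those responses CyA reverts ("restores") — the
proteomic signature of CyA destabilizing HIF-1α signaling.

## What it computes

**Differential abundance.** After a low-abundance filter (≥ 1 count in
every sample) and log2 transform, each protein gets a one-way-layout fit
with condition means and pooled residual variance s²_g (d_g = N − k df).
Variances are moderated with the standard empirical-Bayes machinery: the
prior (d₀, s₀²) is estimated by matching the mean and variance of
log s²_g to the log scaled-F distribution (digamma/trigamma inversion),
and the posterior variance

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)

yields the moderated t statistic with d₀ + d_g df for each pairwise
contrast (log2FC = mean(A) − mean(B)). A protein is differential at raw
p ≤ 0.01 and |log2FC| ≥ 0.5, and *restored* if it is differential in
O19_vs_O1 and O1_vs_O1CyA but not in O19_vs_O1CyA.

**Co-expression network.** On CV-filtered proteins (sd/mean ≥ 0.01 across
all samples, raw scale), edges are weighted by the absolute Pearson
correlation |r| of log2 profiles. Each edge gets a z-score against a null
built from 50 permutations that independently shuffle every protein's
values across samples; edges survive iff |z| ≥ 1.5 and w > 0.5.

**Modules.** Girvan–Newman edge-betweenness community detection with the
max-modularity cut (igraph backend, plus a pure-Python reference
implementation), modules of ≥ 10 proteins, per-module hypergeometric
gene-set over-representation (upper tail, equal to the one-sided Fisher
exact test), and a module *reversal test*: a two-tailed paired t-test
across module members comparing median replicate-wise log2 fold changes
in O19_vs_O1 against O19_vs_O1CyA.

**Knowledge comparison.** Node overlap and degree-ranked hubs against a
curated (frozen, file-based) interaction network restricted to pathway
genes with confidence ≥ 0.4.

**Synthetic data.** A generator plants all of the above structure
(log-normal abundances, ±δ hypoxia effects, CyA-restored proteins,
latent-factor co-expression modules including one module-wide
CyA-reverted shift, low-abundance and low-CV bait) with named, seeded RNG
streams, so every stage is testable without any external download.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (`python analysis/01_simulate.py` … `05_knowledge_comparison.py`).
With the committed seed, `02_differential_abundance.py` prints:

```
low-abundance filter: 5000 -> 4950 proteins
empirical-Bayes prior: d0 = 2.73, s0^2 = 0.0401
contrast O19_vs_O1: 74 DE proteins
contrast O19_vs_O1CyA: 63 DE proteins
contrast O1_vs_O1CyA: 46 DE proteins
restored by CyA: 13 proteins
top enriched set for the DE union: PLANTED_MODULE_0 (p = 4.41e-09)
```

74 differential proteins in the hypoxia contrast comprise the 40 planted
persistent effects, the 10 planted restored proteins and part of the
module that carries the module-wide hypoxia shift; the 13 restored calls
recover all 10 planted restored proteins. `04_community_modules.py` then
reports:

```
communities: 50 total, 4 with >= 10 members (sizes [62, 52, 52, 36]), Q = 0.484
reversal test: modules [0, 1] flagged at p <= 0.05
planted CyA-reverted module: 100% of members inside flagged modules
module recovery: ARI = 0.966, within-module edge recall = 1.000
```

i.e. the detected partition recovers the planted modules almost exactly,
and the module carrying the planted CyA-reverted shift is flagged by the
reversal test (it is also the top-enriched module for its own gene set).

A thin CLI wraps the same library: `protcoex simulate`, `protcoex run`,
`protcoex run-from-network`, `protcoex enrich`, `protcoex report`.

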