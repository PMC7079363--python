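# Methods

## Design and model

The experiment is a one-way layout with three conditions (19% O₂, 1% O₂,
1% O₂ + 1 µg/mL CyA) and three replicates each, observed as a wide
protein × sample table of summed TMT reporter intensities. All modeling
happens on the log2 scale; the raw scale is used only by the two filters.

Per protein g the model is

    y_gcs = µ_gc + ε_gcs,   ε ~ N(0, σ²_g)

with condition means µ_gc and a common residual variance per protein.
`fit_condition_means` returns the means and the pooled residual variance
s²_g with d_g = N − k degrees of freedom (d_g = 6 in the full design).

### Variance moderation

`moderate_variances` implements the empirical-Bayes moderated t: the true
variances are assumed to follow a scaled inverse-χ² prior with d₀ df and
scale s₀², under which s²_g is marginally s₀²·F(d_g, d₀). The
hyperparameters are estimated by moment matching on e_g = log s²_g −
ψ(d_g/2) + log(d_g/2):

* Var(e) − ψ′(d_g/2) > 0 → d₀ = 2·ψ′⁻¹(Var(e) − ψ′(d_g/2)),
  s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2));
* otherwise the ensemble is consistent with a single variance: d₀ = ∞ and
  s̃² = s₀² = exp(mean(e)).

ψ′⁻¹ is solved by bisection (brentq) on [1e-8, 1e8] to 1e-12 — the
trigamma function is strictly monotone there, so this is exact and
unconditionally convergent, which we prefer over a bare Newton iteration;
the asymptotic branches 1/√y (y > 1e7) and 1/y (y < 1e-6) avoid needless
iteration. Zero variances (identical replicates) are excluded from the
moment estimation with a warning and are shrunk like any other protein.
The posterior variance is s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g); the
moderated t for contrast A−B is log2FC/√(s̃²(1/n_A + 1/n_B)) with
d₀ + d_g df (normal tail at d₀ = ∞). With moderation disabled (d₀ = 0)
this reduces exactly to the classical pooled two-sample t, which the test
suite verifies against an independent implementation to 1e-10.

### Differential and restored calls

The DE rule is raw p ≤ 0.01 AND |log2FC| ≥ 0.5. No multiplicity
adjustment gates the call — BH-adjusted p-values are included in every
output table for the reader, but the rule itself is the study's stated
raw-p rule. "A_vs_B" means mean(A) − mean(B); the orientation is noted in
the output headers. A protein is *restored* iff DE in O19_vs_O1, DE in
O1_vs_O1CyA, and not DE in O19_vs_O1CyA.

## Filters

* Low abundance: a protein is kept iff every sample value ≥ min_count
  (default 1). The alternative reading (any condition-mean < 1) is
  exposed as `per="condition_mean"`.
* Coefficient of variation: kept iff population sd / mean ≥ 0.01 across
  all nine samples, computed on raw abundances (CV is not scale-free
  after log transform); a `scale="log2"` flag switches if desired. The
  population (n) rather than sample (n−1) sd is used; at the 0.01
  threshold the choice is immaterial but it is fixed for
  reproducibility.

Both filters are monotone in their thresholds, and reports reconcile
counts exactly.

## Permutation-thresholded co-expression network

Edge weights are |Pearson r| between log2 profiles. The permutation null
independently permutes each protein's nine values within its row (a single
shared permutation would leave every correlation unchanged and is
therefore not a null); after each of the 50 iterations all pairwise |r|
are recomputed, and each pair's z-score is (w_obs − mean_perm)/sd_perm
with the sample (n−1) sd. Edges survive iff |z| ≥ 1.5 and w > 0.5
(strict: weight exactly 0.5 is removed); nodes are endpoints of surviving
edges. The computation holds full n×n double matrices (three accumulators
plus the working matrix, ~1.5 GB at n = 5000), which fits a desktop
profile without blocking.

### Small-sample behavior — important caveat

With only 9 samples the null |r| is wide: P(|r| > 0.5) = 2·P(T₇ >
0.5√7/√0.75) ≈ 0.17 for independent proteins. The permutation z-score
adds little for null pairs (the permuted |r| has the same distribution as
the observed one, so |z| ≥ 1.5 is roughly the upper tail the weight
filter already selects), and the acceptance script measures ~10% of
independent pairs surviving the joint filter. Two consequences:

1. the full-scale (5000-protein) network is dominated by chance edges
   (~1.2M), and
2. edge-betweenness community detection, whose cost grows as
   O(|V||E|²), is not tractable on that graph.

The network/module benchmark therefore runs on a 300-protein panel that
contains the complete planted structure (3 modules of 30, 40 DE, 10
restored, filter bait) over a seeded random background; the statistical
operating point (9 samples, thresholds, permutation count) is unchanged.
Tests assert the within-module edge recall (≥ 0.8 at ρ = 0.9) and bound
the between-module survival by its analytic null tail rather than by a
large-n intuition of "almost zero", which does not hold at n = 9.

## Communities and module tests

Girvan–Newman: iteratively remove the edge of maximal betweenness
(recomputed each step) and select, over the removal sequence, the
partition of connected components maximizing Newman–Girvan modularity
Q = Σ_c (e_c/m − (d_c/2m)²) on the original unweighted graph. The default
backend is igraph's C implementation (`community_edge_betweenness` with
the max-modularity cut); a pure-Python reference implementation with a
canonical tie-break (lexicographically smallest edge among betweenness
ties, first modularity maximum wins) is cross-checked against it and
against a brute-force shortest-path-enumeration oracle on small graphs.
Betweenness and modularity are computed unweighted: the literature's
weights-as-distances and weights-as-strengths conventions conflict, and
on a thresholded graph (all weights > 0.5) the unweighted reading is the
conservative one. Modules are reported by decreasing size; only modules
with ≥ 10 members enter enrichment and reversal testing.

The reversal test compares, across a module's members, the median
replicate-wise log2 fold change in O19_vs_O1 against O19_vs_O1CyA with a
two-tailed *paired* t-test (the same proteins appear in both contrasts);
`paired=False` switches to Welch. Zero-variance differences give p = 1
when all differences are zero and an instructive error otherwise.

Known limitation: the paired test treats module members as independent,
but members of a co-expressed module share their latent factor by
construction, so the factor's chance imbalance between conditions acts as
a module-level pseudo-effect (standard deviation ≈ ρ√(2/3) ≈ 0.73 at
ρ = 0.9 with triplicates). Non-reverted co-expressed modules can
therefore also reach p ≤ 0.05, and in an occasional replicate the factor
draw can partially cancel a genuine module-wide δ = 1.2 shift or the
max-modularity cut can merge a module with background nodes and dilute
its signal. The seeded benchmark asserts that the planted CyA-reverted
module's members sit inside flagged modules; it does not assert that the
flagged set contains nothing else, because under this generator that
would be statistically false.

## Enrichment

Hypergeometric over-representation with inclusive upper tail
P(X ≥ k) — identical to the one-sided Fisher exact test, verified exactly
over all 2×2 tables with N ≤ 30. The universe defaults to quantified
proteins intersected with the union of collection members (the
convention of tools that condition on annotated genes); a flag uses all
quantified proteins instead. Set-size guards default to [3, 500] within
the universe. BH adjustment is applied across tested sets; it is
order-preserving (idempotence does not hold for BH in general and is not
asserted).

## Synthetic data generator

log2 abundance: L[g,s] = µ_g + shift_g(cond(s)) + ρ_g f_{m(g)}(s) + ε_gs
with µ_g ~ N(µ₀ = 10, τ = 2) (raw abundances ~10³, log-normal across
proteins, as for summed reporter intensities), ε ~ N(0, σ = 0.25) (raw
CV ≈ 0.17), and a per-sample standard-normal factor f_m shared within
each module, giving expected within-module correlation ρ²/(ρ² + σ²)
(≈ 0.93 at ρ = 0.9). Latent factors rather than explicit covariance
matrices keep generation O(n_proteins × n_samples). Defaults are the
study conditions: 5000 proteins, 3×3 design, 40 DE at δ = 1.2 (half up,
half down, at both 1% O₂ arms), 10 restored (±δ at 1% O₂ only, random
sign), three modules of 30 at ρ = 0.9, 1% low-abundance and 1% low-CV
bait. Module 0 additionally carries a coherent +δ shift at 1% O₂ only
(the module-wide CyA-reverted structure); its members are deliberately
*not* labeled restored — their per-protein variance includes the factor,
so they are individually too noisy for the per-protein restored call,
mirroring the study's observation that the reverted module and the
individually restored proteins are disjoint sets. Low-abundance rows are
shifted so their minimum raw value is 0.5 counts; low-CV rows get noise
sd 0.002 (raw CV ≈ 0.0014). One global seed feeds named SeedSequence
streams (baselines, effects, factors, noise), so enlarging the panel
does not shuffle existing draws; all assignments are deterministic index
blocks.

What the generator does not emulate: peptide-level roll-up, missing
values, TMT ratio compression, and between-sample normalization effects.
Passing the recovery tests shows the statistics behave as designed under
the assumed model, not that real TMT data satisfy those assumptions.

## Benchmark sizes

* Differential/restored recovery and null p-value calibration: full
  5000-protein design (the differential stage is O(n)).
* Null edge-filter survival: 5000 proteins (~12.5M pairs).
* Network + modules + reversal: 300-protein panel (see the small-sample
  caveat above for why edge-betweenness fixes this size).
* Determinism: full pipeline twice at 150 proteins, compared byte for
  byte, including the 50-permutation z-scores.

## Degenerate inputs and tie-breaks

Duplicate identifiers, missing metadata, non-numeric cells, short GMT
lines and unreadable edge-list lines are hard errors naming the
offender; self-loops and duplicate undirected edges are canonicalized
(max weight kept) with warnings. Constant profiles reaching the
correlation step are hard errors (the CV filter prevents them); pairs
with zero permutation sd get z = +∞ or 0 with a warning. Hub ranking
breaks degree ties alphabetically; module ids order by size then
smallest member; enrichment results sort by (p, set name) for
deterministic output.
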