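"""Synthetic TMT-style abundance data with planted ground truth.

The generator emulates a 3-condition x 3-replicate experiment (19% O2,
1% O2, 1% O2 + CyA) with log-normal raw abundances. On the log2 scale the
abundance of protein g in sample s is

    L[g, s] = mu_g + shift_g(condition(s)) + rho_g * f_{m(g)}(s) + eps[g, s]

with per-protein baseline mu_g ~ Normal(mu0, tau), i.i.d. noise
eps ~ Normal(0, sigma_g), and a per-sample standard-normal latent factor
f_m shared by the members of module m (loading rho_g), which induces an
expected within-module correlation of rho^2 / (rho^2 + sigma^2). Raw
abundances are 2**L.

Planted structure:

* differential proteins carry a shift of +-delta at both 1% O2 conditions
  (a hypoxia response untouched by CyA),
* restored proteins carry +-delta at 1% O2 only (a hypoxia response
  abolished by CyA),
* one designated module (the "reversal module") additionally carries a
  coherent +delta shift at 1% O2 only across all of its members, so its
  fold-change distribution reverts under CyA at the module level even
  though individual members are too noisy (their variance includes the
  latent factor) to be called restored one by one — mirroring the study
  design, where the restored module and the individually restored
  proteins were disjoint,
* low-abundance proteins are shifted so that at least one sample falls
  below one count, and low-CV proteins get near-zero noise, exercising
  the two filters.

One global seed drives named RNG streams (baselines, effects, factors,
noise) so that enlarging the protein panel does not shuffle existing
draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from protcoex.io import RAW, AbundanceMatrix, GeneSetCollection

LABELS = ("null", "de_up", "de_down", "restored", "low_abundance", "low_cv")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic experiment (defaults = study conditions)."""

    n_proteins: int = 5000
    conditions: Sequence[str] = ("O19", "O1", "O1_CyA")
    replicates: int = 3
    mu0: float = 10.0          # baseline mean log2 abundance (~1000 raw counts)
    tau: float = 2.0           # between-protein sd of the baseline
    sigma: float = 0.25        # within-protein log2 noise sd
    de_fraction: float = 0.008     # 40 differential proteins at n=5000
    delta: float = 1.2             # planted |log2FC|
    restored_fraction: float = 0.002   # 10 restored proteins at n=5000
    modules: Sequence[tuple[int, float]] = ((30, 0.9), (30, 0.9), (30, 0.9))
    reversal_module: int | None = 0    # index into ``modules``; None disables
    low_abundance_fraction: float = 0.01
    low_cv_fraction: float = 0.01
    low_cv_sigma: float = 0.002
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_proteins < 1 or self.replicates < 2:
            raise ValueError("need n_proteins >= 1 and replicates >= 2")
        for frac in (self.de_fraction, self.restored_fraction,
                     self.low_abundance_fraction, self.low_cv_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.sigma, self.tau, self.delta) < 0:
            raise ValueError("sigma, tau and delta must be non-negative")
        for size, rho in self.modules:
            if size < 1 or rho <= 0:
                raise ValueError("module sizes must be >= 1 and loadings > 0")
        n_special = (self.n_module_proteins + self.n_de + self.n_restored
                     + self.n_low_abundance + self.n_low_cv)
        if n_special > self.n_proteins:
            raise ValueError(
                f"planted structure needs {n_special} proteins but only "
                f"{self.n_proteins} are generated"
            )
        if self.reversal_module is not None and self.modules:
            if not 0 <= self.reversal_module < len(self.modules):
                raise ValueError("reversal_module must index into modules")

    @property
    def n_de(self) -> int:
        return round(self.de_fraction * self.n_proteins)

    @property
    def n_restored(self) -> int:
        return round(self.restored_fraction * self.n_proteins)

    @property
    def n_low_abundance(self) -> int:
        return round(self.low_abundance_fraction * self.n_proteins)

    @property
    def n_low_cv(self) -> int:
        return round(self.low_cv_fraction * self.n_proteins)

    @property
    def n_module_proteins(self) -> int:
        return sum(size for size, _ in self.modules)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["modules"] = [list(m) for m in self.modules]
        return d


@dataclass
class SyntheticTruth:
    """Planted labels, module membership and realized effects."""

    labels: pd.Series                      # protein -> label in LABELS
    module_of: dict[str, int]              # protein -> planted module index
    reversal_module: int | None
    effects: pd.DataFrame                  # proteins x conditions: planted shifts
    config: GeneratorConfig

    @property
    def de_proteins(self) -> set[str]:
        return set(self.labels.index[self.labels.isin(["de_up", "de_down"])])

    @property
    def restored_proteins(self) -> set[str]:
        return set(self.labels.index[self.labels == "restored"])

    def module_members(self, module: int) -> list[str]:
        return sorted(p for p, m in self.module_of.items() if m == module)

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels.to_dict(),
            "module_of": self.module_of,
            "reversal_module": self.reversal_module,
            "effects": {p: row.to_dict() for p, row in self.effects.iterrows()},
            "config": self.config.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("baselines", "effects", "factors", "noise")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def generate(config: GeneratorConfig) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Draw one synthetic raw abundance matrix plus its ground truth."""
    rngs = _streams(config.seed)
    n = config.n_proteins
    proteins = [f"P{i:05d}" for i in range(1, n + 1)]
    samples = [f"{c}_r{r}" for c in config.conditions for r in range(1, config.replicates + 1)]
    sample_cond = np.array([c for c in config.conditions for _ in range(config.replicates)])
    meta = pd.DataFrame(
        {
            "condition": sample_cond,
            "replicate": [r for _ in config.conditions for r in range(1, config.replicates + 1)],
        },
        index=pd.Index(samples, name="sample"),
    )

    # --- deterministic label/module assignment by index blocks ---
    labels = np.array(["null"] * n, dtype=object)
    module_of_idx = np.full(n, -1)
    cursor = 0
    for m, (size, _rho) in enumerate(config.modules):
        module_of_idx[cursor : cursor + size] = m
        cursor += size
    de_idx = np.arange(cursor, cursor + config.n_de)
    labels[de_idx[: len(de_idx) // 2]] = "de_up"
    labels[de_idx[len(de_idx) // 2 :]] = "de_down"
    cursor += config.n_de
    restored_idx = np.arange(cursor, cursor + config.n_restored)
    labels[restored_idx] = "restored"
    cursor += config.n_restored
    low_ab_idx = np.arange(cursor, cursor + config.n_low_abundance)
    labels[low_ab_idx] = "low_abundance"
    cursor += config.n_low_abundance
    low_cv_idx = np.arange(cursor, cursor + config.n_low_cv)
    labels[low_cv_idx] = "low_cv"

    # --- planted condition shifts ---
    cond_index = {c: i for i, c in enumerate(config.conditions)}
    o1 = cond_index.get("O1")
    o1_cya = cond_index.get("O1_CyA")
    shifts = np.zeros((n, len(config.conditions)))
    sign_rng = rngs["effects"]
    for i in de_idx:
        sign = 1.0 if labels[i] == "de_up" else -1.0
        if o1 is not None:
            shifts[i, o1] = sign * config.delta
        if o1_cya is not None:
            shifts[i, o1_cya] = sign * config.delta
    restored_signs = np.where(sign_rng.random(len(restored_idx)) < 0.5, -1.0, 1.0)
    for i, sign in zip(restored_idx, restored_signs):
        if o1 is not None:
            shifts[i, o1] = sign * config.delta
    if config.reversal_module is not None and config.modules and o1 is not None:
        members = module_of_idx == config.reversal_module
        shifts[members, o1] += config.delta

    # --- assemble log2 values ---
    mu = config.mu0 + config.tau * rngs["baselines"].standard_normal(n)
    factors = rngs["factors"].standard_normal((max(len(config.modules), 1), len(samples)))
    sigma_g = np.full(n, config.sigma)
    sigma_g[low_cv_idx] = config.low_cv_sigma
    eps = rngs["noise"].standard_normal((n, len(samples))) * sigma_g[:, None]
    cond_of_sample = np.array([cond_index[c] for c in sample_cond])
    L = mu[:, None] + shifts[:, cond_of_sample] + eps
    in_module = module_of_idx >= 0
    if in_module.any():
        loadings = np.zeros(n)
        for m, (_size, rho) in enumerate(config.modules):
            loadings[module_of_idx == m] = rho
        L[in_module] += loadings[in_module, None] * factors[module_of_idx[in_module]]
    # low-abundance proteins: shift each row so its minimum raw value is 0.5
    if len(low_ab_idx):
        row_min = L[low_ab_idx].min(axis=1)
        L[low_ab_idx] -= (row_min - math.log2(0.5))[:, None]

    values = pd.DataFrame(2.0 ** L, index=pd.Index(proteins, name="protein"), columns=samples)
    matrix = AbundanceMatrix(values=values, sample_meta=meta, scale=RAW)
    truth = SyntheticTruth(
        labels=pd.Series(labels, index=proteins, name="label"),
        module_of={proteins[i]: int(module_of_idx[i]) for i in range(n) if module_of_idx[i] >= 0},
        reversal_module=config.reversal_module if config.modules else None,
        effects=pd.DataFrame(shifts, index=proteins, columns=list(config.conditions)),
        config=config,
    )
    return matrix, truth


def make_gene_sets(
    truth: SyntheticTruth,
    n_decoy_sets: int = 20,
    decoy_size: int = 25,
    seed: int = 0,
) -> GeneSetCollection:
    """A synthetic gene-set collection: one set per planted module + decoys.

    Decoy sets are drawn uniformly from the generated proteins. Useful for
    exercising enrichment end to end without external annotation files.
    """
    rng = np.random.default_rng(seed)
    proteins = [p.upper() for p in truth.labels.index]
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    modules = sorted({m for m in truth.module_of.values()})
    for m in modules:
        members = frozenset(p.upper() for p in truth.module_members(m))
        sets[f"PLANTED_MODULE_{m}"] = members
        descriptions[f"PLANTED_MODULE_{m}"] = f"synthetic: planted co-expression module {m}"
    for d in range(n_decoy_sets):
        members = frozenset(rng.choice(proteins, size=min(decoy_size, len(proteins)),
                                       replace=False).tolist())
        sets[f"DECOY_{d:03d}"] = members
        descriptions[f"DECOY_{d:03d}"] = "synthetic: random decoy set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def make_knowledge_table(
    truth: SyntheticTruth,
    within_module_score: float = 0.9,
    n_decoy_edges: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """A synthetic curated interaction table plus its pathway gene list.

    Within-module edges get a high confidence score; decoy edges between
    random proteins get scores uniform in [0, 1]. Stands in for a frozen
    interaction-database export in demonstrations and tests.
    """
    rng = np.random.default_rng(seed)
    proteins = [p.upper() for p in truth.labels.index]
    rows = []
    genes: set[str] = set()
    for m in sorted({m for m in truth.module_of.values()}):
        members = [p.upper() for p in truth.module_members(m)]
        genes.update(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < 0.3:
                    rows.append((members[i], members[j], within_module_score))
    for _ in range(n_decoy_edges):
        u, v = rng.choice(proteins, size=2, replace=False)
        genes.update((u, v))
        rows.append((u, v, float(rng.random())))
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    return table, sorted(genes)


def evaluate_recovery(
    truth: SyntheticTruth,
    de_called: Iterable[str] | None = None,
    restored_called: Iterable[str] | None = None,
    partition: dict[str, int] | None = None,
    network=None,
) -> dict:
    """Recovery metrics of pipeline outputs against the planted truth.

    * DE precision/recall of ``de_called`` against the de_up/de_down labels,
      plus the false-positive rate among unplanted (label ``null``,
      module-free) proteins;
    * restored precision/recall of ``restored_called``;
    * adjusted Rand index between the planted and detected partitions,
      restricted to planted-module members (members without a detected
      assignment count as singletons);
    * fraction of within-module protein pairs present as network edges.

    Precision is reported as NaN when nothing was called.
    """
    out: dict = {}

    def prf(called: set[str], positives: set[str], background: set[str], prefix: str):
        tp = len(called & positives)
        out[f"{prefix}_recall"] = tp / len(positives) if positives else float("nan")
        out[f"{prefix}_precision"] = tp / len(called) if called else float("nan")
        fp_pool = called & background
        out[f"{prefix}_fp_rate"] = len(fp_pool) / len(background) if background else float("nan")

    unplanted = set(truth.labels.index[truth.labels == "null"]) - set(truth.module_of)
    if de_called is not None:
        prf(set(de_called), truth.de_proteins, unplanted, "de")
    if restored_called is not None:
        prf(set(restored_called), truth.restored_proteins, unplanted, "restored")
    if partition is not None:
        from sklearn.metrics import adjusted_rand_score

        members = sorted(truth.module_of)
        planted = [truth.module_of[p] for p in members]
        detected = []
        next_singleton = -1
        for p in members:
            if p in partition:
                detected.append(partition[p])
            else:
                detected.append(next_singleton)
                next_singleton -= 1
        out["module_ari"] = float(adjusted_rand_score(planted, detected)) if members else float("nan")
    if network is not None:
        graph = network.graph if hasattr(network, "graph") else network
        hits = total = 0
        by_module: dict[int, list[str]] = {}
        for p, m in truth.module_of.items():
            by_module.setdefault(m, []).append(p)
        for members_m in by_module.values():
            for i in range(len(members_m)):
                for j in range(i + 1, len(members_m)):
                    total += 1
                    if graph.has_edge(members_m[i], members_m[j]):
                        hits += 1
        out["within_module_edge_recall"] = hits / total if total else float("nan")
    return out
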