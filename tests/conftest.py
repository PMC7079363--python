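"""Shared fixtures: tiny handmade matrices and seeded synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from protcoex import GeneratorConfig, generate
from protcoex.io import RAW, AbundanceMatrix


def build_matrix(values: np.ndarray, scale: str = RAW, conditions=("O19", "O1", "O1_CyA"),
                 replicates: int = 3, protein_prefix: str = "P") -> AbundanceMatrix:
    """Wrap an array (proteins x len(conditions)*replicates) as an AbundanceMatrix."""
    n_prot, n_samp = values.shape
    assert n_samp == len(conditions) * replicates
    samples = [f"{c}_r{r}" for c in conditions for r in range(1, replicates + 1)]
    meta = pd.DataFrame(
        {
            "condition": [c for c in conditions for _ in range(replicates)],
            "replicate": [r for _ in conditions for r in range(1, replicates + 1)],
        },
        index=pd.Index(samples, name="sample"),
    )
    df = pd.DataFrame(
        values,
        index=[f"{protein_prefix}{i + 1}" for i in range(n_prot)],
        columns=samples,
    )
    return AbundanceMatrix(values=df, sample_meta=meta, scale=scale)


@pytest.fixture
def tiny_matrix() -> AbundanceMatrix:
    rng = np.random.default_rng(0)
    return build_matrix(rng.uniform(2.0, 100.0, size=(3, 9)))


@pytest.fixture(scope="session")
def small_synthetic():
    """300-protein dataset with the full planted structure (40 DE, 10
    restored, 3 modules of 30 incl. the reversal module, 10 low-abundance,
    10 low-CV)."""
    config = GeneratorConfig(
        n_proteins=300,
        de_fraction=40 / 300,
        restored_fraction=10 / 300,
        low_abundance_fraction=10 / 300,
        low_cv_fraction=10 / 300,
        seed=7,
    )
    matrix, truth = generate(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def small_network_modules(small_synthetic):
    """Thresholded co-expression network and detected modules for the
    300-protein dataset (Girvan-Newman is the expensive step; share it)."""
    from protcoex import (
        cv_filter,
        filter_low_abundance,
        girvan_newman,
        log2_transform,
        pairwise_abs_pearson,
        permutation_zscores,
        threshold_network,
    )

    _, matrix, _ = small_synthetic
    filtered, _ = filter_low_abundance(matrix)
    cvm, _ = cv_filter(filtered)
    net_in = log2_transform(cvm)
    ids, W = pairwise_abs_pearson(net_in)
    _, Z = permutation_zscores(net_in, n_perm=50, seed=23)
    net = threshold_network(ids, W, Z)
    moduleset = girvan_newman(net)
    return log2_transform(filtered), net, moduleset


def small_pipeline_config(outdir, seed: int = 77):
    from protcoex.pipeline import PipelineConfig

    return PipelineConfig(seed=seed, outdir=str(outdir))


def small_pipeline_inputs(seed: int = 77):
    """150-protein generator config plus sidecar inputs for pipeline runs."""
    from protcoex.simulate import make_gene_sets, make_knowledge_table

    config = GeneratorConfig(
        n_proteins=150,
        de_fraction=20 / 150,
        restored_fraction=5 / 150,
        modules=((15, 0.9), (15, 0.9)),
        reversal_module=0,
        low_abundance_fraction=5 / 150,
        low_cv_fraction=5 / 150,
        seed=seed,
    )
    matrix, truth = generate(config)
    collection = make_gene_sets(truth, seed=seed)
    knowledge_table, pathway_genes = make_knowledge_table(truth, seed=seed)
    return matrix, truth, collection, knowledge_table, pathway_genes


@pytest.fixture(scope="session")
def pipeline_paired_runs(tmp_path_factory):
    """The same 150-protein pipeline executed twice with identical config."""
    from protcoex.pipeline import PipelineConfig, run_pipeline

    matrix, truth, collection, knowledge_table, pathway_genes = small_pipeline_inputs()
    outs = []
    for label in ("run_a", "run_b"):
        outdir = tmp_path_factory.mktemp(label)
        config = PipelineConfig(seed=123, outdir=str(outdir))
        report = run_pipeline(
            config,
            matrix=matrix,
            collection=collection,
            knowledge_table=knowledge_table,
            pathway_genes=pathway_genes,
        )
        outs.append((outdir, report))
    return outs, truth


@pytest.fixture(scope="session")
def null_pvalues_5000():
    """Moderated p-values of the hypoxia contrast on a 5000-protein pure-null
    dataset (no planted effects, no modules), shared across tests."""
    from protcoex import (
        compute_contrast,
        filter_low_abundance,
        fit_condition_means,
        log2_transform,
        moderate_variances,
    )

    config = GeneratorConfig(
        n_proteins=5000,
        de_fraction=0.0,
        restored_fraction=0.0,
        modules=(),
        reversal_module=None,
        low_abundance_fraction=0.0,
        low_cv_fraction=0.0,
        seed=20260928,
    )
    matrix, _ = generate(config)
    filtered, _ = filter_low_abundance(matrix)
    mfit = moderate_variances(fit_condition_means(log2_transform(filtered)))
    return compute_contrast(mfit, "O19_vs_O1").table["p"].to_numpy()
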