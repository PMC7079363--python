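"""Protein filters and the log2 transform that define the analysis universe.

Two filters precede all downstream statistics:

* a low-abundance filter (a protein must reach at least ``min_count``
  summed reporter counts in every sample), applied before differential
  analysis, and
* a coefficient-of-variation filter (sd/mean across all samples must be at
  least ``min_cv``), applied to the raw abundances before the
  co-expression network so that near-constant proteins cannot contribute
  spurious correlations.

CV uses the population standard deviation (denominator n). The choice is
immaterial at the default threshold of 0.01 but is fixed here for
reproducibility; a ``scale`` flag allows computing CV on log2 values
instead of raw ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from protcoex.io import LOG2, RAW, AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Accounting for one filtering step; counts always reconcile exactly."""

    n_input: int
    n_removed_low_abundance: int = 0
    n_removed_low_cv: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed_low_abundance - self.n_removed_low_cv

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_low_abundance": self.n_removed_low_abundance,
            "n_removed_low_cv": self.n_removed_low_cv,
            "n_output": self.n_output,
            "thresholds": dict(self.thresholds),
        }


def filter_low_abundance(
    matrix: AbundanceMatrix, min_count: float = 1.0, per: str = "sample"
) -> tuple[AbundanceMatrix, FilterReport]:
    """Drop proteins with fewer than ``min_count`` counts per sample.

    ``per="sample"`` (default) drops a protein if ANY sample value falls
    below ``min_count``; ``per="condition_mean"`` drops it if any
    condition's mean does. Raw-scale input required.
    """
    if matrix.scale != RAW:
        raise ValueError("filter_low_abundance requires raw-scale abundances")
    if min_count < 0:
        raise ValueError("min_count must be non-negative")
    vals = matrix.values
    if per == "sample":
        keep = (vals >= min_count).all(axis=1)
    elif per == "condition_mean":
        cond = matrix.sample_meta.loc[list(vals.columns), "condition"]
        means = vals.T.groupby(cond.to_numpy()).mean().T
        keep = (means >= min_count).all(axis=1)
    else:
        raise ValueError(f"per must be 'sample' or 'condition_mean', got {per!r}")
    out = AbundanceMatrix(vals.loc[keep], matrix.sample_meta, RAW)
    report = FilterReport(
        n_input=len(vals),
        n_removed_low_abundance=int((~keep).sum()),
        thresholds={"min_count": min_count, "per": per},
    )
    logger.info(
        "low-abundance filter: %d -> %d proteins (min_count=%g per %s)",
        report.n_input,
        report.n_output,
        min_count,
        per,
    )
    return out, report


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Return the matrix with values replaced by log2(raw)."""
    if matrix.scale != RAW:
        raise ValueError("matrix is already on the log2 scale")
    arr = matrix.values.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError(
            "log2 transform requires strictly positive abundances; apply "
            "filter_low_abundance (min_count >= 1) first"
        )
    return AbundanceMatrix(
        pd.DataFrame(np.log2(arr), index=matrix.values.index, columns=matrix.values.columns),
        matrix.sample_meta,
        LOG2,
    )


def cv_filter(
    matrix: AbundanceMatrix, min_cv: float = 0.01, scale: str = RAW
) -> tuple[AbundanceMatrix, FilterReport]:
    """Retain proteins with coefficient of variation >= ``min_cv``.

    CV = population sd / mean across ALL samples, computed on the raw
    abundances by default (``scale="log2"`` switches to log2 values). A
    zero-mean protein has undefined CV and is removed with a warning.
    """
    if matrix.scale != RAW:
        raise ValueError("cv_filter expects a raw-scale matrix")
    if scale == RAW:
        arr = matrix.values.to_numpy(dtype=float)
    elif scale == LOG2:
        arr = np.log2(matrix.values.to_numpy(dtype=float))
    else:
        raise ValueError(f"scale must be 'raw' or 'log2', got {scale!r}")
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=0)
    zero_mean = mean == 0
    if zero_mean.any():
        logger.warning("%d protein(s) with zero mean removed (CV undefined)", zero_mean.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(zero_mean, np.nan, sd / np.abs(mean))
    keep = ~zero_mean & (cv >= min_cv)
    out = AbundanceMatrix(matrix.values.loc[keep], matrix.sample_meta, RAW)
    report = FilterReport(
        n_input=len(matrix.values),
        n_removed_low_cv=int((~keep).sum()),
        thresholds={"min_cv": min_cv, "scale": scale},
    )
    logger.info(
        "CV filter: %d -> %d proteins (min_cv=%g on %s scale)",
        report.n_input,
        report.n_output,
        min_cv,
        scale,
    )
    return out, report


def qq_normality_check(matrix: AbundanceMatrix, outdir=None) -> pd.DataFrame:
    """Per-sample Shapiro-Wilk normality diagnostics on log2 abundances.

    Returns a DataFrame (sample, statistic, p) and, if ``outdir`` is given,
    writes one quantile-quantile plot per sample there. Advisory only: this
    never filters anything.
    """
    if matrix.scale != LOG2:
        raise ValueError("qq_normality_check expects log2-scale values")
    if len(matrix.values) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 proteins per sample")
    rows = []
    for sample in matrix.sample_ids:
        x = matrix.values[sample].to_numpy(dtype=float)
        # Shapiro-Wilk is exact only up to n=5000; subsample deterministically beyond
        if len(x) > 5000:
            x = x[:: int(np.ceil(len(x) / 5000))]
        stat, p = stats.shapiro(x)
        rows.append({"sample": sample, "statistic": float(stat), "p": float(p)})
        if outdir is not None:
            _write_qq_plot(x, sample, outdir)
    return pd.DataFrame(rows).set_index("sample")


def _write_qq_plot(x: np.ndarray, sample: str, outdir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    fig, ax = plt.subplots(figsize=(4, 4))
    stats.probplot(x, dist="norm", plot=ax)
    ax.set_title(f"QQ plot, {sample}")
    path = Path(outdir) / f"qq_{sample}.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
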