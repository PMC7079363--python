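"""Per-protein linear models and empirical-Bayes moderated t-statistics.

The model is a one-way layout on log2 abundances: each protein g gets a
mean per condition and a pooled residual variance s_g^2 with
d_g = N - k degrees of freedom. Variance moderation follows the standard
empirical-Bayes derivation for the moderated t: the marginal distribution
of s_g^2 under a scaled inverse-chi-square prior on the true variances is
a scaled F, so the prior degrees of freedom d0 and prior variance s0^2 are
recovered by matching the mean and variance of log s_g^2 to the log
scaled-F distribution via digamma/trigamma inversion. The posterior
variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces s_g^2 in the t-statistic, which then has d0 + d_g degrees of
freedom (a normal reference when d0 is infinite).

A contrast "A_vs_B" is mean(A) - mean(B) on the log2 scale, so a positive
log2 fold change means higher abundance in A.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from protcoex.io import LOG2, AbundanceMatrix

logger = logging.getLogger(__name__)

#: The pairwise contrasts of the three-condition design. Keys accept the
#: compact spelling without the inner underscore ("O1CyA" == "O1_CyA").
CANONICAL_CONTRASTS = ("O19_vs_O1", "O19_vs_O1CyA", "O1_vs_O1CyA")

_CONDITION_ALIASES = {"O19": "O19", "O1": "O1", "O1CYA": "O1_CyA", "O1_CYA": "O1_CyA"}


def parse_contrast(name: str, conditions: list[str]) -> tuple[str, str]:
    """Resolve a contrast name "A_vs_B" to a pair of known conditions."""
    if "_vs_" not in name:
        raise ValueError(f"contrast {name!r} is not of the form 'A_vs_B'")
    left, right = name.split("_vs_", 1)

    def resolve(token: str) -> str:
        if token in conditions:
            return token
        alias = _CONDITION_ALIASES.get(token.upper())
        if alias is not None and alias in conditions:
            return alias
        raise ValueError(f"unknown condition {token!r} in contrast {name!r}; "
                         f"known conditions: {conditions}")

    return resolve(left), resolve(right)


@dataclass
class ModelFit:
    """One-way-layout fit: condition means and pooled residual variances."""

    means: pd.DataFrame          # proteins x conditions, log2 scale
    s2: pd.Series                # pooled residual variance per protein
    df_resid: int                # N - k, shared by all proteins
    n_per_condition: dict[str, int]

    def __post_init__(self) -> None:
        if self.df_resid <= 0:
            raise ValueError("residual degrees of freedom must be positive")
        if (self.s2 < 0).any():
            raise ValueError("residual variances must be non-negative")


@dataclass
class ModeratedFit:
    """A :class:`ModelFit` with shrunken (posterior) variances."""

    fit: ModelFit
    d0: float                    # prior degrees of freedom, may be +inf
    s0_sq: float                 # prior variance
    s2_post: pd.Series           # posterior variances

    @property
    def df_total(self) -> float:
        return self.d0 + self.fit.df_resid


@dataclass
class ContrastResult:
    """Per-protein log2FC, moderated t and p for one named contrast."""

    name: str
    table: pd.DataFrame          # columns: log2fc, t, p, p_adj

    def __post_init__(self) -> None:
        required = {"log2fc", "t", "p"}
        if not required <= set(self.table.columns):
            raise ValueError(f"contrast table needs columns {sorted(required)}")


def fit_condition_means(matrix: AbundanceMatrix) -> ModelFit:
    """Fit condition means and the pooled residual variance per protein."""
    if matrix.scale != LOG2:
        raise ValueError("fit_condition_means expects log2-scale values")
    conditions = matrix.conditions
    n_per = {c: len(matrix.samples_for(c)) for c in conditions}
    for c, n in n_per.items():
        if n < 2:
            raise ValueError(f"condition {c!r} has {n} replicate(s); need >= 2")
    n_total = sum(n_per.values())
    df_resid = n_total - len(conditions)
    means = pd.DataFrame(index=matrix.values.index, dtype=float)
    rss = np.zeros(len(matrix.values))
    for c in conditions:
        block = matrix.values[matrix.samples_for(c)].to_numpy(dtype=float)
        mu = block.mean(axis=1)
        means[c] = mu
        rss += ((block - mu[:, None]) ** 2).sum(axis=1)
    s2 = pd.Series(rss / df_resid, index=matrix.values.index, name="s2")
    return ModelFit(means=means, s2=s2, df_resid=df_resid, n_per_condition=n_per)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is monotone decreasing)."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    f = lambda x: float(special.polygamma(1, x)) - y
    lo, hi = 1e-8, 1e8
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12, maxiter=200))


def moderate_variances(fit: ModelFit, skip: bool = False) -> ModeratedFit:
    """Estimate (d0, s0^2) by moment matching and shrink the variances.

    With ``skip=True`` (the d0 = 0 limit) the fit is returned unmoderated.
    If the variance of log s_g^2 is no larger than its expected sampling
    variance, the prior is effectively degenerate: d0 = +inf and every
    posterior variance equals s0^2.
    """
    s2 = fit.s2.to_numpy(dtype=float)
    if skip:
        return ModeratedFit(fit=fit, d0=0.0, s0_sq=float("nan"), s2_post=fit.s2.copy())
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all residual variances are zero; data are degenerate")
    if positive.size < s2.size:
        logger.warning(
            "%d protein(s) with zero residual variance excluded from prior estimation",
            s2.size - positive.size,
        )
    d = float(fit.df_resid)
    # e_g = log s_g^2 corrected for the chi-square sampling bias
    e = np.log(positive) - special.digamma(d / 2.0) + math.log(d / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0)) if n > 1 else 0.0
    if evar > 0:
        try:
            d0 = 2.0 * trigamma_inverse(evar)
            s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
        except (ValueError, RuntimeError):
            logger.warning("prior estimation did not converge; falling back to d0 = +inf")
            d0, s0_sq = math.inf, math.exp(emean)
    else:
        d0, s0_sq = math.inf, math.exp(emean)
    if math.isinf(d0):
        s2_post = pd.Series(s0_sq, index=fit.s2.index)
    else:
        s2_post = pd.Series((d0 * s0_sq + d * s2) / (d0 + d), index=fit.s2.index)
    return ModeratedFit(fit=fit, d0=d0, s0_sq=s0_sq, s2_post=s2_post)


def compute_contrast(mfit: ModeratedFit, contrast: str) -> ContrastResult:
    """Moderated t-test of one pairwise contrast A_vs_B.

    log2FC = mean(A) - mean(B); t = log2FC / sqrt(s~^2 (1/n_A + 1/n_B));
    the p-value is the two-sided tail of Student's t with d0 + d_g degrees
    of freedom (normal tail when d0 is infinite). Benjamini-Hochberg
    adjusted p-values across proteins are included for transparency; the
    differential call itself uses raw p (see :func:`call_de`).
    """
    fit = mfit.fit
    cond_a, cond_b = parse_contrast(contrast, list(fit.means.columns))
    n_a, n_b = fit.n_per_condition[cond_a], fit.n_per_condition[cond_b]
    lfc = fit.means[cond_a] - fit.means[cond_b]
    se = np.sqrt(mfit.s2_post.to_numpy() * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc.to_numpy() / se, np.where(lfc.to_numpy() == 0, 0.0, np.inf))
    if math.isinf(mfit.df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=mfit.df_total)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    from statsmodels.stats.multitest import multipletests

    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2fc": lfc, "t": t, "p": p, "p_adj": p_adj}, index=fit.means.index
    )
    return ContrastResult(name=contrast, table=table)


def call_de(
    result: ContrastResult, p_max: float = 0.01, lfc_min: float = 0.5
) -> set[str]:
    """Differential proteins: raw p <= p_max AND |log2FC| >= lfc_min.

    The rule deliberately uses unadjusted p-values; BH-adjusted values are
    carried in the table for the reader but do not gate the call.
    """
    if p_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    t = result.table
    mask = (t["p"] <= p_max) & (t["log2fc"].abs() >= lfc_min)
    return set(t.index[mask])


def classify_restored(
    results: dict[str, ContrastResult],
    p_max: float = 0.01,
    lfc_min: float = 0.5,
) -> set[str]:
    """Proteins whose hypoxia response is reverted by cyclosporine A.

    A protein is "restored" iff it is differential in O19_vs_O1 AND in
    O1_vs_O1CyA but NOT in O19_vs_O1CyA: its abundance at 1% O2 under CyA
    returns to a level indistinguishable from 19% O2.
    """
    needed = set(CANONICAL_CONTRASTS)
    if set(results) != needed:
        raise ValueError(f"need exactly the contrasts {sorted(needed)}, got {sorted(results)}")
    de = {name: call_de(res, p_max=p_max, lfc_min=lfc_min) for name, res in results.items()}
    return (de["O19_vs_O1"] & de["O1_vs_O1CyA"]) - de["O19_vs_O1CyA"]
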