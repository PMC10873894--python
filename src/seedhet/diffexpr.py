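"""Rank-based differential expression between seed groups.

Per gene: a two-sided Wilcoxon rank-sum test on normalized expression plus a
log2 fold change of de-logged group means, BH correction over all genes
tested in the comparison, and a significance call requiring both
adjusted p < alpha and |log2FC| strictly above the threshold.
"""

from __future__ import annotations

import logging
import math
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .config import Config
from .datatypes import NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)

#: largest combined sample size for which the exact null distribution is used
EXACT_MAX_N = 12


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the combined sample size is at most
    ``EXACT_MAX_N`` and there are no ties; otherwise the normal approximation
    with midranks, tie-corrected variance and continuity correction.  Returns
    the rank-sum statistic W of the first sample and the p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    if a.size + b.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        if a.size + b.size <= EXACT_MAX_N:
            logger.debug("ties present at n+m=%d: falling back to approximation", a.size + b.size)
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U1 -> rank sum of a
    return w, float(res.pvalue)


def log2_fold_change(
    nm: NormalizedMatrix,
    genes: Sequence[str],
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 0.1,
) -> pd.Series:
    """log2((mean_A + c) / (mean_B + c)) of de-logged normalized expression."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    expr = np.expm1(nm.values.loc[:, list(genes)])
    mean_a = expr.loc[group_a].mean(axis=0)
    mean_b = expr.loc[group_b].mean(axis=0)
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount)).rename("log2fc")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_genes(
    nm: NormalizedMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    cfg: Config = Config(),
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two seed groups.

    Returns a DataFrame indexed by gene with columns log2fc, p_value,
    p_adjusted and significant.  Groups smaller than 3 seeds are allowed but
    flagged low-power (``result.attrs["low_power"]``).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    low_power = min(len(group_a), len(group_b)) < 3
    if low_power:
        logger.warning(
            "group sizes %d vs %d: results are low-power", len(group_a), len(group_b)
        )
    xa = nm.values.loc[group_a].to_numpy(dtype=float)
    xb = nm.values.loc[group_b].to_numpy(dtype=float)
    n = len(group_a) + len(group_b)
    if n <= EXACT_MAX_N:
        pvals = np.array(
            [wilcoxon_rank_sum(xa[:, j], xb[:, j])[1] for j in range(xa.shape[1])]
        )
    else:
        res = scipy.stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic", axis=0)
        pvals = np.asarray(res.pvalue, dtype=float)
    lfc = log2_fold_change(nm, nm.gene_ids, group_a, group_b, cfg.pseudocount_fc)
    padj = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "log2fc": lfc.to_numpy(),
            "p_value": pvals,
            "p_adjusted": padj,
            "significant": (padj < cfg.de_alpha) & (np.abs(lfc.to_numpy()) > cfg.de_lfc_threshold),
        },
        index=nm.gene_ids,
    )
    out.attrs["low_power"] = low_power
    return out


def monotone_fraction(
    nm: NormalizedMatrix,
    genes: Sequence[str],
    ordered_groups: Sequence[Sequence[str]],
) -> float:
    """Fraction of genes whose group means are weakly monotone along the order.

    ``ordered_groups`` is a sequence of seed-id groups, e.g. small, medium,
    large; the gradient check counts genes whose means never reverse
    direction through the intermediate group(s).
    """
    if len(ordered_groups) < 3:
        raise ValidationError("need at least 3 ordered groups")
    genes = list(genes)
    if not genes:
        raise ValidationError("empty gene list")
    means = []
    for group in ordered_groups:
        group = list(group)
        if not group:
            raise ValidationError("a group is absent/empty")
        means.append(nm.values.loc[group, genes].mean(axis=0).to_numpy())
    arr = np.vstack(means)  # groups x genes
    diffs = np.diff(arr, axis=0)
    mono = (diffs >= 0).all(axis=0) | (diffs <= 0).all(axis=0)
    return float(mono.mean())


def set_overlap(a, b) -> Tuple[int, int, int]:
    """(|a only|, |a and b|, |b only|) — Venn partition counts."""
    a, b = set(a), set(b)
    inter = a & b
    return len(a - inter), len(inter), len(b - inter)
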