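"""Seed-level QC, gene filters, depth normalization, gene scaling and PCA.

Two gene filters mirror the study design: genes averaging fewer than one raw
read per seed are dropped, and genes whose raw counts track the per-seed
intergenic read totals (Pearson r strictly above the threshold, within any
single condition) are treated as contamination-driven and dropped.  Both
filters work on raw counts, so their removal sets are independent of each
other and of normalization.

Normalization is log1p counts-per-``scale`` (default 10,000):
``ln(1 + count / total_genic * scale)`` — deterministic and library-size
invariant.
"""

from __future__ import annotations

import logging
from typing import List, Tuple

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)


def seed_qc_metrics(m: CountMatrix) -> pd.DataFrame:
    """Per-seed totals, detected genes and intergenic fraction.

    Seeds with zero reads overall (genic + intergenic) get an undefined (NaN)
    fraction and are flagged.
    """
    total = m.counts.sum(axis=1)
    detected = (m.counts > 0).sum(axis=1)
    denom = total + m.intergenic
    flagged = denom == 0
    if flagged.any():
        logger.warning("%d seed(s) have zero total reads; fraction undefined", int(flagged.sum()))
    frac = np.where(denom > 0, m.intergenic / denom.where(denom > 0, 1), np.nan)
    return pd.DataFrame(
        {
            "total_genic_reads": total,
            "detected_genes": detected,
            "intergenic_fraction": frac,
            "flagged": flagged,
        },
        index=m.seed_ids,
    )


def filter_low_expressed(m: CountMatrix, threshold: float = 1.0) -> Tuple[CountMatrix, List[str]]:
    """Remove genes with mean raw count across all seeds strictly below ``threshold``.

    A gene averaging exactly the threshold is retained (the cutoff is
    "fewer than", not "at most").  Retained gene order is preserved.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    means = m.counts.mean(axis=0)
    removed = list(m.gene_ids[means < threshold])
    kept = m.gene_ids[~(means < threshold)]
    return m.subset_genes(kept), removed


def intergenic_correlations(m: CountMatrix) -> pd.DataFrame:
    """Per-condition Pearson r between each gene's raw counts and intergenic totals.

    Zero-variance genes (or a zero-variance intergenic vector) within a
    condition cannot correlate and get r = 0 there.
    """
    out = {}
    for cond in pd.unique(m.condition):
        mask = (m.condition == cond).to_numpy()
        if mask.sum() < 3:
            raise ValidationError(f"condition {cond!r} has fewer than 3 seeds")
        x = m.counts.to_numpy(dtype=float)[mask]
        y = m.intergenic.to_numpy(dtype=float)[mask]
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        xn = np.sqrt((xc**2).sum(axis=0))
        yn = np.sqrt((yc**2).sum())
        zero = xn == 0
        if zero.any():
            logger.info(
                "condition %s: %d zero-variance gene(s), r set to 0", cond, int(zero.sum())
            )
        denom = np.where(zero, 1.0, xn) * (yn if yn > 0 else 1.0)
        r = (xc * yc[:, None]).sum(axis=0) / denom
        r[zero] = 0.0
        if yn == 0:
            logger.info("condition %s: intergenic counts constant, all r set to 0", cond)
            r[:] = 0.0
        out[cond] = r
    return pd.DataFrame(out, index=m.gene_ids)


def filter_intergenic_correlated(
    m: CountMatrix, threshold: float = 0.3
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Remove genes correlated with intergenic reads in *any* condition.

    Returns the filtered matrix and a table of per-condition r values for the
    removed genes.  The comparison is strict: r exactly at the threshold is
    retained.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    r = intergenic_correlations(m)
    removed_mask = (r > threshold).any(axis=1)
    removed = r.loc[removed_mask]
    kept = m.gene_ids[~removed_mask.to_numpy()]
    return m.subset_genes(kept), removed


def normalize_counts(m: CountMatrix, scale: float = 10000.0) -> NormalizedMatrix:
    """log1p counts-per-``scale``: ``ln(1 + count / total_genic * scale)``."""
    totals = m.counts.sum(axis=1).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = list(m.seed_ids[totals == 0])
        raise ValidationError(
            f"seeds with zero genic total: {bad[:5]}... — exclude them during QC first"
        )
    values = np.log1p(m.counts.to_numpy(dtype=float) / totals[:, None] * scale)
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=m.seed_ids, columns=m.gene_ids),
        scale=scale,
        method_tag=f"log1p_cp{scale:g}",
    )


def scale_genes(nm: NormalizedMatrix) -> pd.DataFrame:
    """Per-gene z-score across seeds; zero-variance genes map to all zeros."""
    if nm.values.shape[0] < 2:
        raise ValidationError("scaling needs at least 2 seeds")
    x = nm.values.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = sd == 0
    z = (x - mu) / np.where(zero, 1.0, sd)
    z[:, zero] = 0.0
    return pd.DataFrame(z, index=nm.seed_ids, columns=nm.gene_ids)


def pca(values: pd.DataFrame, n_components: int = 2) -> Tuple[pd.DataFrame, np.ndarray]:
    """Centered-SVD principal components with a deterministic sign convention.

    Returns per-seed coordinates and explained-variance fractions.  Each
    component is oriented so its largest-magnitude gene loading is positive.
    """
    n, p = values.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min(dims)={min(n, p)}")
    x = values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total_var = (xc**2).sum()
    evr = (s**2 / total_var)[:n_components] if total_var > 0 else np.zeros(n_components)
    scores = u[:, :n_components] * s[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            scores[:, k] = -scores[:, k]
            vt[k] = -vt[k]
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return pd.DataFrame(scores, index=values.index, columns=cols), evr
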