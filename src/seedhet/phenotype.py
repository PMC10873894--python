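"""Seed-size computation and phenotype statistics.

Covers the dormancy-phenotype battery: size of germinated vs dormant seeds
(rank-sum on pooled seeds, per-replicate means reported), size by day of
germination (pairwise rank-sum with BH correction, dormant seeds forming
their own class), extreme-size selection from the distribution tails, the
paired t-test on extreme-pool germination percentages, and the pixel-to-mm^2
area conversion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import PhenotypeTable, ValidationError
from .diffexpr import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

#: class label used for non-germinated seeds in day-wise comparisons
DORMANT_CLASS = "dormant"


def seed_area_from_px(area_px_1: float, area_px_2: float, coef_mm_per_px: float) -> float:
    """Seed area in mm^2: mean of two pixel-area measurements times coef^2."""
    if area_px_1 < 0 or area_px_2 < 0:
        raise ValidationError("pixel areas must be non-negative")
    if coef_mm_per_px <= 0:
        raise ValidationError("mm/px coefficient must be positive")
    return (area_px_1 + area_px_2) / 2.0 * coef_mm_per_px**2


@dataclass
class SizeByGermination:
    p_value: float
    statistic: float
    replicate_means: pd.DataFrame  # replicate x {germinated, dormant} mean sizes


def compare_size_by_germination(pt: PhenotypeTable) -> SizeByGermination:
    """Rank-sum test of seed size, germinated vs dormant, pooled across replicates.

    Per-replicate class means are reported alongside (the plotted points);
    the test itself pools seeds from all replicates.
    """
    df = pt.df
    germ = df[df["germinated"]]["area_mm2"].to_numpy()
    dorm = df[~df["germinated"]]["area_mm2"].to_numpy()
    if germ.size == 0 or dorm.size == 0:
        raise ValidationError("both germinated and dormant seeds are required")
    stat, p = wilcoxon_rank_sum(germ, dorm)
    means = (
        df.assign(outcome=np.where(df["germinated"], "germinated", "dormant"))
        .groupby(["replicate", "outcome"], sort=True)["area_mm2"]
        .mean()
        .unstack("outcome")
    )
    return SizeByGermination(p_value=p, statistic=stat, replicate_means=means)


@dataclass
class SizeByDay:
    class_means: pd.Series       # mean size per day class (dormant last)
    pairwise: pd.DataFrame       # class_a, class_b, p_value, p_adjusted
    excluded_classes: List[str]


def size_by_germination_day(pt: PhenotypeTable) -> SizeByDay:
    """Mean size per germination-day class with all pairwise rank-sum tests.

    Non-germinated seeds form their own class.  Classes with fewer than 2
    seeds are excluded (logged).  BH correction is applied over all pairs.
    """
    df = pt.df.copy()
    df["day_class"] = np.where(
        df["germinated"], "day" + df["germination_day"].astype(str), DORMANT_CLASS
    )
    sizes = df.groupby("day_class")["area_mm2"]
    counts = sizes.count()
    excluded = list(counts.index[counts < 2])
    if excluded:
        logger.info("excluding day classes with <2 seeds: %s", excluded)
    keep = [c for c in counts.index if c not in excluded]
    if len(keep) < 2:
        raise ValidationError("need at least 2 day classes with >= 2 seeds")

    def _key(c):  # dormant sorts after numbered days
        return (1, math.inf) if c == DORMANT_CLASS else (0, int(c.removeprefix("day")))

    keep.sort(key=_key)
    groups = {c: df.loc[df["day_class"] == c, "area_mm2"].to_numpy() for c in keep}
    rows = []
    for i, ca in enumerate(keep):
        for cb in keep[i + 1 :]:
            _, p = wilcoxon_rank_sum(groups[ca], groups[cb])
            rows.append({"class_a": ca, "class_b": cb, "p_value": p})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adjusted"] = bh_adjust(pairwise["p_value"].to_numpy())
    means = pd.Series({c: groups[c].mean() for c in keep}, name="mean_area_mm2")
    return SizeByDay(class_means=means, pairwise=pairwise, excluded_classes=excluded)


def select_extremes(pt: PhenotypeTable, fraction: float = 0.10) -> Tuple[List[str], List[str]]:
    """The floor(fraction*n) smallest and largest seeds by area.

    Ties are broken by seed_id for determinism.  The two sets must not
    overlap (error if n < 2k).
    """
    n = pt.n_seeds
    k = int(math.floor(fraction * n))
    if k < 1:
        raise ValidationError(f"fraction {fraction} selects no seeds at n={n}")
    if n < 2 * k:
        raise ValidationError(f"extreme sets would overlap: n={n}, k={k}")
    ordered = pt.df.sort_values(["area_mm2", "seed_id"], kind="mergesort")
    small = list(ordered["seed_id"].iloc[:k])
    large = list(ordered["seed_id"].iloc[-k:])
    return small, large


def paired_t_test(x, y, alternative: str = "two-sided") -> Tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("need equal-length paired samples of size >= 2")
    d = x - y
    if d.std(ddof=1) == 0:
        raise ValidationError("paired differences have zero variance; t undefined")
    res = scipy.stats.ttest_rel(x, y, alternative=alternative)
    return float(res.statistic), x.size - 1, float(res.pvalue)


def germination_percentage(pt: PhenotypeTable) -> float:
    """Percentage of germinated seeds, in [0, 100]."""
    if pt.n_seeds == 0:
        raise ValidationError("empty phenotype subset")
    return 100.0 * float(pt.df["germinated"].mean())


def subset(pt: PhenotypeTable, seed_ids) -> PhenotypeTable:
    """Restrict a phenotype table to the given seed ids."""
    wanted = set(seed_ids)
    return PhenotypeTable(pt.df[pt.df["seed_id"].isin(wanted)].reset_index(drop=True))
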