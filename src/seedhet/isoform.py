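"""Proximal vs distal poly(A) isoform usage from 3'-end coverage.

Reads are counted strand-aware inside two BED-defined half-open windows; the
usage statistic is the proximal/distal count ratio.  Ratios with a zero
denominator are undefined (not infinite) and are excluded from tests with a
logged count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import CoverageTrack, GenomicWindow, ValidationError

logger = logging.getLogger(__name__)


def count_window_reads(track: CoverageTrack, window: GenomicWindow) -> int:
    """Number of 3'-end positions p on the window's strand with start <= p < end."""
    if track.chrom != window.chrom:
        raise ValidationError(
            f"track chromosome {track.chrom!r} does not match window {window.chrom!r}"
        )
    mask = (
        (track.positions >= window.start)
        & (track.positions < window.end)
        & (track.strands == window.strand)
    )
    return int(mask.sum())


def isoform_ratio(proximal_count: int, distal_count: int) -> float:
    """proximal/distal; NaN (undefined) when the denominator is zero."""
    if proximal_count < 0 or distal_count < 0:
        raise ValidationError("counts must be non-negative")
    if distal_count == 0:
        if proximal_count > 0:
            logger.info("distal count 0 with proximal %d: ratio undefined", proximal_count)
        return math.nan
    return proximal_count / distal_count


def proximal_fraction(ratio: float) -> float:
    """Proximal site-usage fraction implied by a proximal/distal ratio r.

    p = r / (1 + r); with exact window counts this equals
    proximal / (proximal + distal).  NaN propagates for undefined ratios.
    """
    if math.isnan(ratio):
        return math.nan
    if ratio < 0:
        raise ValidationError("ratio must be non-negative")
    return ratio / (1.0 + ratio)


@dataclass
class RatioComparison:
    """Small-vs-large ratio comparison with the per-replicate ratio table."""

    table: pd.DataFrame          # class_label, replicate, ratio (defined only)
    test: str                    # "paired t-test" or "wilcoxon"
    statistic: float
    p_value: float
    n_excluded: int


def compare_ratios(
    ratios: pd.DataFrame,
    small_label: str = "small",
    large_label: str = "large",
) -> RatioComparison:
    """Compare isoform ratios between the small and large classes.

    ``ratios`` needs columns class_label, replicate, ratio.  Undefined (NaN)
    ratios are excluded and counted.  When both classes cover exactly the
    same replicates, a two-sided paired t-test on per-replicate pairs is
    used; otherwise a two-sided Wilcoxon rank-sum test.  Zero-variance paired
    differences yield p = 1 (no evidence either way).
    """
    required = {"class_label", "replicate", "ratio"}
    if missing := required - set(ratios.columns):
        raise ValidationError(f"ratio table missing columns {sorted(missing)}")
    defined = ratios.dropna(subset=["ratio"]).copy()
    n_excluded = len(ratios) - len(defined)
    if n_excluded:
        logger.info("excluded %d undefined ratio(s)", n_excluded)
    for label in (small_label, large_label):
        n = (defined["class_label"] == label).sum()
        if n == 0:
            raise ValidationError(f"all ratios undefined in class {label!r}")
        if n < 2:
            raise ValidationError(f"class {label!r} has fewer than 2 defined ratios")
    small = defined[defined["class_label"] == small_label].set_index("replicate")["ratio"]
    large = defined[defined["class_label"] == large_label].set_index("replicate")["ratio"]
    paired = set(small.index) == set(large.index) and small.index.is_unique and large.index.is_unique
    if paired:
        reps = sorted(small.index)
        diffs = small.loc[reps].to_numpy() - large.loc[reps].to_numpy()
        if np.allclose(diffs.std(ddof=1), 0):
            return RatioComparison(defined, "paired t-test", 0.0, 1.0, n_excluded)
        res = scipy.stats.ttest_rel(small.loc[reps], large.loc[reps])
        return RatioComparison(defined, "paired t-test", float(res.statistic), float(res.pvalue), n_excluded)
    from .diffexpr import wilcoxon_rank_sum

    stat, p = wilcoxon_rank_sum(small.to_numpy(), large.to_numpy())
    return RatioComparison(defined, "wilcoxon", stat, p, n_excluded)
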