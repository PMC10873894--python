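"""Co-expression module discovery and composite per-seed signatures.

Modules are connected components of the graph whose edges join gene pairs
with Pearson correlation strictly above the threshold (default 0.5) across
single seeds.  A module score is the per-seed mean of normalized expression
over its genes; the germination-competence index contrasts the
germination-associated module against the dormancy-associated one, and the
seed-size signature contrasts genes up in large seeds against genes up in
small seeds (higher = more large-seed-like).
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import GeneModule, NormalizedMatrix, SignatureScores, ValidationError

logger = logging.getLogger(__name__)


def gene_correlation(nm: NormalizedMatrix, genes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Gene x gene Pearson correlation across seeds.

    Zero-variance genes are an error (exclude them first): they have no
    defined correlation.
    """
    values = nm.values if genes is None else nm.values.loc[:, list(genes)]
    if values.shape[0] < 3:
        raise ValidationError("need at least 3 seeds")
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = list(values.columns[sd == 0])
        raise ValidationError(f"zero-variance gene(s): {bad[:5]}")
    corr = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=values.columns, columns=values.columns)


def correlation_graph_modules(
    corr: pd.DataFrame, threshold: float = 0.5, min_size: int = 10
) -> List[GeneModule]:
    """Connected components of the r > threshold graph, largest first.

    Components smaller than ``min_size`` are dropped.  Labels are
    "cluster 1", "cluster 2", ... by descending size, ties broken by the
    lexicographically smallest member gene id.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    genes = corr.index
    r = corr.to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    hit = r[iu] > threshold  # strict
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    graph.add_edges_from(
        (genes[i], genes[j]) for i, j in zip(iu[0][hit], iu[1][hit])
    )
    comps = [c for c in nx.connected_components(graph) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [GeneModule(label=f"cluster {k + 1}", genes=frozenset(c)) for k, c in enumerate(comps)]


def module_score(nm: NormalizedMatrix, module: GeneModule) -> SignatureScores:
    """Per-seed mean normalized expression over the module's genes."""
    genes = sorted(module.genes)
    missing = set(genes) - set(nm.gene_ids)
    if missing:
        raise ValidationError(f"module {module.label}: genes missing from matrix: {sorted(missing)[:5]}")
    scores = nm.values.loc[:, genes].mean(axis=1)
    return SignatureScores(scores=scores, definition=f"mean({module.label}; {len(genes)} genes)")


def germination_index(
    nm: NormalizedMatrix, module_up: GeneModule, module_down: GeneModule
) -> SignatureScores:
    """Germination-competence index: score(up module) - score(down module).

    Higher values place a seed closer to germination.
    """
    if module_up.genes & module_down.genes:
        raise ValidationError("modules overlap")
    up = module_score(nm, module_up)
    down = module_score(nm, module_down)
    return SignatureScores(
        scores=up.scores - down.scores,
        definition=f"{module_up.label}(+) - {module_down.label}(-)",
    )


def size_signature(
    nm: NormalizedMatrix, up_in_small: Iterable[str], up_in_large: Iterable[str]
) -> SignatureScores:
    """Seed-size signature: mean(up-in-large) - mean(up-in-small).

    Built from a small-vs-large DE gene split; higher = transcriptionally
    more similar to large seeds.
    """
    up_in_small, up_in_large = set(up_in_small), set(up_in_large)
    if not up_in_small or not up_in_large:
        raise ValidationError("both gene sets must be non-empty")
    if up_in_small & up_in_large:
        raise ValidationError("gene sets overlap")
    large = nm.values.loc[:, sorted(up_in_large)].mean(axis=1)
    small = nm.values.loc[:, sorted(up_in_small)].mean(axis=1)
    return SignatureScores(
        scores=large - small,
        definition=f"mean({len(up_in_large)} up-in-large) - mean({len(up_in_small)} up-in-small)",
    )


def signature_correlation(s1: SignatureScores, s2: SignatureScores) -> Tuple[float, float]:
    """Pearson r between two per-seed signatures, with its t-distribution p-value."""
    if not s1.seed_ids.equals(s2.seed_ids):
        raise ValidationError("signatures must cover the same seeds in the same order")
    if len(s1.scores) < 3:
        raise ValidationError("need at least 3 seeds")
    res = scipy.stats.pearsonr(s1.scores.to_numpy(), s2.scores.to_numpy())
    return float(res.statistic), float(res.pvalue)


def orient_modules(
    nm: NormalizedMatrix,
    modules: Sequence[GeneModule],
    condition: pd.Series,
    condition_order: Sequence[str],
) -> Tuple[GeneModule, GeneModule]:
    """Assign germination (up) vs dormancy (down) roles to the two main modules.

    Seeds recovering from dormancy induction advance toward germination, so
    the module whose mean score rises more from the first to the last
    condition in ``condition_order`` is the germination-associated one.  With
    fewer than two conditions the label order is kept, with a warning.
    """
    if len(modules) < 2:
        raise ValidationError("need at least two modules to orient")
    m1, m2 = modules[0], modules[1]
    conds = [c for c in condition_order if (condition == c).any()]
    if len(conds) < 2:
        logger.warning("fewer than 2 conditions present; keeping module label order")
        return m1, m2
    first, last = conds[0], conds[-1]
    deltas = []
    for mod in (m1, m2):
        s = module_score(nm, mod).scores
        deltas.append(s[condition == last].mean() - s[condition == first].mean())
    return (m1, m2) if deltas[0] >= deltas[1] else (m2, m1)
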