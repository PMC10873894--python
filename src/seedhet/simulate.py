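"""Synthetic single-seed experiments with planted ground truth.

The generator emulates the statistical structure of a secondary-dormancy
single-seed 3' RNA-seq study: per condition 96 seeds in 3 pools of 32, a
latent germination-competence axis ``g`` on which two anti-correlated gene
modules load (+lambda / -lambda), a seed-size covariate ``z`` coupled to the
axis at correlation ``rho``, per-seed intergenic contamination that can leak
into a planted gene set, a "comet tail" subpopulation shifted along the axis
in the recovery condition, and a two-window proximal/distal poly(A) locus.

Counts are Poisson (negative binomial when ``dispersion > 0``):

    x_ij ~ Poisson(L_i * beta_j * exp(load_j * g_i))
    intergenic_i ~ Poisson(f * L_i)
    contaminated j: x_ij += Poisson(kappa * intergenic_i)

Same seed, same outputs, bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import (
    CountMatrix,
    CoverageTrack,
    GenomicWindow,
    PhenotypeTable,
    ValidationError,
)


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Count-matrix generator settings (defaults are the study conditions)."""

    n_seeds: int = 96                  # per condition, split into pools
    n_pools: int = 3                   # pools of 32 seeds each
    conditions: Tuple[str, ...] = ("3d", "7d24h")
    condition_means: Tuple[float, ...] = (0.0, 0.5)
    n_genes: int = 2000
    module_size: int = 50              # each of the two planted modules
    lam: float = 0.8                   # module loading +-lambda on the axis
    rho: float = 0.6                   # corr(size covariate z, axis g)
    intergenic_rate: float = 0.05      # f: intergenic reads per genic library unit
    kappa: float = 0.0                 # contamination leak-through per intergenic read
    n_contaminated: int = 0
    dispersion: float = 0.0            # NB dispersion; 0 = Poisson
    tail_fraction: float = 0.25        # comet tail share of the tail condition
    tail_shift: float = 2.0
    tail_condition: str = "7d24h"
    selection_quantile: float = 0.10   # sequenced seeds are pre-selected from the
                                       # size-distribution tails (0.5 = no selection,
                                       # small/large then split at the median)
    mean_library_size: float = 10000.0
    library_size_sigma: float = 0.0    # lognormal sd of genic library size
    baseline_sigma: float = 1.0        # lognormal spread of per-gene baselines
    planted_min_mean: float = 2.5      # planted gene sets drawn from genes with
                                       # expected count >= this (regulons are expressed)


@dataclass(frozen=True)
class PhenoSimConfig:
    """Phenotype generator settings.

    Sizes are Normal(0.11, 0.015) mm^2 truncated at zero — a plausible scale
    for Arabidopsis dry seeds.  Germination probability follows
    logistic(a + b z) on the standardized size z; day-of-germination is
    1 + geometric with success probability logistic(c0 + c1 z), capped at the
    scoring horizon, so larger seeds germinate earlier.
    """

    n_seeds: int = 500
    n_replicates: int = 4
    size_mean_mm2: float = 0.11
    size_sd_mm2: float = 0.015
    germ_intercept: float = 0.0        # a: ~50% germination at the mean size
    germ_slope: float = 2.0            # b: planted size -> germination link
    day_intercept: float = 0.4
    day_slope: float = 0.5
    max_day: int = 7


@dataclass(frozen=True)
class LocusSimConfig:
    """Two-isoform locus generator settings (synthetic window coordinates)."""

    depth: int = 1000                  # N total 3'-end reads
    p_prox: float = 0.7
    chrom: str = "chr5"
    strand: str = "+"
    proximal: Tuple[int, int] = (1000, 1400)
    distal: Tuple[int, int] = (1600, 2000)


@dataclass
class SimTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    g: Optional[pd.Series] = None                # latent germination axis
    z: Optional[pd.Series] = None                # standardized size covariate
    module_up: Optional[frozenset] = None        # +lambda loadings
    module_down: Optional[frozenset] = None      # -lambda loadings
    lam: Optional[float] = None
    rho: Optional[float] = None
    contaminated_genes: Optional[frozenset] = None
    kappa: Optional[float] = None
    intergenic_rate: Optional[float] = None
    baseline_expr: Optional[pd.Series] = None    # beta_j
    library_size: Optional[pd.Series] = None     # L_i
    tail_seeds: Optional[frozenset] = None
    tail_shift: Optional[float] = None
    size_mm2: Optional[pd.Series] = None
    germ_prob: Optional[pd.Series] = None
    p_prox: Optional[float] = None
    locus_depth: Optional[int] = None
    proximal_count: Optional[int] = None


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_experiment(cfg: SimConfig = SimConfig(), rng_seed: int = 0) -> Tuple[CountMatrix, SimTruth]:
    """Generate a single-seed count matrix with planted modules and coupling.

    Seeds are labelled ``{condition}_p{pool}_s{idx}``.  Mirroring the
    sequencing design, the seeds of each condition are pre-selected from the
    two tails of the size distribution (``selection_quantile`` per side) and
    ``class_label`` records the side; at quantile 0.5 no selection happens
    and labels come from a median split.
    """
    if 2 * cfg.module_size + cfg.n_contaminated > cfg.n_genes:
        raise SimulationError("module and contaminated gene sets exceed n_genes")
    if len(cfg.conditions) != len(cfg.condition_means):
        raise SimulationError("conditions and condition_means lengths differ")
    if cfg.n_seeds % cfg.n_pools:
        raise SimulationError("n_seeds must divide evenly into pools")
    rng = np.random.default_rng(rng_seed)

    n_digits = len(str(cfg.n_genes - 1))
    genes = pd.Index([f"g{j:0{n_digits}d}" for j in range(cfg.n_genes)], name="gene_id")

    # per-gene baselines: lognormal composition summing to 1
    beta = rng.lognormal(mean=math.log(1.0 / cfg.n_genes), sigma=cfg.baseline_sigma, size=cfg.n_genes)
    beta = beta / beta.sum()

    # planted sets (modules, contamination targets) live among genes expressed
    # well enough to survive QC, as their real counterparts do
    n_special = 2 * cfg.module_size + cfg.n_contaminated
    eligible = np.flatnonzero(cfg.mean_library_size * beta >= cfg.planted_min_mean)
    if len(eligible) < n_special:
        raise SimulationError(
            f"only {len(eligible)} genes exceed planted_min_mean; need {n_special}"
        )
    special = rng.choice(eligible, size=n_special, replace=False)
    module_up = frozenset(genes[special[: cfg.module_size]])
    module_down = frozenset(genes[special[cfg.module_size : 2 * cfg.module_size]])
    contaminated = frozenset(genes[special[2 * cfg.module_size :]])

    loadings = np.zeros(cfg.n_genes)
    loadings[np.isin(genes, list(module_up))] = cfg.lam
    loadings[np.isin(genes, list(module_down))] = -cfg.lam

    def _draw_size_coupled(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eps1, z, label) for n seeds, emulating the sequencing design:
        seeds pre-selected from the two tails of the size distribution."""
        q = cfg.selection_quantile
        if not 0 < q <= 0.5:
            raise SimulationError("selection_quantile must lie in (0, 0.5]")
        root = math.sqrt(1.0 - cfg.rho**2)
        if q >= 0.5:  # no selection: median split of the pool
            eps1 = rng.standard_normal(n)
            z = cfg.rho * eps1 + root * rng.standard_normal(n)
            label = np.where(z > np.median(z), "large", "small")
            return eps1, z, label
        z_cut = float(scipy.stats.norm.ppf(q))
        n_small = n // 2
        halves = {}
        for side, want in (("small", n_small), ("large", n - n_small)):
            kept_e, kept_z = [], []
            got = 0
            while got < want:
                e1 = rng.standard_normal(max(256, int(want / q)))
                zz = cfg.rho * e1 + root * rng.standard_normal(len(e1))
                keep = zz <= z_cut if side == "small" else zz >= -z_cut
                kept_e.append(e1[keep])
                kept_z.append(zz[keep])
                got += int(keep.sum())
            halves[side] = (
                np.concatenate(kept_e)[:want],
                np.concatenate(kept_z)[:want],
            )
        # interleave small/large so pools stay balanced
        eps1 = np.empty(n)
        z = np.empty(n)
        label = np.empty(n, dtype=object)
        # large leads the alternation so odd n gives floor(n/2) smalls
        sides = np.array(["large", "small"] * ((n + 1) // 2))[:n]
        for side in ("small", "large"):
            idx = np.flatnonzero(sides == side)
            eps1[idx], z[idx] = halves[side]
            label[idx] = side
        return eps1, z, label

    seed_ids, g_all, z_all, cond_all, label_all, tail_ids = [], [], [], [], [], []
    pool_size = cfg.n_seeds // cfg.n_pools
    for cond, mu in zip(cfg.conditions, cfg.condition_means):
        eps1, z, label = _draw_size_coupled(cfg.n_seeds)
        g = mu + eps1
        ids = [
            f"{cond}_p{i // pool_size + 1}_s{i % pool_size:02d}" for i in range(cfg.n_seeds)
        ]
        if cond == cfg.tail_condition and cfg.tail_fraction > 0:
            n_tail = int(round(cfg.tail_fraction * cfg.n_seeds))
            tail_idx = rng.choice(cfg.n_seeds, size=n_tail, replace=False)
            g[tail_idx] += cfg.tail_shift
            tail_ids.extend(ids[i] for i in tail_idx)
        seed_ids.extend(ids)
        g_all.append(g)
        z_all.append(z)
        label_all.append(label)
        cond_all.extend([cond] * cfg.n_seeds)
    idx = pd.Index(seed_ids, name="seed_id")
    g = pd.Series(np.concatenate(g_all), index=idx, name="g")
    z = pd.Series(np.concatenate(z_all), index=idx, name="z")
    condition = pd.Series(cond_all, index=idx, name="condition")
    label = pd.Series(np.concatenate(label_all), index=idx, name="class_label")

    if cfg.library_size_sigma > 0:
        library = rng.lognormal(
            mean=math.log(cfg.mean_library_size) - cfg.library_size_sigma**2 / 2.0,
            sigma=cfg.library_size_sigma,
            size=len(idx),
        )
    else:
        library = np.full(len(idx), cfg.mean_library_size)
    rates = library[:, None] * beta[None, :] * np.exp(np.outer(g.to_numpy(), np.ones(cfg.n_genes)) * loadings[None, :])
    if cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        rates = rates * rng.gamma(shape=shape, scale=1.0 / shape, size=rates.shape)
    counts = rng.poisson(rates)
    intergenic = rng.poisson(cfg.intergenic_rate * library)
    if contaminated and cfg.kappa > 0:
        cols = np.isin(genes, list(contaminated))
        counts[:, cols] += rng.poisson(
            cfg.kappa * intergenic[:, None], size=(len(idx), int(cols.sum()))
        )

    matrix = CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64), index=idx, columns=genes),
        intergenic=pd.Series(intergenic.astype(np.int64), index=idx, name="intergenic"),
        condition=condition,
        class_label=label,
    )
    truth = SimTruth(
        g=g,
        z=z,
        module_up=module_up,
        module_down=module_down,
        lam=cfg.lam,
        rho=cfg.rho,
        contaminated_genes=contaminated,
        kappa=cfg.kappa,
        intergenic_rate=cfg.intergenic_rate,
        baseline_expr=pd.Series(beta, index=genes, name="beta"),
        library_size=pd.Series(library, index=idx, name="library_size"),
        tail_seeds=frozenset(tail_ids),
        tail_shift=cfg.tail_shift,
    )
    return matrix, truth


def simulate_phenotypes(
    cfg: PhenoSimConfig = PhenoSimConfig(), rng_seed: int = 0
) -> Tuple[PhenotypeTable, SimTruth]:
    """Generate a per-seed phenotype table with a size -> germination link."""
    if cfg.size_sd_mm2 <= 0:
        raise SimulationError("size_sd_mm2 must be > 0")
    if cfg.n_seeds < cfg.n_replicates:
        raise SimulationError("need at least one seed per replicate")
    rng = np.random.default_rng(rng_seed)
    n = cfg.n_seeds
    size = cfg.size_mean_mm2 + cfg.size_sd_mm2 * rng.standard_normal(n)
    while (size <= 0).any():  # truncate at zero (essentially never at defaults)
        bad = size <= 0
        size[bad] = cfg.size_mean_mm2 + cfg.size_sd_mm2 * rng.standard_normal(int(bad.sum()))
    z = (size - cfg.size_mean_mm2) / cfg.size_sd_mm2
    p_germ = _logistic(cfg.germ_intercept + cfg.germ_slope * z)
    germinated = rng.random(n) < p_germ
    p_day = _logistic(cfg.day_intercept + cfg.day_slope * z)
    day = np.minimum(rng.geometric(p_day), cfg.max_day)
    idx = pd.Index([f"seed{i:04d}" for i in range(n)], name="seed_id")
    replicate = [f"R{i % cfg.n_replicates + 1}" for i in range(n)]
    df = pd.DataFrame(
        {
            "seed_id": idx,
            "area_mm2": size,
            "germinated": germinated,
            "germination_day": pd.array(
                [int(d) if ok else None for d, ok in zip(day, germinated)], dtype="Int64"
            ),
            "replicate": replicate,
        }
    )
    truth = SimTruth(
        z=pd.Series(z, index=idx, name="z"),
        size_mm2=pd.Series(size, index=idx, name="size_mm2"),
        germ_prob=pd.Series(p_germ, index=idx, name="germ_prob"),
    )
    return PhenotypeTable(df), truth


def simulate_locus_reads(
    cfg: LocusSimConfig = LocusSimConfig(), rng_seed: int = 0
) -> Tuple[CoverageTrack, Tuple[GenomicWindow, GenomicWindow], SimTruth]:
    """Generate 3'-end reads for a two-isoform locus.

    The proximal window receives Binomial(N, p_prox) reads; the remainder
    fall in the distal window.  Positions are uniform within each window.
    """
    if not 0.0 <= cfg.p_prox <= 1.0:
        raise SimulationError("p_prox must lie in [0, 1]")
    prox = GenomicWindow(cfg.chrom, *cfg.proximal, cfg.strand, "proximal")
    dist = GenomicWindow(cfg.chrom, *cfg.distal, cfg.strand, "distal")
    if prox.overlaps(dist):
        raise SimulationError("proximal and distal windows overlap")
    rng = np.random.default_rng(rng_seed)
    n_prox = int(rng.binomial(cfg.depth, cfg.p_prox)) if cfg.depth else 0
    pos_prox = rng.integers(prox.start, prox.end, size=n_prox)
    pos_dist = rng.integers(dist.start, dist.end, size=cfg.depth - n_prox)
    positions = np.concatenate([pos_prox, pos_dist])
    track = CoverageTrack(
        chrom=cfg.chrom,
        positions=positions,
        strands=np.asarray([cfg.strand] * len(positions), dtype=object),
    )
    truth = SimTruth(p_prox=cfg.p_prox, locus_depth=cfg.depth, proximal_count=n_prox)
    return track, (prox, dist), truth
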