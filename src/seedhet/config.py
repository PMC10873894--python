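"""Pipeline configuration.

Thresholds default to the values used throughout the analysis: genes with a
mean of <1 read per seed are discarded, genes whose raw counts correlate with
per-seed intergenic reads at Pearson r > 0.3 in any condition are treated as
contamination-driven, co-expression edges require r > 0.5, and differential
expression calls require BH-adjusted p < 0.05 together with
|log2 fold change| > log2(1.2).  All inequalities are strict, exactly as the
thresholds are written.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range configuration values."""


@dataclass(frozen=True)
class Config:
    """Tunable thresholds for the single-seed analysis pipeline.

    Attributes
    ----------
    min_mean_reads_per_seed
        Genes with mean raw count across seeds strictly below this are removed.
    intergenic_corr_threshold
        Genes with Pearson r strictly above this against per-seed intergenic
        counts in any condition are removed.
    coexpr_corr_threshold
        Minimum (strict) pairwise Pearson correlation for a co-expression edge.
    min_module_size
        Smallest connected component reported as a gene module.
    de_alpha
        BH-adjusted p-value cutoff (strict) for differential expression.
    de_lfc_threshold
        Minimum (strict) absolute log2 fold change for a DE call.
    extreme_fraction
        Fraction of the size distribution taken from each tail when selecting
        extreme seeds.
    norm_scale
        Counts-per-``norm_scale`` library-size normalization target.
    pseudocount_fc
        Pseudocount added to both group means before the fold-change ratio.
    rng_seed
        Seed for every stochastic stage of a pipeline run.
    """

    min_mean_reads_per_seed: float = 1.0
    intergenic_corr_threshold: float = 0.3
    coexpr_corr_threshold: float = 0.5
    min_module_size: int = 10
    de_alpha: float = 0.05
    de_lfc_threshold: float = math.log2(1.2)
    extreme_fraction: float = 0.10
    norm_scale: float = 10000.0
    pseudocount_fc: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "min_mean_reads_per_seed",
            "intergenic_corr_threshold",
            "coexpr_corr_threshold",
            "de_lfc_threshold",
            "norm_scale",
            "pseudocount_fc",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.min_module_size < 1:
            raise ConfigError(f"min_module_size must be >= 1, got {self.min_module_size}")
        if not 0.0 < self.de_alpha < 1.0:
            raise ConfigError(f"de_alpha must lie in (0, 1), got {self.de_alpha}")
        if not 0.0 < self.extreme_fraction <= 0.5:
            raise ConfigError(
                f"extreme_fraction must lie in (0, 0.5], got {self.extreme_fraction}"
            )


_FIELD_NAMES = {f.name for f in dataclasses.fields(Config)}
_INT_FIELDS = {"min_module_size", "rng_seed"}


def load_config(path: str | Path) -> Config:
    """Load a YAML config, applying defaults for absent keys.

    Unknown keys are rejected rather than ignored so that typos do not
    silently fall back to defaults.  The effective configuration is echoed to
    the log.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a YAML mapping")
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    coerced = {}
    for key, value in raw.items():
        try:
            coerced[key] = int(value) if key in _INT_FIELDS else float(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config key {key!r}: cannot coerce {value!r}") from exc
    cfg = Config(**coerced)
    logger.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg
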