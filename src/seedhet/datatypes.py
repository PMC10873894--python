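"""Domain containers shared by all pipeline stages.

Counts are seeds x genes non-negative integers with a per-seed intergenic
read total and a condition label for every seed.  Genomic coordinates are
0-based half-open throughout (BED-native).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An object violates a structural invariant."""


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


@dataclass
class CountMatrix:
    """UMI counts for single seeds.

    ``counts`` is a seeds x genes integer DataFrame; ``intergenic`` and
    ``condition`` are per-seed Series aligned to its index.  ``class_label``
    optionally carries a second grouping (e.g. small/medium/large or
    genotype).
    """

    counts: pd.DataFrame
    intergenic: pd.Series
    condition: pd.Series
    class_label: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def seed_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_seeds(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")
        if not self.counts.index.is_unique or not self.counts.columns.is_unique:
            raise ValidationError("seed and gene ids must be unique")
        for name, series in (("intergenic", self.intergenic), ("condition", self.condition)):
            if not series.index.equals(self.counts.index):
                raise ValidationError(f"{name} index does not match seed ids")
        ig = self.intergenic.to_numpy()
        if not np.issubdtype(ig.dtype, np.integer):
            if not np.all(np.equal(np.mod(ig, 1), 0)):
                raise ValidationError("intergenic counts must be integers")
            self.intergenic = self.intergenic.astype(np.int64)
            ig = self.intergenic.to_numpy()
        if (ig < 0).any():
            raise ValidationError("intergenic counts must be non-negative")
        if self.condition.isna().any():
            raise ValidationError("condition must be defined for every seed")
        if self.class_label is not None and not self.class_label.index.equals(self.counts.index):
            raise ValidationError("class_label index does not match seed ids")

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[:, list(genes)],
            intergenic=self.intergenic,
            condition=self.condition,
            class_label=self.class_label,
        )

    def subset_seeds(self, seeds) -> "CountMatrix":
        seeds = list(seeds)
        return CountMatrix(
            counts=self.counts.loc[seeds],
            intergenic=self.intergenic.loc[seeds],
            condition=self.condition.loc[seeds],
            class_label=None if self.class_label is None else self.class_label.loc[seeds],
        )


@dataclass
class NormalizedMatrix:
    """Depth-normalized expression (seeds x genes reals)."""

    values: pd.DataFrame
    scale: float
    method_tag: str = "log1p_cp"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("normalized values must be finite")
        if self.method_tag.startswith("log1p") and (arr < 0).any():
            raise ValidationError("log1p-normalized values must be non-negative")

    @property
    def seed_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.columns


#: phenotype table column order on disk
PHENO_COLUMNS = ["seed_id", "area_mm2", "germinated", "germination_day", "replicate", "class_label"]


@dataclass
class PhenotypeTable:
    """Per-seed morphology and germination outcome.

    Columns: seed_id (unique), area_mm2 (> 0), germinated (bool),
    germination_day (int >= 1, only for germinated seeds), replicate,
    optional class_label.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = {"seed_id", "area_mm2", "germinated", "replicate"} - set(df.columns)
        if missing:
            raise ValidationError(f"phenotype table missing columns {sorted(missing)}")
        if "germination_day" not in df.columns:
            df = df.assign(germination_day=pd.NA)
        if "class_label" not in df.columns:
            df = df.assign(class_label=pd.NA)
        if not df["seed_id"].is_unique:
            raise ValidationError("seed_id values must be unique")
        area = df["area_mm2"].to_numpy(dtype=float)
        if not np.isfinite(area).all() or (area <= 0).any():
            raise ValidationError("area_mm2 must be finite and positive")
        day = df["germination_day"]
        germ = df["germinated"].astype(bool)
        has_day = day.notna()
        if (has_day & ~germ).any():
            raise ValidationError("germination_day set for a non-germinated seed")
        if has_day.any():
            dvals = day[has_day].astype(float)
            if (dvals < 1).any() or not np.all(np.equal(np.mod(dvals, 1), 0)):
                raise ValidationError("germination_day must be an integer >= 1")
        self.df = df.reset_index(drop=True)

    @property
    def n_seeds(self) -> int:
        return len(self.df)


_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class GenomicWindow:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    label: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"window {self.label}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(f"window {self.label}: strand must be + or -")

    def overlaps(self, other: "GenomicWindow") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class CoverageTrack:
    """3'-end read positions on one chromosome (0-based), with strands."""

    chrom: str
    positions: np.ndarray
    strands: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        strands = np.asarray(self.strands, dtype=object)
        if pos.shape != strands.shape:
            raise ValidationError("positions and strands must have equal length")
        if len(pos) and not set(np.unique(strands)) <= _STRANDS:
            raise ValidationError("strands must be + or -")
        if (pos < 0).any():
            raise ValidationError("positions must be non-negative")
        order = np.argsort(pos, kind="stable")
        self.positions = pos[order]
        self.strands = strands[order]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class GeneModule:
    """A discovered co-expressed gene set."""

    label: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"module {self.label} is empty")


@dataclass
class SignatureScores:
    """Per-seed composite score; ``definition`` records genes and sign convention."""

    scores: pd.Series
    definition: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValidationError("signature scores must be finite")
        if not self.scores.index.is_unique:
            raise ValidationError("one score per seed required")

    @property
    def seed_ids(self) -> pd.Index:
        return self.scores.index
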