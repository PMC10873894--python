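"""Readers and writers: MTX + TSV sidecars, dense TSV, BED6, bedGraph.

MTX layout: ``<stem>.mtx`` (seeds x genes, integer COO sorted by seed then
gene) with sidecars ``<stem>.seeds.tsv`` (seed_id, condition, intergenic,
optional class_label) and ``<stem>.genes.tsv`` (gene_id).

Dense-TSV layout: genes as rows, seeds as columns, header row of seed ids,
with reserved rows ``__intergenic__`` (integer), ``__condition__`` and
optionally ``__class__`` (strings) so the dialect round-trips the full
object.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    PHENO_COLUMNS,
    CountMatrix,
    CoverageTrack,
    FormatError,
    GenomicWindow,
    PhenotypeTable,
    ValidationError,
)

_RESERVED_ROWS = ("__intergenic__", "__condition__", "__class__")


def _mtx_paths(path: Path) -> tuple[Path, Path, Path]:
    stem = path.with_suffix("") if path.suffix == ".mtx" else path
    return stem.with_suffix(".mtx"), Path(f"{stem}.seeds.tsv"), Path(f"{stem}.genes.tsv")


def _infer_format(path: Path) -> str:
    return "mtx" if path.suffix == ".mtx" else "tsv"


def read_count_matrix(path: str | Path, format: Optional[str] = None) -> CountMatrix:
    """Read a CountMatrix from MTX-with-sidecars or dense TSV."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        return _read_mtx(path)
    if fmt == "tsv":
        return _read_dense_tsv(path)
    raise FormatError(f"unknown count-matrix format {fmt!r}")


def _read_mtx(path: Path) -> CountMatrix:
    mtx_path, seeds_path, genes_path = _mtx_paths(path)
    for p in (mtx_path, seeds_path, genes_path):
        if not p.exists():
            raise FormatError(f"missing count-matrix file: {p}")
    mat = scipy.io.mmread(mtx_path)
    seeds = pd.read_csv(seeds_path, sep="\t", dtype={"seed_id": str})
    genes = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str})
    if "seed_id" not in seeds.columns or "intergenic" not in seeds.columns:
        raise FormatError(f"{seeds_path}: needs seed_id and intergenic columns")
    if "condition" not in seeds.columns:
        raise FormatError(f"{seeds_path}: needs a condition column")
    if "gene_id" not in genes.columns:
        raise FormatError(f"{genes_path}: needs a gene_id column")
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if dense.shape != (len(seeds), len(genes)):
        raise ValidationError(
            f"matrix shape {dense.shape} does not match sidecars "
            f"({len(seeds)} seeds, {len(genes)} genes)"
        )
    if not np.all(np.equal(np.mod(dense, 1), 0)):
        raise ValidationError(f"{mtx_path}: non-integer entries")
    idx = pd.Index(seeds["seed_id"], name="seed_id")
    counts = pd.DataFrame(dense.astype(np.int64), index=idx, columns=pd.Index(genes["gene_id"], name="gene_id"))
    class_label = None
    if "class_label" in seeds.columns and seeds["class_label"].notna().any():
        class_label = pd.Series(seeds["class_label"].to_numpy(), index=idx, name="class_label")
    return CountMatrix(
        counts=counts,
        intergenic=pd.Series(seeds["intergenic"].to_numpy(), index=idx, name="intergenic"),
        condition=pd.Series(seeds["condition"].to_numpy(), index=idx, name="condition"),
        class_label=class_label,
    )


def _read_dense_tsv(path: Path) -> CountMatrix:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "__intergenic__" not in raw.index:
        raise FormatError(f"{path}: dense TSV must contain an __intergenic__ row")
    idx = pd.Index(raw.columns.astype(str), name="seed_id")
    intergenic = pd.to_numeric(raw.loc["__intergenic__"], errors="raise")
    if "__condition__" in raw.index:
        condition = pd.Series(raw.loc["__condition__"].to_numpy(), index=idx, name="condition")
    else:
        # dense fixtures without condition metadata: single pseudo-condition
        condition = pd.Series("pool", index=idx, name="condition")
    class_label = None
    if "__class__" in raw.index:
        class_label = pd.Series(raw.loc["__class__"].to_numpy(), index=idx, name="class_label")
    body = raw.drop(index=[r for r in _RESERVED_ROWS if r in raw.index])
    try:
        vals = body.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric count entry ({exc})") from exc
    if not np.all(np.equal(np.mod(vals, 1), 0)):
        raise ValidationError(f"{path}: non-integer count entries")
    if (vals < 0).any():
        raise ValidationError(f"{path}: negative count entries")
    counts = pd.DataFrame(vals.astype(np.int64).T, index=idx, columns=pd.Index(body.index.astype(str), name="gene_id"))
    intergenic = pd.Series(intergenic.to_numpy(dtype=np.int64), index=idx, name="intergenic")
    return CountMatrix(counts=counts, intergenic=intergenic, condition=condition, class_label=class_label)


def write_count_matrix(m: CountMatrix, path: str | Path, format: Optional[str] = None) -> Path:
    """Write a CountMatrix; output is re-readable with identical content."""
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        mtx_path, seeds_path, genes_path = _mtx_paths(path)
        coo = scipy.sparse.coo_matrix(m.counts.to_numpy(dtype=np.int64))
        # canonical (seed, gene) ordering
        order = np.lexsort((coo.col, coo.row))
        coo = scipy.sparse.coo_matrix(
            (coo.data[order], (coo.row[order], coo.col[order])), shape=coo.shape
        )
        scipy.io.mmwrite(mtx_path, coo, field="integer")
        seeds = pd.DataFrame(
            {
                "seed_id": m.seed_ids,
                "condition": m.condition.to_numpy(),
                "intergenic": m.intergenic.to_numpy(),
            }
        )
        if m.class_label is not None:
            seeds["class_label"] = m.class_label.to_numpy()
        seeds.to_csv(seeds_path, sep="\t", index=False)
        pd.DataFrame({"gene_id": m.gene_ids}).to_csv(genes_path, sep="\t", index=False)
        return mtx_path
    if fmt == "tsv":
        body = m.counts.T.astype(object)
        extra = {"__intergenic__": m.intergenic.to_numpy(dtype=object),
                 "__condition__": m.condition.to_numpy(dtype=object)}
        if m.class_label is not None:
            extra["__class__"] = m.class_label.to_numpy(dtype=object)
        full = pd.concat([body, pd.DataFrame(extra, index=m.seed_ids).T])
        full.index.name = "gene_id"
        full.to_csv(path, sep="\t")
        return path
    raise FormatError(f"unknown count-matrix format {fmt!r}")


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"seed_id": str, "replicate": str},
    )
    if "germinated" in df.columns:
        df["germinated"] = df["germinated"].map(
            {"True": True, "False": False, True: True, False: False, "true": True, "false": False}
        )
        if df["germinated"].isna().any():
            raise FormatError(f"{path}: germinated column must be true/false")
    if "germination_day" in df.columns:
        df["germination_day"] = df["germination_day"].astype("Int64")
    return PhenotypeTable(df)


def write_phenotype_table(pt: PhenotypeTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pt.df.reindex(columns=PHENO_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_windows(path: str | Path) -> List[GenomicWindow]:
    """Read BED6 windows (chrom, start, end, name/label, score, strand)."""
    windows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: BED6 needs 6 fields, got {len(fields)}")
        chrom, start, end, label, _score, strand = fields[:6]
        try:
            window = GenomicWindow(chrom, int(start), int(end), strand, label)
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        windows.append(window)
    labels = [w.label for w in windows]
    if len(labels) != len(set(labels)):
        raise ValidationError(f"{path}: duplicate window labels")
    return windows


def write_windows(windows: List[GenomicWindow], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.label}\t0\t{w.strand}\n")
    return path


def read_coverage(path: str | Path, default_strand: str = "+") -> CoverageTrack:
    """Read 3'-end positions from a bedGraph or a position TSV.

    bedGraph (``chrom start end depth``) carries no strand; every expanded
    position gets ``default_strand``.  The position TSV dialect is
    ``chrom pos strand`` with one row per read.
    """
    path = Path(path)
    text = Path(path).read_text().splitlines()
    chroms, positions, strands = [], [], []
    is_bedgraph = path.suffix.lower() in {".bedgraph", ".bg"}
    for lineno, line in enumerate(text, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split()
        try:
            if is_bedgraph:
                if len(fields) != 4:
                    raise FormatError("bedGraph needs 4 fields")
                chrom, start, end, depth = fields
                start_i, end_i, depth_i = int(start), int(end), int(depth)
                if depth_i < 0 or start_i >= end_i:
                    raise FormatError("invalid interval or negative depth")
                for pos in range(start_i, end_i):
                    chroms.append(chrom)
                    positions.extend([pos] * depth_i)
                    strands.extend([default_strand] * depth_i)
            else:
                if len(fields) != 3:
                    raise FormatError("position TSV needs 3 fields (chrom, pos, strand)")
                chrom, pos, strand = fields
                chroms.append(chrom)
                positions.append(int(pos))
                strands.append(strand)
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    chrom_set = set(chroms)
    if len(chrom_set) > 1:
        raise ValidationError(f"{path}: track spans multiple chromosomes {sorted(chrom_set)}")
    chrom = chrom_set.pop() if chrom_set else "."
    return CoverageTrack(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        strands=np.asarray(strands, dtype=object),
    )


def write_coverage(track: CoverageTrack, path: str | Path) -> Path:
    """Write a track as a position TSV (one row per read)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for pos, strand in zip(track.positions, track.strands):
            fh.write(f"{track.chrom}\t{pos}\t{strand}\n")
    return path
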