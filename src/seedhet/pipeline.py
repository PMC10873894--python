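"""End-to-end orchestration: QC -> normalize -> DE -> modules -> signatures
-> signature correlation -> isoform ratios -> phenotype statistics.

``run_all`` is deterministic given the seed: a single seed is fanned out to
per-stage child seeds through ``numpy.random.SeedSequence([seed, stage])``,
so any stage can be rerun alone with the same stream.  Every output table is
TSV with a header, re-readable by the IO layer, and a YAML manifest records
the effective configuration and SHA-256 hashes of the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import coexpr, diffexpr, io, isoform, phenotype, qc
from .config import Config
from .datatypes import CountMatrix, PhenotypeTable, ValidationError
from .simulate import (
    LocusSimConfig,
    PhenoSimConfig,
    SimConfig,
    simulate_experiment,
    simulate_locus_reads,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)

# stage indices for child-seed derivation
_STAGE_EXPERIMENT = 0
_STAGE_PHENOTYPES = 1
_STAGE_LOCUS = 2

#: per-class proximal-site usage for the simulated two-isoform locus
DEFAULT_CLASS_P_PROX = {"small": 0.7, "large": 0.4}
#: pool size per replicate for the simulated extreme-selection experiment
EXTREMES_POOL_SIZE = 1000


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(rng_seed: int, stage: int, item: int = 0) -> int:
    """Deterministic child seed for a pipeline stage (< 2**31)."""
    return int(np.random.SeedSequence([rng_seed, stage, item]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    cfg: Config,
    out_dir: str | Path,
    rng_seed: Optional[int] = None,
    counts: Optional[CountMatrix] = None,
    phenotypes: Optional[PhenotypeTable] = None,
    simulate: bool = False,
    sim_cfg: SimConfig = SimConfig(),
    pheno_cfg: PhenoSimConfig = PhenoSimConfig(),
    locus_cfg: LocusSimConfig = LocusSimConfig(),
    class_p_prox: Dict[str, float] = DEFAULT_CLASS_P_PROX,
) -> Dict[str, Path]:
    """Run the full analysis and write the report bundle to ``out_dir``.

    With ``simulate=True`` the inputs are generated; otherwise ``counts``
    (and optionally ``phenotypes``) must be supplied.  Returns a mapping of
    output names to file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg.rng_seed if rng_seed is None else rng_seed
    outputs: Dict[str, Path] = {}

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with _stage("inputs"):
        if simulate:
            counts, truth = simulate_experiment(sim_cfg, stage_seed(seed, _STAGE_EXPERIMENT))
            phenotypes, _ = simulate_phenotypes(pheno_cfg, stage_seed(seed, _STAGE_PHENOTYPES))
            outputs["counts"] = io.write_count_matrix(counts, out_dir / "counts.mtx")
            outputs["phenotypes"] = io.write_phenotype_table(phenotypes, out_dir / "phenotypes.tsv")
        elif counts is None:
            raise ValidationError("no count matrix given and --simulate not requested")

    with _stage("qc"):
        metrics = qc.seed_qc_metrics(counts)
        outputs["qc_report"] = out_dir / "qc_report.tsv"
        metrics.to_csv(outputs["qc_report"], sep="\t", index_label="seed_id")
        ok_seeds = counts.seed_ids[counts.counts.sum(axis=1) > 0]
        counts_ok = counts.subset_seeds(ok_seeds) if len(ok_seeds) < counts.n_seeds else counts

        low_m, removed_low = qc.filter_low_expressed(counts_ok, cfg.min_mean_reads_per_seed)
        filt, removed_ig = qc.filter_intergenic_correlated(low_m, cfg.intergenic_corr_threshold)
        removed = pd.concat(
            [
                pd.DataFrame({"gene_id": removed_low, "reason": "low_expression"}),
                pd.DataFrame({"gene_id": removed_ig.index, "reason": "intergenic_correlated"}),
            ]
        )
        outputs["removed_genes"] = out_dir / "removed_genes.tsv"
        removed.to_csv(outputs["removed_genes"], sep="\t", index=False)

    with _stage("normalize"):
        nm = qc.normalize_counts(filt, cfg.norm_scale)

    with _stage("de"):
        if filt.class_label is None:
            raise ValidationError("class labels (small/large) required for DE")
        small = list(filt.seed_ids[filt.class_label == "small"])
        large = list(filt.seed_ids[filt.class_label == "large"])
        de = diffexpr.de_genes(nm, large, small, cfg)  # log2fc > 0 = up in large
        outputs["de"] = out_dir / "de_large_vs_small.tsv"
        de.to_csv(outputs["de"], sep="\t", index_label="gene_id")

    with _stage("modules"):
        sd = nm.values.std(axis=0)
        corr = coexpr.gene_correlation(nm, nm.gene_ids[sd > 0])
        modules = coexpr.correlation_graph_modules(
            corr, cfg.coexpr_corr_threshold, cfg.min_module_size
        )
        module_rows = [
            {"gene_id": g, "module": m.label} for m in modules for g in sorted(m.genes)
        ]
        outputs["modules"] = out_dir / "modules.tsv"
        pd.DataFrame(module_rows, columns=["gene_id", "module"]).to_csv(
            outputs["modules"], sep="\t", index=False
        )

    with _stage("signatures"):
        if len(modules) < 2:
            raise ValidationError(f"found {len(modules)} module(s); need 2 for the index")
        cond_order = list(dict.fromkeys(counts.condition))
        mod_up, mod_down = coexpr.orient_modules(nm, modules, filt.condition, cond_order)
        germ_idx = coexpr.germination_index(nm, mod_up, mod_down)
        up_in_large = set(de.index[de["significant"] & (de["log2fc"] > 0)])
        up_in_small = set(de.index[de["significant"] & (de["log2fc"] < 0)])
        size_sig = coexpr.size_signature(nm, up_in_small, up_in_large)
        sig = pd.DataFrame(
            {
                "germination_index": germ_idx.scores,
                "size_signature": size_sig.scores,
            }
        )
        outputs["signatures"] = out_dir / "signatures.tsv"
        sig.to_csv(outputs["signatures"], sep="\t", index_label="seed_id")
        r, p = coexpr.signature_correlation(size_sig, germ_idx)
        outputs["signature_correlation"] = out_dir / "signature_correlation.tsv"
        pd.DataFrame(
            [{"r": r, "p_value": p, "n_seeds": len(sig)}]
        ).to_csv(outputs["signature_correlation"], sep="\t", index=False)

    with _stage("isoform"):
        rows = []
        for c, (label, p_prox) in enumerate(sorted(class_p_prox.items())):
            for rep in range(4):
                lcfg = dataclasses.replace(locus_cfg, p_prox=p_prox)
                track, (prox, dist), _ = simulate_locus_reads(
                    lcfg, stage_seed(seed, _STAGE_LOCUS, c * 100 + rep)
                )
                ratio = isoform.isoform_ratio(
                    isoform.count_window_reads(track, prox),
                    isoform.count_window_reads(track, dist),
                )
                rows.append({"class_label": label, "replicate": f"R{rep + 1}", "ratio": ratio})
        ratios = pd.DataFrame(rows)
        outputs["isoform_ratios"] = out_dir / "isoform_ratios.tsv"
        ratios.to_csv(outputs["isoform_ratios"], sep="\t", index=False)
        cmp = isoform.compare_ratios(ratios)
        outputs["isoform_test"] = out_dir / "isoform_test.tsv"
        pd.DataFrame(
            [{"test": cmp.test, "statistic": cmp.statistic, "p_value": cmp.p_value,
              "n_excluded": cmp.n_excluded}]
        ).to_csv(outputs["isoform_test"], sep="\t", index=False)

    with _stage("phenotype"):
        if phenotypes is not None:
            res = phenotype.compare_size_by_germination(phenotypes)
            outputs["phenotype_stats"] = out_dir / "phenotype_stats.tsv"
            pd.DataFrame(
                [{"test": "wilcoxon_pooled", "statistic": res.statistic, "p_value": res.p_value}]
            ).to_csv(outputs["phenotype_stats"], sep="\t", index=False)
            outputs["phenotype_replicate_means"] = out_dir / "phenotype_replicate_means.tsv"
            res.replicate_means.to_csv(outputs["phenotype_replicate_means"], sep="\t")
            # extreme-selection experiment: per replicate, a fresh pool is
            # sorted and its size extremes scored for germination
            pcts = {"small": [], "large": []}
            for rep in range(pheno_cfg.n_replicates):
                pool_cfg = dataclasses.replace(
                    pheno_cfg, n_seeds=EXTREMES_POOL_SIZE, n_replicates=1
                )
                pool, _ = simulate_phenotypes(
                    pool_cfg, stage_seed(seed, _STAGE_PHENOTYPES, rep + 1)
                )
                small_ids, large_ids = phenotype.select_extremes(pool, cfg.extreme_fraction)
                pcts["small"].append(
                    phenotype.germination_percentage(phenotype.subset(pool, small_ids))
                )
                pcts["large"].append(
                    phenotype.germination_percentage(phenotype.subset(pool, large_ids))
                )
            t, dof, p = phenotype.paired_t_test(pcts["large"], pcts["small"])
            outputs["extremes_germination"] = out_dir / "extremes_germination.tsv"
            pd.DataFrame(
                {
                    "replicate": [f"R{i + 1}" for i in range(pheno_cfg.n_replicates)],
                    "small_germination_pct": pcts["small"],
                    "large_germination_pct": pcts["large"],
                }
            ).to_csv(outputs["extremes_germination"], sep="\t", index=False)
            outputs["extremes_test"] = out_dir / "extremes_test.tsv"
            pd.DataFrame(
                [{"test": "paired_t", "t": t, "df": dof, "p_value": p}]
            ).to_csv(outputs["extremes_test"], sep="\t", index=False)

    def _plain(obj):
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        return obj

    with _stage("manifest"):
        manifest = {
            "rng_seed": seed,
            "config": _plain(dataclasses.asdict(cfg)),
            "simulated": bool(simulate),
            "sim_config": _plain(dataclasses.asdict(sim_cfg)) if simulate else None,
            "pheno_config": _plain(dataclasses.asdict(pheno_cfg)) if simulate else None,
            "outputs": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in sorted(outputs.items())},
        }
        manifest_path = out_dir / "manifest.yaml"
        manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
        outputs["manifest"] = manifest_path

    return outputs
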