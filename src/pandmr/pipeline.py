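"""End-to-end orchestration: simulate -> normalize -> site stats ->
pan-cancer DMS -> DMR -> merge -> intersect -> co-expression.

Each collection (e.g. a discovery and a validation set, mirroring a
TCGA-discovery / GEO-validation design) gets its own cohorts over one
shared probe manifest; DMS and DMR calling run per collection, and the
common region set is the genomic intersection across collections. The
run writes every stage's tables plus a machine-readable ``summary.json``
and is fully determined by the config (including its master seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .coexpr import block_contrast, correlation_matrix, distal_association
from .core import PlantedDMR, ValidationError
from .io import (
    write_beta_matrix,
    write_expression,
    write_manifest,
    write_sample_sheet,
)
from .normalize import filter_cohorts, normalize_cohorts
from .regions import (
    call_dmrs,
    dmr_table,
    dmrs_to_bed,
    intersect_collections,
    merge_dmrs,
)
from .simulate import (
    DEFAULT_BLOCKS,
    build_manifest_with_runs,
    generate_beta_cohorts,
    generate_expression_cohorts,
)
from .sitestats import cohort_stats_tables, pan_cancer_dms

__all__ = ["run_all", "simulate_inputs"]

logger = logging.getLogger(__name__)


def _stable_sub_seed(master: int, index: int) -> int:
    """Deterministic 31-bit sub-seed for a numbered stage."""
    return int(
        np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31)
    )


def planted_from_config(config: PipelineConfig) -> list[PlantedDMR]:
    return [PlantedDMR(**entry) for entry in config.planted]


def simulate_inputs(config: PipelineConfig, collection_index: int = 0):
    """Manifest + beta cohorts for one collection under the config seed."""
    planted = planted_from_config(config)
    manifest = build_manifest_with_runs(
        planted,
        n_background_probes=config.n_background_probes,
        chroms=config.chroms,
        mean_spacing_bp=config.mean_spacing_bp,
        seed=_stable_sub_seed(config.seed, 0),
    )
    cohorts = generate_beta_cohorts(
        manifest,
        n_cohorts=config.n_cohorts,
        n_normal=config.n_normal,
        n_tumor=config.n_tumor,
        planted=planted,
        baseline_params=config.baseline_params,
        planted_baseline_params=config.planted_baseline_params,
        noise_sd=config.noise_sd,
        cohort_sd=config.cohort_sd,
        seed=_stable_sub_seed(config.seed, 1 + collection_index),
        sample_prefix=f"{config.collections[collection_index]}_",
    )
    return manifest, cohorts


def run_all(config: PipelineConfig, write_intermediates: bool = True) -> dict:
    """Run the full pipeline; returns the summary dict (also written to disk).

    The shared manifest is generated once; each collection draws its own
    cohorts carrying the same planted truth. Stages per collection:
    quantile normalization (joint or per cohort), cohort-size filtering,
    per-cohort site statistics, pan-cancer DMS aggregation, DMR calling
    and merging. Collections are then intersected into the common DMR
    set. Expression cohorts are generated once and summarized per cohort
    as normal/tumor block contrasts plus distal-gene associations.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("pandmr")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_all(config, out_dir, write_intermediates)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_all(config: PipelineConfig, out_dir: Path, write_intermediates: bool) -> dict:
    logger.info("pandmr %s, config hash %s", __version__, config.config_hash())
    config.to_yaml(out_dir / "config.yaml")

    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "collections": {},
    }
    planted = planted_from_config(config)
    summary["planted"] = [asdict(p) for p in planted]

    merged_by_collection: dict[str, list] = {}
    manifest = None
    for idx, collection in enumerate(config.collections):
        cdir = out_dir / collection
        cdir.mkdir(exist_ok=True)
        manifest, cohorts = simulate_inputs(config, collection_index=idx)
        if write_intermediates and idx == 0:
            write_manifest(manifest, out_dir / "manifest.tsv")
        if write_intermediates:
            write_sample_sheet(cohorts.sample_sheet(), cdir / "sample_sheet.tsv")
            for name, (normal_m, tumor_m) in cohorts.cohorts.items():
                write_beta_matrix(normal_m, cdir / f"beta_{name}_normal.tsv")
                write_beta_matrix(tumor_m, cdir / f"beta_{name}_tumor.tsv")

        scope = config.normalize_scope
        normalized = normalize_cohorts(cohorts, mode=config.qn_mode, scope=scope)
        filtered = filter_cohorts(normalized, min_group_size=config.min_group_size)
        tables = cohort_stats_tables(filtered, use_logit=config.use_logit_test)
        if write_intermediates:
            for name, table in tables.items():
                table.to_csv(cdir / f"site_stats_{name}.tsv", sep="\t", index=False)
        dms = pan_cancer_dms(
            tables,
            q_threshold=config.q_threshold,
            mean_auc_threshold=config.mean_auc_threshold,
            min_significant_fraction=config.min_significant_fraction,
            direction_mode=config.direction_mode,
        )
        if write_intermediates:
            dms.to_csv(cdir / "pan_cancer_dms.tsv", sep="\t", index=False)
        dmrs = call_dmrs(
            dms, manifest,
            min_sites=config.min_sites,
            min_density_per_kb=config.min_density_per_kb,
        )
        merged = merge_dmrs(dmrs, max_gap_bp=config.max_gap_bp)
        merged_by_collection[collection] = merged
        if write_intermediates:
            dmr_table(merged).to_csv(cdir / "dmr_table.tsv", sep="\t", index=False)
            dmrs_to_bed(merged).to_csv(cdir / "dmrs.bed", sep="\t", index=False, header=False)
        summary["collections"][collection] = {
            "n_cohorts": len(filtered.cohorts),
            "n_probes": len(manifest),
            "n_dms": int(len(dms)),
            "n_dmrs": len(dmrs),
            "n_dmrs_merged": len(merged),
            "dmrs": dmr_table(merged).to_dict(orient="records"),
        }

    # common regions across collections
    names = list(config.collections)
    common = merged_by_collection[names[0]]
    for other in names[1:]:
        common = intersect_collections(
            common, merged_by_collection[other], min_overlap_bp=config.min_overlap_bp
        )
    summary["common_dmrs"] = dmr_table(common).to_dict(orient="records")
    summary["n_common_dmrs"] = len(common)
    if write_intermediates:
        dmr_table(common).to_csv(out_dir / "common_dmrs.tsv", sep="\t", index=False)

    # co-expression stage
    expr = generate_expression_cohorts(
        n_cohorts=config.n_cohorts,
        n_normal=config.expr_n_normal,
        n_tumor=config.expr_n_tumor,
        r_within_normal=config.r_within_normal,
        r_within_tumor=config.r_within_tumor,
        r_between=config.r_between,
        distal_gene=config.distal_gene,
        distal_gene_r_tumor=config.distal_gene_r_tumor,
        seed=_stable_sub_seed(config.seed, 9001),
    )
    coexpr_summary = {}
    edir = out_dir / "coexpr"
    if write_intermediates:
        edir.mkdir(exist_ok=True)
    for cname, groups in expr.cohorts.items():
        entry = {}
        for gname, matrix in groups.items():
            corr = correlation_matrix(matrix)
            contrast = block_contrast(corr, expr.block_assignment)
            assoc = distal_association(
                matrix, config.distal_gene, expr.cluster_genes, alpha=config.alpha
            )
            entry[gname] = {
                "contrast": contrast.contrast,
                "within_mean": contrast.within_mean,
                "between_mean": contrast.between_mean,
                "n_distal_significant": int(assoc["significant"].sum()),
            }
            if write_intermediates:
                write_expression(matrix, edir / f"expression_{cname}_{gname}.tsv")
                corr.matrix.to_csv(edir / f"corr_{cname}_{gname}.tsv", sep="\t")
                assoc.to_csv(edir / f"distal_{cname}_{gname}.tsv", sep="\t", index=False)
        entry["contrast_drop"] = entry["normal"]["contrast"] - entry["tumor"]["contrast"]
        coexpr_summary[cname] = entry
    summary["coexpr"] = coexpr_summary

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", out_dir / "summary.json")
    return summary
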