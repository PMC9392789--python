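"""End-to-end orchestration: synthesise or ingest, filter, score, correct,
compare, DE/GSEA, and write a machine-readable run report.

Every stage writes its outputs as TSV/JSON under the output directory and
appends one JSON line to ``log.jsonl``; a failed stage aborts the run and
quarantines partial outputs under ``failed/``. A rerun with the same config
and seed reproduces identical outputs for all deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .baseline import (
    adjust_for_purity,
    classify_quadrants,
    compute_baselines,
    compute_bc_ccs,
)
from .containers import GroupAssignment, ValidationError
from .de import (
    correlate_genes_to_bccs,
    fit_moderated_de,
    module_ttest,
    rank_statistic,
    volcano_partition,
)
from .embedding import flag_embedding_outliers, run_pca, select_variable_genes
from .filtering import apply_small_group_rule, run_full_cascade
from .genomic import compare_arm_calls, compare_mutations, enriched_in_group2
from .gsea import preranked_gsea
from .scoring import compute_module_score, compute_signature_score, minmax_rescale
from .synthetic import SyntheticConfig, cohort_gene_sets, default_config, generate_cohort

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Defaults are the thresholds used throughout: groups of ten or more
    samples, FDR 5% for mutation/arm/DE comparisons, FDR 10% for GSEA,
    |log2FC| > 2 for DE significance, and rho > 0.3 as the correlation
    reference line.
    """

    synthetic: bool = True
    synthetic_config: Optional[SyntheticConfig] = None
    # paths, used when synthetic is False
    manifest: Optional[str] = None
    expression: Optional[str] = None
    purity: Optional[str] = None
    mutations: Optional[str] = None
    arm_calls: Optional[str] = None
    gene_sets: Optional[str] = None
    signature_name: str = "CCS"
    # thresholds
    min_group_size: int = 10
    outlier_alpha: float = 0.001
    max_outlier_frac: float = 0.01
    quadrant_threshold: float = 0.5
    group1: tuple = ()
    group2: tuple = ()
    fdr_genomic: float = 0.05
    fdr_de: float = 0.05
    fdr_gsea: float = 0.10
    lfc_threshold: float = 2.0
    rho_reference: float = 0.3
    n_top_genes: int = 6364
    n_perm: int = 1000
    esr1_gene: Optional[str] = "ESR1"
    seed: int = 0

    def validate(self) -> None:
        for name in ("outlier_alpha", "quadrant_threshold", "fdr_genomic",
                     "fdr_de", "fdr_gsea"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValidationError("lfc_threshold must be >= 0")
        if set(self.group1) & set(self.group2):
            raise ValidationError("group1 and group2 overlap")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        syn = raw.pop("synthetic_config", None)
        config = cls(**raw)
        if syn is not None:
            from .synthetic import TissueSpec

            tissues = [TissueSpec(**t) for t in syn.pop("tissues", [])]
            arm = {k: tuple(v) for k, v in syn.pop("arm_enrichment", {}).items()}
            config.synthetic_config = SyntheticConfig(
                tissues=tissues, arm_enrichment=arm, **syn
            )
        return config


@dataclass
class RunReport:
    filter_report: dict = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    version: str = __version__
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2)


class _StageLogger:
    def __init__(self, path: Path):
        self.path = path

    def log(self, stage: str, **info) -> None:
        record = {"stage": stage, "time": time.time(), **info}
        with open(self.path, "a", encoding="utf-8") as handle:
            handle.write(json.dumps(record) + "\n")


def run_pipeline(config: RunConfig, outdir) -> RunReport:
    """Execute the full analysis in order; see module docstring."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_log = _StageLogger(outdir / "log.jsonl")
    report = RunReport(seed=config.seed)
    report.thresholds = {
        k: getattr(config, k)
        for k in ("min_group_size", "outlier_alpha", "quadrant_threshold",
                  "fdr_genomic", "fdr_de", "fdr_gsea", "lfc_threshold",
                  "rho_reference")
    }
    current_stage = "setup"
    try:
        # ---- inputs ------------------------------------------------------
        current_stage = "inputs"
        if config.synthetic:
            syn_config = config.synthetic_config or default_config(seed=config.seed)
            syn_config.seed = config.seed
            cohort = generate_cohort(syn_config)
            manifest, expr = cohort.manifest, cohort.expression
            purity, mutations, arms = cohort.purity, cohort.mutations, cohort.arm_calls
            gene_sets = cohort_gene_sets(cohort.truth, seed=config.seed)
            groups = GroupAssignment(
                frozenset(config.group1 or syn_config.group1_cancer_types),
                frozenset(config.group2 or syn_config.group2_cancer_types),
            )
            cohort.truth.to_json(outdir / "truth.json")
            bio.write_manifest(manifest, outdir / "manifest.tsv")
            bio.write_expression(expr, outdir / "expression.tsv")
            bio.write_purity(purity, outdir / "purity.tsv")
            bio.write_mutations(mutations, outdir / "mutations.tsv")
            bio.write_arm_calls(arms, outdir / "arm_calls.tsv")
            bio.write_gmt(gene_sets, outdir / "gene_sets.gmt")
        else:
            manifest = bio.read_manifest(config.manifest)
            expr = bio.read_expression(config.expression)
            purity = bio.read_purity(config.purity) if config.purity else pd.Series(dtype=float)
            mutations = bio.read_mutations(config.mutations) if config.mutations else None
            arms = bio.read_arm_calls(config.arm_calls) if config.arm_calls else None
            gene_sets = bio.read_gmt(config.gene_sets) if config.gene_sets else []
            groups = GroupAssignment(frozenset(config.group1), frozenset(config.group2))
        stage_log.log("inputs", n_samples=len(manifest), n_genes=expr.n_genes)

        # ---- filtering ---------------------------------------------------
        current_stage = "filtering"
        manifest, filter_report = run_full_cascade(manifest)
        manifest = apply_small_group_rule(manifest, config.min_group_size)
        manifest.check_site_matching()
        expr = expr.subset_samples(
            [s for s in expr.sample_ids if s in set(manifest.sample_ids)]
        )
        report.filter_report = filter_report.to_dict()
        stage_log.log("filtering", **report.filter_report)

        # ---- embedding QC ------------------------------------------------
        current_stage = "embedding_qc"
        n_top = min(config.n_top_genes, expr.n_genes)
        top_genes = select_variable_genes(expr, n_top)
        pca = run_pca(expr, top_genes, k=2)
        outliers = flag_embedding_outliers(pca, config.outlier_alpha)
        # The Mahalanobis rule assumes one elliptical bulk; on a strongly
        # clustered pan-tissue embedding it flags whole tissues. Only
        # auto-remove when the flagged set is a small fraction, mirroring
        # the rarity of genuinely aberrant samples.
        if len(outliers) > config.max_outlier_frac * len(manifest):
            report.warnings.append(
                f"{len(outliers)} samples flagged as embedding outliers "
                f"(> {config.max_outlier_frac:.0%} of cohort); embedding is "
                "likely clustered, none removed"
            )
            outliers = set()
        if outliers:
            from .filtering import remove_flagged_outliers

            manifest, _ = remove_flagged_outliers(manifest, outliers,
                                                  "EMBEDDING_OUTLIER")
            expr = expr.subset_samples(
                [s for s in expr.sample_ids if s in set(manifest.sample_ids)]
            )
            report.warnings.append(f"removed {len(outliers)} embedding outliers")
        pca.frame().to_csv(outdir / "pca.tsv", sep="\t")
        stage_log.log("embedding_qc", n_outliers=len(outliers))

        # ---- scoring -----------------------------------------------------
        current_stage = "scoring"
        signature = next(
            (gs for gs in gene_sets if gs.name == config.signature_name), None
        )
        if signature is None:
            raise ValidationError(
                f"signature {config.signature_name!r} not among the gene sets"
            )
        scores = minmax_rescale(compute_signature_score(expr, signature))
        score_frame = pd.DataFrame(
            {"raw": scores.raw, "scaled": scores.scaled}
        ).rename_axis("sample_id")
        score_frame.to_csv(outdir / "scores.tsv", sep="\t")
        stage_log.log("scoring", n_genes_used=scores.n_genes_used,
                      n_genes_missing=scores.n_genes_missing)

        # ---- baseline correction ----------------------------------------
        current_stage = "baseline_correction"
        baselines = compute_baselines(scores, manifest)
        tumor_ids = list(manifest.frame.loc[manifest.is_tumor, "sample_id"])
        bc = compute_bc_ccs(scores.subset(tumor_ids), baselines, manifest)
        if len(purity):
            bc = adjust_for_purity(bc, purity)
        quadrants = classify_quadrants(scores, scores, manifest,
                                       config.quadrant_threshold)
        baselines.rename_axis("tissue").to_csv(outdir / "baselines.tsv", sep="\t")
        bc.rename_axis("sample_id").to_csv(outdir / "bc_scores.tsv", sep="\t")
        quadrants.to_csv(outdir / "quadrants.tsv", sep="\t")
        stage_log.log("baseline_correction", n_tumors=len(bc),
                      quadrants=quadrants["quadrant"].value_counts().to_dict())

        # ---- genomic comparison -----------------------------------------
        current_stage = "genomic_comparison"
        if mutations is not None and len(mutations):
            mut_results = compare_mutations(mutations, manifest, groups)
            mut_results.to_csv(outdir / "mutation_comparison.tsv", sep="\t",
                               index=False)
            stage_log.log(
                "mutations",
                n_enriched=len(enriched_in_group2(mut_results, config.fdr_genomic)),
            )
        if arms is not None and len(arms):
            arm_results = compare_arm_calls(arms, manifest, groups)
            arm_results.to_csv(outdir / "arm_comparison.tsv", sep="\t", index=False)
            stage_log.log(
                "arm_calls",
                n_enriched=len(enriched_in_group2(arm_results, config.fdr_genomic)),
            )

        # ---- DE + GSEA ---------------------------------------------------
        current_stage = "de_enrichment"
        de = fit_moderated_de(
            expr, manifest, groups, esr1_gene=config.esr1_gene,
            lfc_threshold=config.lfc_threshold, fdr=config.fdr_de,
        )
        up, down = volcano_partition(de, config.lfc_threshold)
        de.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
        ranking = rank_statistic(de)
        gsea = preranked_gsea(ranking, gene_sets, n_perm=config.n_perm,
                              seed=config.seed)
        if not gsea.empty:
            gsea.assign(
                leading_edge=gsea["leading_edge"].map(",".join)
            ).to_csv(outdir / "gsea_results.tsv", sep="\t", index=False)
        stage_log.log("de_enrichment", n_up=len(up), n_down=len(down),
                      n_sets=len(gsea))

        # hormone-module t-tests + correlation of DE genes to BC-CCS
        current_stage = "modules_correlation"
        module_sets = [gs for gs in gene_sets if gs.name.endswith("_MODULE")]
        if module_sets and len(bc):
            g1_ids = [s for s in bc.index
                      if bc.loc[s, "cancer_type"] in groups.group1]
            g2_ids = [s for s in bc.index
                      if bc.loc[s, "cancer_type"] in groups.group2]
            g1_scores, g2_scores = {}, {}
            for gs in module_sets:
                mod = compute_module_score(expr, gs)
                g1_scores[gs.name] = mod.raw.loc[[s for s in g1_ids
                                                  if s in mod.raw.index]]
                g2_scores[gs.name] = mod.raw.loc[[s for s in g2_ids
                                                  if s in mod.raw.index]]
            modules = module_ttest(g1_scores, g2_scores)
            modules.to_csv(outdir / "module_ttests.tsv", sep="\t", index=False)
        sig_genes = up + down
        if sig_genes and len(bc) >= 10:
            correlations = correlate_genes_to_bccs(
                expr, bc, sig_genes, config.rho_reference
            )
            correlations.to_csv(outdir / "bccs_correlations.tsv", sep="\t",
                                index=False)
        stage_log.log("modules_correlation")

        report.outputs = {
            p.name: str(p) for p in sorted(outdir.glob("*.tsv"))
        }
        report.to_json(outdir / "report.json")
        stage_log.log("done")
        return report
    except Exception:
        failed_dir = outdir / "failed"
        failed_dir.mkdir(exist_ok=True)
        for item in list(outdir.iterdir()):
            if item.name != "failed" and item.is_file():
                shutil.move(str(item), failed_dir / item.name)
        logger.error("pipeline failed at stage %r", current_stage)
        raise
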