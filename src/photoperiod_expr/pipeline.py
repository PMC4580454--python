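"""End-to-end orchestration: score -> select -> normalize -> cluster ->
enrich -> temporal patterns.

The pipeline is deterministic: identical inputs and configuration produce
byte-identical outputs (no timestamps inside files).  A provenance record
echoing the full configuration, per-stage counts and the enrichment cutoff
applied to each group is embedded in ``summary.json``.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import __version__
from .cluster_heatmap import ward_cluster, zscore_rows
from .go_enrichment import CutoffPolicy, enrich_all_groups
from .io_tables import (
    AnnotationMap,
    ExpressionMatrix,
    ResultBundle,
    read_annotation_table,
    read_design,
    read_expression_table,
    read_gaf,
    write_results,
)
from .selection_stats import score_all, select_top_n
from .temporal_profiles import characterize_all

log = logging.getLogger("photoperiod_expr")

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_files"]


@dataclass
class PipelineConfig:
    """Flat parameter surface of one pipeline run."""

    top_n: int = 1000
    k_groups: int = 7
    ward_variant: str = "d2"
    clip: float = 3.0
    alpha: float = 0.05
    strict_alpha: float = 1e-7
    overflow_threshold: int = 100
    background: str = "all"        # or "annotated"
    fdr: bool = False
    pseudocount: float = 0.01
    min_fold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.top_n >= self.k_groups >= 1:
            raise ValueError(
                f"require top_n >= K >= 1, got top_n={self.top_n}, K={self.k_groups}"
            )
        if self.clip <= 0:
            raise ValueError("clip bound must be positive")
        if self.pseudocount < 0 or self.min_fold < 1:
            raise ValueError("pseudocount >= 0 and min_fold >= 1 required")

    @property
    def cutoff_policy(self) -> CutoffPolicy:
        return CutoffPolicy(
            alpha=self.alpha,
            overflow_threshold=self.overflow_threshold,
            strict_alpha=self.strict_alpha,
        )


def run_pipeline(
    matrix: ExpressionMatrix,
    annotations: AnnotationMap,
    config: PipelineConfig = PipelineConfig(),
) -> ResultBundle:
    """Run all stages on in-memory inputs and return the result bundle."""
    counts: Dict[str, int] = {"genes_read": matrix.n_genes}

    scores = score_all(matrix)
    selected = select_top_n(scores, config.top_n)
    counts["genes_selected"] = len(selected)
    log.info("selected %d of %d genes", len(selected), matrix.n_genes)

    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    sel_idx = [pos[g] for g in selected]
    sub = ExpressionMatrix(
        gene_ids=selected, values=matrix.values[sel_idx], design=matrix.design
    )
    rel, excluded = zscore_rows(sub)
    counts["genes_excluded_zero_variance"] = len(excluded)
    if excluded:
        log.warning(
            "%d zero-variance gene(s) excluded from clustering: %s%s",
            len(excluded), ", ".join(excluded[:5]),
            "..." if len(excluded) > 5 else "",
        )
    if len(rel.gene_ids) < config.k_groups:
        raise ValueError(
            f"only {len(rel.gene_ids)} clusterable genes after zero-variance "
            f"exclusion; K={config.k_groups} requested"
        )

    clusters = ward_cluster(rel, config.k_groups, variant=config.ward_variant)
    counts["groups"] = clusters.K
    log.info("clustered %d genes into %d groups", len(rel.gene_ids), clusters.K)

    universe = set(matrix.gene_ids)
    enrichment = enrich_all_groups(
        clusters.group_of, annotations, universe,
        policy=config.cutoff_policy, background=config.background,
        fdr=config.fdr,
    )
    counts["terms_tested"] = len(enrichment)
    counts["terms_significant"] = (
        int(enrichment["significant"].sum()) if len(enrichment) else 0
    )
    log.info(
        "tested %d (group, term) pairs, %d significant",
        counts["terms_tested"], counts["terms_significant"],
    )
    cutoffs = {}
    if len(enrichment):
        for grp, sub_df in enrichment.groupby("group"):
            cutoffs[str(grp)] = float(sub_df["cutoff_applied"].iloc[0])

    patterns = characterize_all(
        sub, min_fold=config.min_fold, pseudocount=config.pseudocount
    )

    provenance = {
        "version": __version__,
        "config": asdict(config),
        "stage_counts": counts,
        "cutoff_applied_per_group": cutoffs,
    }
    return ResultBundle(
        scores=scores,
        selected=selected,
        relmatrix=rel.to_frame(),
        clusters=clusters,
        enrichment=enrichment,
        patterns=patterns,
        provenance=provenance,
    )


def run_pipeline_files(
    expression_path,
    annotation_path,
    design_path,
    outdir,
    config: PipelineConfig = PipelineConfig(),
    annotation_format: str = "tsv",
) -> ResultBundle:
    """File-based entry point: read the three inputs, run, write outputs."""
    design = read_design(design_path)
    matrix = read_expression_table(expression_path, design)
    if annotation_format == "gaf":
        annotations = read_gaf(annotation_path)
    else:
        annotations = read_annotation_table(annotation_path)
    bundle = run_pipeline(matrix, annotations, config)
    write_results(bundle, outdir)
    return bundle
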