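"""End-to-end orchestration of the analysis stages, in experiment order:
peak calling -> amplicon exclusion -> stitching and hockey-stick cut ->
expressed-gene assignment -> collapsed-union differential coverage ->
occupancy matrix and circuit inference -> spike-in expression analysis.

Every stage is a pure function of (inputs, config, seed); the CLI and the
acceptance script are thin wrappers around :func:`run_study`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import evaluate
from .circuit import CRCGraph, OccupancyMatrix, build_occupancy_matrix, compare_crcs, infer_crc
from .config import PipelineConfig
from .coverage import CoverageTrack, rpm_normalize
from .intervals import GeneAnnotation, GenomicInterval
from .landscape import (
    DifferentialRegion,
    collapse_se_union,
    differential_coverage,
    promoter_activity,
)
from .peaks import call_peaks_dual, exclude_region
from .rose import StitchParams, SuperEnhancerCall, identify_super_enhancers
from .simulate import CONTROL, TREATED, SyntheticDataset, SyntheticDesign, generate
from .spikein import fold_changes, library_size_factors, spikein_size_factors

__all__ = ["ConditionResult", "StudyResult", "run_condition", "run_study", "run_synthetic_study"]


@dataclass
class ConditionResult:
    condition: str
    se_calls: list[SuperEnhancerCall]
    expressed_genes: set[str]
    occupancy: OccupancyMatrix
    crc: CRCGraph


@dataclass
class StudyResult:
    conditions: dict[str, ConditionResult]
    union_regions: list[GenomicInterval]
    differential: list[DifferentialRegion]
    crc_delta: dict[str, list[str]]
    expression: object  # DataFrame from fold_changes
    size_factors: object
    metrics: dict = field(default_factory=dict)


def run_condition(
    condition: str,
    tracks: Mapping[str, CoverageTrack],
    annotation: Sequence[GeneAnnotation],
    cfg: PipelineConfig,
) -> ConditionResult:
    """Single-condition stages: peaks on H3K27ac, exclusion, ROSE-style SE
    identification, promoter-activity expression calls, gene assignment,
    occupancy matrix, and circuit inference."""
    h3_raw = tracks["H3K27ac"]
    peaks = call_peaks_dual(
        h3_raw, cfg.peak_p_strict, cfg.peak_p_lenient, cfg.peak_min_len_bp
    )
    for exclusion in cfg.exclusion_intervals():
        peaks = exclude_region(peaks, exclusion)
    rpm = {name: rpm_normalize(t) for name, t in tracks.items()}
    calls = identify_super_enhancers(
        peaks,
        annotation,
        rpm["H3K27ac"],
        params=StitchParams(cfg.stitch_distance_bp, cfg.tss_exclusion_bp),
    )
    expression = promoter_activity(
        annotation, rpm["H3K27ac"], cfg.promoter_half_width_bp
    )
    expressed = {e.gene_id for e in expression if e.is_expressed}
    from .landscape import assign_enhancer

    for call in calls:
        call.assigned_gene = assign_enhancer(call.region, expression, annotation)

    candidate_regions = [c.region for c in calls]
    occupancy = build_occupancy_matrix(
        rpm, candidate_regions,
        control="IgG", h3k27ac="H3K27ac",
        min_fold=cfg.enrichment_min_fold, floor=cfg.enrichment_floor,
    )
    se_assignments: dict[str, list[GenomicInterval]] = {}
    for call in calls:
        if call.is_super and call.assigned_gene:
            se_assignments.setdefault(call.assigned_gene, []).append(call.region)
    tf_tracks = {tf: rpm[tf] for tf in cfg.candidate_tfs if tf in rpm}
    crc = infer_crc(
        condition, cfg.candidate_tfs, se_assignments, tf_tracks, rpm["IgG"],
        expressed, cfg.enrichment_min_fold, cfg.enrichment_floor,
    )
    return ConditionResult(condition, calls, expressed, occupancy, crc)


def run_study(dataset: SyntheticDataset, cfg: PipelineConfig) -> StudyResult:
    """The full two-condition analysis on one dataset, plus recovery metrics
    against the dataset's ground-truth manifest."""
    conditions = {
        cond: run_condition(cond, dataset.tracks[cond], dataset.annotation, cfg)
        for cond in (CONTROL, TREATED)
    }
    union = collapse_se_union(
        [conditions[CONTROL].se_calls, conditions[TREATED].se_calls]
    )
    rpm_h3 = {
        cond: rpm_normalize(dataset.tracks[cond]["H3K27ac"])
        for cond in (CONTROL, TREATED)
    }
    differential = differential_coverage(
        union,
        rpm_h3,
        {"A": [CONTROL], "B": [TREATED]},
        dataset.annotation,
        cfg.fold_threshold,
        cfg.differential_pseudocount,
    )
    delta = compare_crcs(conditions[CONTROL].crc, conditions[TREATED].crc)

    design = dataset.manifest["expression"]["design"]
    size_factors = spikein_size_factors(dataset.counts)
    expression = fold_changes(
        dataset.counts, dataset.gene_lengths, design,
        factors=size_factors,
        filter_tpm=cfg.tpm_filter, pseudocount=cfg.expression_pseudocount,
    )
    metrics = _score(dataset, conditions, differential, delta, expression)
    return StudyResult(
        conditions, union, differential, delta, expression, size_factors, metrics
    )


def _score(dataset, conditions, differential, delta, expression) -> dict:
    manifest = dataset.manifest
    metrics: dict = {}
    for cond, res in conditions.items():
        planted = [
            GenomicInterval(chrom, start, end)
            for chrom, start, end in manifest["se_spans"][cond].values()
        ]
        metrics[f"se_f1_{cond}"] = evaluate.se_recovery_f1(res.se_calls, planted)
        metrics[f"crc_exact_{cond}"] = evaluate.crc_recovered_exactly(
            res.crc.members, manifest["crc"][cond]["members"]
        )
    truth_spans: dict[str, list[GenomicInterval]] = {}
    labels = manifest["differential_labels"]
    all_spans = {**manifest["se_spans"][CONTROL], **manifest["se_spans"][TREATED]}
    for gid, (chrom, start, end) in all_spans.items():
        truth_spans.setdefault(labels[gid], []).append(
            GenomicInterval(chrom, start, end)
        )
    metrics.update(evaluate.differential_scores(differential, truth_spans))
    metrics["crc_delta_exact"] = delta == manifest["crc_delta"]
    planted_down = manifest["expression"]["planted_down_genes"]
    metrics["planted_down_median_log2fc"] = float(
        np.median(expression.loc[planted_down, "log2_fold_change"])
    )
    return metrics


def run_synthetic_study(
    seed: int,
    design: SyntheticDesign | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[SyntheticDataset, StudyResult]:
    """Generate the default synthetic study and run the full pipeline on it."""
    design = design or SyntheticDesign()
    dataset = generate(design, seed)
    if cfg is None:
        cfg = PipelineConfig(seed=seed)
    if not cfg.candidate_tfs:
        cfg.candidate_tfs = list(dataset.manifest["tf_genes"])
    return dataset, run_study(dataset, cfg)
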