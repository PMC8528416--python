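"""Enhancer-to-gene assignment and cross-condition differential H3K27ac.

Expression is proxied by promoter H3K27ac: a gene is "expressed" in a sample
when its TSS +/- 500 bp coverage falls in the top two-thirds of all genes.
Each enhancer is assigned to the single expressed gene whose TSS is nearest
the enhancer center. For differential analysis, super-enhancers identified
separately per sample are collapsed into one union set of regions, per-region
depth-normalized coverage is compared between conditions, and regions are
classified gained / lost / stable by log2 fold change against a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import RPM, CoverageTrack, region_signal, rpm_normalize
from .intervals import GeneAnnotation, GenomicInterval, merge_intervals
from .rose import SuperEnhancerCall

__all__ = [
    "ExpressionCall",
    "DifferentialRegion",
    "promoter_activity",
    "assign_enhancer",
    "collapse_se_union",
    "differential_coverage",
    "differential_table",
]

log = logging.getLogger(__name__)

PROMOTER_HALF_WIDTH = 500  # TSS +/- 500 bp
EXPRESSED_FRACTION = 2 / 3  # top two-thirds of promoter coverage


@dataclass(frozen=True)
class ExpressionCall:
    gene_id: str
    promoter_coverage: float
    is_expressed: bool


@dataclass
class DifferentialRegion:
    region: GenomicInterval
    coverage: dict[str, float]  # sample -> normalized (RPM) coverage
    log2_fold_change: float  # condition B vs A, pseudocount applied
    status: str  # gained | lost | stable
    assigned_gene: str | None


def promoter_activity(
    annotation: Sequence[GeneAnnotation],
    track: CoverageTrack,
    half_width: int = PROMOTER_HALF_WIDTH,
) -> list[ExpressionCall]:
    """Promoter coverage per gene and the top-two-thirds expressed flag.

    The threshold is the coverage of the gene at ascending rank floor(n/3);
    every gene at or above it (boundary ties inclusive) is expressed, so at
    least ceil(2n/3) genes are expressed.
    """
    if not annotation:
        raise ValueError("empty annotation")
    cov = np.array(
        [
            region_signal(
                track,
                GenomicInterval(
                    g.chrom, max(0, g.tss - half_width), g.tss + half_width
                ),
            )
            for g in annotation
        ]
    )
    threshold = np.sort(cov)[len(cov) // 3]
    return [
        ExpressionCall(g.gene_id, float(c), bool(c >= threshold))
        for g, c in zip(annotation, cov)
    ]


def assign_enhancer(
    enhancer: GenomicInterval,
    expressed: Sequence[ExpressionCall],
    annotation: Sequence[GeneAnnotation],
) -> str | None:
    """Assign an enhancer to the single expressed gene whose TSS is nearest
    the enhancer center (floor midpoint); ties go to the leftmost TSS.
    Returns None when the chromosome has no expressed gene."""
    expressed_ids = {e.gene_id for e in expressed if e.is_expressed}
    candidates = [
        g
        for g in annotation
        if g.chrom == enhancer.chrom and g.gene_id in expressed_ids
    ]
    if not candidates:
        log.debug("no expressed gene on %s: enhancer unassigned", enhancer.chrom)
        return None
    center = enhancer.center
    best = min(candidates, key=lambda g: (abs(g.tss - center), g.tss))
    return best.gene_id


def collapse_se_union(
    se_sets: Sequence[Sequence[SuperEnhancerCall]],
) -> list[GenomicInterval]:
    """Collapsed union of super-enhancer regions across samples: overlap-merge
    of every is_super region; disjoint, sorted, order-invariant."""
    if len(se_sets) < 2:
        raise ValueError("need at least two super-enhancer sets")
    regions = [c.region for calls in se_sets for c in calls if c.is_super]
    return merge_intervals(regions, gap=0)


def _union_expressed(
    annotation: Sequence[GeneAnnotation],
    tracks: Mapping[str, CoverageTrack],
) -> list[ExpressionCall]:
    """Expressed in any sample = union of per-sample expressed sets."""
    union: dict[str, float] = {}
    expressed_ids: set[str] = set()
    for track in tracks.values():
        for call in promoter_activity(annotation, track):
            union[call.gene_id] = max(
                union.get(call.gene_id, 0.0), call.promoter_coverage
            )
            if call.is_expressed:
                expressed_ids.add(call.gene_id)
    return [
        ExpressionCall(gid, cov, gid in expressed_ids)
        for gid, cov in union.items()
    ]


def differential_coverage(
    union_regions: Sequence[GenomicInterval],
    tracks: Mapping[str, CoverageTrack],
    condition_pairs: Mapping[str, Sequence[str]],
    annotation: Sequence[GeneAnnotation] | None = None,
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> list[DifferentialRegion]:
    """Classify union regions as gained / lost / stable between two conditions.

    ``condition_pairs`` maps ``{"A": [samples...], "B": [samples...]}``; the
    fold change is B vs A on per-region RPM coverage averaged within each
    condition, with a pseudocount so empty regions give log2FC = 0. Status is
    gained when log2FC >= log2(fold_threshold), lost when <= -log2(threshold).
    Swapping the condition labels maps gained <-> lost exactly.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if set(condition_pairs) != {"A", "B"}:
        raise ValueError("condition_pairs must have exactly conditions 'A' and 'B'")
    for cond, samples in condition_pairs.items():
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples")
        for s in samples:
            if s not in tracks:
                raise ValueError(f"sample {s!r} missing from tracks")
    # raw tracks are depth-normalized here; that requires mapped_reads
    tracks = dict(tracks)
    for name, track in tracks.items():
        if track.units != RPM:
            if track.mapped_reads <= 0:
                raise ValueError(f"track {name!r} lacks mapped_reads for RPM")
            tracks[name] = rpm_normalize(track)

    expressed = (
        _union_expressed(annotation, tracks) if annotation is not None else []
    )
    log_t = np.log2(fold_threshold)
    out: list[DifferentialRegion] = []
    for region in union_regions:
        cov = {s: region_signal(t, region) for s, t in tracks.items()}
        mean_a = float(np.mean([cov[s] for s in condition_pairs["A"]]))
        mean_b = float(np.mean([cov[s] for s in condition_pairs["B"]]))
        lfc = float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))
        if lfc >= log_t:
            status = "gained"
        elif lfc <= -log_t:
            status = "lost"
        else:
            status = "stable"
        gene = (
            assign_enhancer(region, expressed, annotation)
            if annotation is not None
            else None
        )
        out.append(DifferentialRegion(region, cov, lfc, status, gene))
    return out


def differential_table(results: Sequence[DifferentialRegion]) -> pd.DataFrame:
    """Scatter-ready TSV layout: region, per-sample coverage, log2FC, status,
    assigned gene."""
    rows = []
    for r in results:
        row = {
            "chrom": r.region.chrom,
            "start": r.region.start,
            "end": r.region.end,
        }
        row.update({f"coverage_{s}": v for s, v in r.coverage.items()})
        row["log2_fold_change"] = r.log2_fold_change
        row["status"] = r.status
        row["assigned_gene"] = r.assigned_gene or ""
        rows.append(row)
    return pd.DataFrame(rows)
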