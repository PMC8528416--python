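"""Seeded two-condition synthetic genome study with planted ground truth.

The generator emulates the statistical structure of a differentiation-agent
experiment on a regulatory genome: a control condition whose identity is
maintained by a set of super-enhancer-driven transcription factors, and a
treated condition in which part of that circuit is decommissioned while a new
one forms. It plants, on a small two-chromosome genome:

* typical enhancers (single blocks, condition-stable),
* super-enhancer clusters (constituents within stitch range) that are lost,
  gained or stable between conditions, each hosted near a gene whose promoter
  signal encodes its expressed/silent state,
* TF occupancy tracks coupled to a known circuit graph (members bind their
  own and each other's super-enhancers; an IgG track is flat background),
* a gene-by-sample count table with planted per-gene fold changes, an
  optional global expression shift, and spike-in rows independent of it.

Bin-level read noise is Poisson(intensity x exposure); an exact-mean mode
replaces draws with rounded means for noiseless oracle tests. Everything is
deterministic given the seed. The accompanying manifest fully determines the
expected output of every pipeline stage on noiseless settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import GeneAnnotation, GenomicInterval, ReadPlacement

__all__ = ["SyntheticDesign", "SyntheticDataset", "generate", "simulate_read_placements"]

CONTROL, TREATED = "control", "treated"


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the planted genome study (defaults are the study
    conditions every recovery test runs under)."""

    chrom_sizes: tuple[tuple[str, int], ...] = (("chr1", 5_000_000), ("chr2", 5_000_000))
    bin_width: int = 50
    genes_per_chrom: int = 30
    gene_spacing: int = 150_000
    first_tss: int = 200_000
    # planted signal intensities, Poisson mean per 50-bp bin
    background: float = 0.2
    promoter_intensity: float = 10.0
    typical_intensity: float = 5.0
    se_intensity: float = 20.0
    tf_intensity: float = 15.0
    exposure: float = 1.0  # multiplies every intensity (sequencing depth knob)
    noise: str = "poisson"  # "poisson" | "exact" (rounded means, noiseless)
    # enhancer geometry
    typical_offsets: tuple[int, ...] = (40_000, 60_000, 80_000, 100_000, 120_000)
    typical_width: int = 1_000
    se_offset: int = 5_000
    se_constituent_width: int = 1_500
    se_constituent_gap: int = 4_000
    se_n_constituents: int = 3
    # hosts per class per chromosome (lost / gained / stable / expressed filler)
    n_lost: int = 5
    n_gained: int = 5
    n_stable: int = 5
    n_filler: int = 10
    # candidate circuit TFs: (gene offset within its class, class) per TF
    # expression table
    n_expression_genes: int = 1_000
    n_spikeins: int = 40
    n_planted_down: int = 100
    planted_down_fold: float = 4.0  # treated = control / fold
    tf_expression_fold: float = 8.0
    global_shift: float = 1.0  # multiplies every biological gene in treated
    replicates: int = 3
    expression_depth: float = 1.0

    def sizes(self) -> dict[str, int]:
        return dict(self.chrom_sizes)


@dataclass
class SyntheticDataset:
    chrom_sizes: dict[str, int]
    annotation: list[GeneAnnotation]
    tracks: dict[str, dict[str, CoverageTrack]]  # condition -> target -> track
    counts: pd.DataFrame
    gene_lengths: pd.Series
    manifest: dict


def _gene_layout(design: SyntheticDesign):
    """Deterministic host-class layout. Per chromosome, genes fall in blocks:
    lost hosts, gained hosts, stable hosts, expressed filler, silent."""
    sizes = design.sizes()
    genes: list[GeneAnnotation] = []
    classes: dict[str, list[str]] = {
        "lost": [], "gained": [], "stable": [], "filler": [], "silent": []
    }
    tf_ids: list[str] = []
    k = 0
    for chrom in sizes:
        for i in range(design.genes_per_chrom):
            tss = design.first_tss + i * design.gene_spacing
            if i < design.n_lost:
                cls = "lost"
            elif i < design.n_lost + design.n_gained:
                cls = "gained"
            elif i < design.n_lost + design.n_gained + design.n_stable:
                cls = "stable"
            elif i < design.n_lost + design.n_gained + design.n_stable + design.n_filler:
                cls = "filler"
            else:
                cls = "silent"
            gid = f"G{k:03d}"
            genes.append(GeneAnnotation(gid, gid, chrom, tss, "+"))
            classes[cls].append(gid)
            k += 1
    # six circuit TFs on the first chromosome: two lost, two gained, two stable
    tf_ids = [classes["lost"][0], classes["lost"][1],
              classes["gained"][0], classes["gained"][1],
              classes["stable"][0], classes["stable"][1]]
    return genes, classes, tf_ids


def _se_span(design: SyntheticDesign, tss: int) -> tuple[int, int]:
    step = design.se_constituent_width + design.se_constituent_gap
    start = tss + design.se_offset
    end = start + (design.se_n_constituents - 1) * step + design.se_constituent_width
    return start, end


def _se_constituents(design: SyntheticDesign, tss: int) -> list[tuple[int, int]]:
    step = design.se_constituent_width + design.se_constituent_gap
    return [
        (tss + design.se_offset + j * step,
         tss + design.se_offset + j * step + design.se_constituent_width)
        for j in range(design.se_n_constituents)
    ]


def _draw_track(
    profile: dict[str, np.ndarray],
    design: SyntheticDesign,
    rng: np.random.Generator,
) -> CoverageTrack:
    bins = {}
    for chrom, mean in profile.items():
        lam = mean * design.exposure
        if design.noise == "exact":
            bins[chrom] = np.round(lam)
        else:
            bins[chrom] = rng.poisson(lam).astype(float)
    mapped = max(1, int(round(sum(a.sum() for a in bins.values()))))
    return CoverageTrack(bins, design.bin_width, "raw_counts", mapped)


def generate(design: SyntheticDesign, seed: int) -> SyntheticDataset:
    """Build the full synthetic study: coverage tracks per condition and
    target, the count table, the annotation, and the ground-truth manifest."""
    if design.noise not in ("poisson", "exact"):
        raise ValueError(f"unknown noise mode {design.noise!r}")
    rng = np.random.default_rng(seed)
    sizes = design.sizes()
    bw = design.bin_width
    genes, classes, tf_ids = _gene_layout(design)
    by_id = {g.gene_id: g for g in genes}
    for tf in tf_ids:
        if tf not in by_id:
            raise ValueError(f"circuit TF gene {tf!r} absent from annotation")

    expressed = {
        CONTROL: set(classes["lost"]) | set(classes["stable"]) | set(classes["filler"]),
        TREATED: set(classes["gained"]) | set(classes["stable"]) | set(classes["filler"]),
    }
    se_hosts = {
        CONTROL: classes["lost"] + classes["stable"],
        TREATED: classes["gained"] + classes["stable"],
    }
    crc_members = {
        CONTROL: sorted([tf_ids[0], tf_ids[1], tf_ids[4], tf_ids[5]]),
        TREATED: sorted([tf_ids[2], tf_ids[3], tf_ids[4], tf_ids[5]]),
    }

    n_bins = {c: int(np.ceil(s / bw)) for c, s in sizes.items()}

    def blank() -> dict[str, np.ndarray]:
        return {c: np.full(n, design.background) for c, n in n_bins.items()}

    def add_block(profile, chrom, start, end, intensity):
        profile[chrom][start // bw : int(np.ceil(end / bw))] += intensity

    tracks: dict[str, dict[str, CoverageTrack]] = {}
    for cond in (CONTROL, TREATED):
        profiles: dict[str, dict[str, np.ndarray]] = {"H3K27ac": blank(), "IgG": blank()}
        for tf in tf_ids:
            profiles[tf] = blank()
        h3 = profiles["H3K27ac"]
        for g in genes:
            if g.gene_id in expressed[cond]:
                add_block(h3, g.chrom, max(0, g.tss - 500), g.tss + 500,
                          design.promoter_intensity)
            for off in design.typical_offsets:
                add_block(h3, g.chrom, g.tss + off, g.tss + off + design.typical_width,
                          design.typical_intensity)
            if g.gene_id in se_hosts[cond]:
                for s, e in _se_constituents(design, g.tss):
                    add_block(h3, g.chrom, s, e, design.se_intensity)
        # circuit members bind their own and each other's super-enhancers
        for tf_i in crc_members[cond]:
            for tf_j in crc_members[cond]:
                host = by_id[tf_j]
                s, e = _se_span(design, host.tss)
                add_block(profiles[tf_i], host.chrom, s, e, design.tf_intensity)
        tracks[cond] = {
            target: _draw_track(profile, design, rng)
            for target, profile in profiles.items()
        }

    counts, lengths, expr_truth = _generate_counts(design, genes, tf_ids, classes, rng)

    manifest = {
        "seed": seed,
        "chrom_sizes": sizes,
        "bin_width": bw,
        "gene_classes": classes,
        "tf_genes": tf_ids,
        "expressed_genes": {c: sorted(v) for c, v in expressed.items()},
        "se_spans": {
            cond: {
                gid: [by_id[gid].chrom, *_se_span(design, by_id[gid].tss)]
                for gid in se_hosts[cond]
            }
            for cond in (CONTROL, TREATED)
        },
        "typical_enhancers": [
            [g.chrom, g.tss + off, g.tss + off + design.typical_width]
            for g in genes
            for off in design.typical_offsets
        ],
        "differential_labels": {
            gid: cls
            for cls in ("lost", "gained", "stable")
            for gid in classes[cls]
        },
        "crc": {
            cond: {
                "members": crc_members[cond],
                "edges": sorted(
                    (i, j) for i in crc_members[cond] for j in crc_members[cond]
                ),
            }
            for cond in (CONTROL, TREATED)
        },
        "crc_delta": {
            "shared": sorted(set(crc_members[CONTROL]) & set(crc_members[TREATED])),
            "lost": sorted(set(crc_members[CONTROL]) - set(crc_members[TREATED])),
            "gained": sorted(set(crc_members[TREATED]) - set(crc_members[CONTROL])),
        },
        "expression": expr_truth,
    }
    return SyntheticDataset(sizes, genes, tracks, counts, lengths, manifest)


def _generate_counts(design, genes, tf_ids, classes, rng):
    """Count table with planted fold changes, a global shift, and spike-ins
    that see sequencing depth but not the biological shift."""
    annot_ids = [g.gene_id for g in genes]
    filler = [f"X{k:04d}" for k in range(len(annot_ids), design.n_expression_genes)]
    gene_ids = annot_ids + filler
    spike_ids = [f"ERCC-{k + 1:05d}" for k in range(design.n_spikeins)]

    mu = rng.lognormal(np.log(200.0), 1.0, size=len(gene_ids))
    conc = rng.lognormal(np.log(100.0), 1.0, size=design.n_spikeins)
    lengths = pd.Series(
        rng.integers(500, 5000, size=len(gene_ids) + design.n_spikeins).astype(float),
        index=gene_ids + spike_ids,
        name="length",
    )

    fold = pd.Series(1.0, index=gene_ids)
    planted_down = list(rng.choice(filler, size=design.n_planted_down, replace=False))
    fold[planted_down] = 1.0 / design.planted_down_fold
    tf_fold = {}
    for tf, cls in ((t, c) for t in tf_ids for c in ("lost", "gained")
                    if t in classes[c]):
        fold[tf] = (1.0 / design.tf_expression_fold if cls == "lost"
                    else design.tf_expression_fold)
        tf_fold[tf] = float(np.log2(fold[tf]))

    samples = [f"{cond}_{r + 1}" for cond in (CONTROL, TREATED)
               for r in range(design.replicates)]
    depths = rng.uniform(0.8, 1.2, size=len(samples)) * design.expression_depth
    cols = {}
    for s, depth in zip(samples, depths):
        treated = s.startswith(TREATED)
        lam_genes = mu * depth * (fold.to_numpy() if treated else 1.0)
        if treated:
            lam_genes = lam_genes * design.global_shift
        lam_spikes = conc * depth
        lam = np.concatenate([lam_genes, lam_spikes])
        cols[s] = (np.round(lam) if design.noise == "exact"
                   else rng.poisson(lam)).astype(int)
    counts = pd.DataFrame(cols, index=gene_ids + spike_ids)
    truth = {
        "samples": samples,
        "design": {
            "control": [s for s in samples if s.startswith(CONTROL)],
            "treated": [s for s in samples if s.startswith(TREATED)],
        },
        "true_depths": {s: float(d) for s, d in zip(samples, depths)},
        "planted_down_genes": planted_down,
        "planted_down_log2fc": float(-np.log2(design.planted_down_fold)),
        "tf_expression_log2fc": tf_fold,
        "global_shift": design.global_shift,
        "global_shift_log2": float(np.log2(design.global_shift)),
    }
    return counts, lengths, truth


def simulate_read_placements(
    blocks: Sequence[GenomicInterval],
    reads_per_block: int,
    rng: np.random.Generator,
    read_length: int = 200,
) -> list[ReadPlacement]:
    """Uniform read placements inside planted blocks — demonstrative input for
    the read-extension / binning stage (bin-level tracks are the primary
    simulation path)."""
    reads: list[ReadPlacement] = []
    for block in blocks:
        lo = block.start
        hi = max(lo + 1, block.end - read_length)
        positions = rng.integers(lo, hi, size=reads_per_block)
        strands = rng.choice(["+", "-"], size=reads_per_block)
        reads.extend(
            ReadPlacement(block.chrom, int(p), str(s))
            for p, s in zip(positions, strands)
        )
    return reads
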