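"""Core regulatory circuitry (CRC) inference from TF occupancy.

A CRC is a set of transcription factors, each driven by a super-enhancer,
that bind their own and each other's super-enhancers — an interconnected
autoregulatory loop. The module builds a genome-wide region-by-target
occupancy matrix (rows enriched for at least one target, ranked by integrated
H3K27ac), calls per-region enrichment of each TF against an IgG control,
derives a directed TF -> TF-gene binding graph per condition, extracts the
fully interconnected member set, and compares circuits across conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coverage import RPM, CoverageTrack, region_density
from .intervals import GenomicInterval

__all__ = [
    "OccupancyMatrix",
    "CRCGraph",
    "enrichment_call",
    "build_occupancy_matrix",
    "infer_crc",
    "compare_crcs",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_FOLD = 3.0
DEFAULT_FLOOR = 0.5  # per-bin RPM floor on the control density


def enrichment_call(
    target_track: CoverageTrack,
    region: GenomicInterval,
    control_track: CoverageTrack,
    min_fold: float = DEFAULT_MIN_FOLD,
    floor: float = DEFAULT_FLOOR,
) -> bool:
    """True iff the target's mean per-bin RPM in the region is at least
    ``min_fold`` times the control (IgG) density, where the control density is
    floored at ``floor`` RPM per bin to keep near-empty controls from blowing
    the ratio up."""
    if target_track.units != RPM or control_track.units != RPM:
        raise ValueError("enrichment calls expect RPM tracks")
    target = region_density(target_track, region)
    control = max(region_density(control_track, region), floor)
    return bool(target >= min_fold * control)


@dataclass
class OccupancyMatrix:
    """Region-by-target signal matrix; rows are regions enriched for at least
    one non-control target, ordered by descending integrated H3K27ac."""

    regions: list[GenomicInterval]
    targets: list[str]
    values: np.ndarray  # regions x targets, per-bin RPM density
    h3k27ac_target: str = "H3K27ac"

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{r.chrom}:{r.start}-{r.end}" for r in self.regions]
        return pd.DataFrame(self.values, index=idx, columns=self.targets)


def build_occupancy_matrix(
    tracks: Mapping[str, CoverageTrack],
    candidate_regions: Sequence[GenomicInterval],
    control: str = "IgG",
    h3k27ac: str = "H3K27ac",
    min_fold: float = DEFAULT_MIN_FOLD,
    floor: float = DEFAULT_FLOOR,
) -> OccupancyMatrix:
    """Retain candidate regions enriched for >= 1 non-control target, fill the
    signal matrix, and rank rows by descending H3K27ac signal."""
    if h3k27ac not in tracks:
        raise ValueError(f"H3K27ac track {h3k27ac!r} required")
    if control not in tracks:
        raise ValueError(f"control track {control!r} required")
    targets = list(tracks)
    kept: list[GenomicInterval] = []
    rows: list[list[float]] = []
    for region in candidate_regions:
        enriched = any(
            enrichment_call(tracks[t], region, tracks[control], min_fold, floor)
            for t in targets
            if t != control
        )
        if enriched:
            kept.append(region)
            rows.append([region_density(tracks[t], region) for t in targets])
    if not kept:
        log.warning("no region enriched for any target: empty occupancy matrix")
        return OccupancyMatrix([], targets, np.zeros((0, len(targets))), h3k27ac)
    values = np.array(rows)
    order = np.argsort(-values[:, targets.index(h3k27ac)], kind="stable")
    return OccupancyMatrix(
        [kept[i] for i in order], targets, values[order], h3k27ac
    )


@dataclass
class CRCGraph:
    """Directed TF -> TF-gene binding graph for one condition.

    An edge i -> j means TF i's binding is enriched at (any of) the
    super-enhancer(s) assigned to TF j's gene. Members form the largest
    admissible set that is a complete directed subgraph including self-loops:
    every member binds its own and every other member's super-enhancer.
    """

    condition: str
    candidates: list[str]
    admissible: list[str]
    edges: set[tuple[str, str]]
    members: list[str]

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "candidates": self.candidates,
            "admissible": self.admissible,
            "edges": sorted(self.edges),
            "members": self.members,
        }


def _max_complete_subgraph(
    nodes: Sequence[str], edges: set[tuple[str, str]]
) -> list[str]:
    """Largest node set fully interconnected under the directed edge set,
    self-loops required. Complete directed subgraphs correspond to cliques of
    the undirected "mutual edge" graph over self-loop nodes; candidate sets
    are small, so exact clique enumeration is cheap. Ties between equally
    large sets break to the lexicographically smallest, for determinism."""
    looped = [n for n in nodes if (n, n) in edges]
    g = nx.Graph()
    g.add_nodes_from(looped)
    for i in looped:
        for j in looped:
            if i < j and (i, j) in edges and (j, i) in edges:
                g.add_edge(i, j)
    best: list[str] = []
    for clique in nx.find_cliques(g):
        clique = sorted(clique)
        if len(clique) > len(best) or (len(clique) == len(best) and clique < best):
            best = clique
    return best


def infer_crc(
    condition: str,
    candidates: Sequence[str],
    se_assignments: Mapping[str, Sequence[GenomicInterval]],
    tf_tracks: Mapping[str, CoverageTrack],
    control_track: CoverageTrack,
    expressed_genes: set[str],
    min_fold: float = DEFAULT_MIN_FOLD,
    floor: float = DEFAULT_FLOOR,
    min_inbound: int | None = None,
) -> CRCGraph:
    """Infer the CRC for one condition.

    A candidate TF is admissible iff its gene is expressed and has at least
    one assigned super-enhancer in this condition. Edge i -> j is present iff
    TF i's track is enriched at any super-enhancer assigned to TF j. Members
    are the largest complete directed subgraph with self-loops; with
    ``min_inbound=k`` a relaxed rule is used instead (every member bound by
    >= k members, found by iterative pruning).
    """
    admissible = [
        tf
        for tf in candidates
        if tf in expressed_genes and se_assignments.get(tf)
    ]
    if not admissible:
        log.warning("condition %s: no admissible CRC candidates", condition)
        return CRCGraph(condition, list(candidates), [], set(), [])
    missing = [tf for tf in admissible if tf not in tf_tracks]
    if missing:
        raise ValueError(f"no occupancy track for candidate TFs {missing}")
    edges: set[tuple[str, str]] = set()
    for i in admissible:
        for j in admissible:
            bound = any(
                enrichment_call(tf_tracks[i], se, control_track, min_fold, floor)
                for se in se_assignments[j]
            )
            if bound:
                edges.add((i, j))
    if min_inbound is None:
        members = _max_complete_subgraph(admissible, edges)
    else:
        members = sorted(admissible)
        while True:
            inbound = {
                j: sum((i, j) in edges for i in members) for j in members
            }
            drop = [j for j in members if inbound[j] < min_inbound]
            if not drop:
                break
            members = [j for j in members if j not in drop]
    return CRCGraph(condition, list(candidates), admissible, edges, members)


def compare_crcs(graph_a: CRCGraph, graph_b: CRCGraph) -> dict[str, list[str]]:
    """Membership delta between two conditions: shared, lost (A only) and
    gained (B only). Symmetric under label swap (shared invariant, lost and
    gained exchange)."""
    if set(graph_a.candidates) != set(graph_b.candidates):
        raise ValueError("CRC graphs must share one candidate universe")
    a, b = set(graph_a.members), set(graph_b.members)
    return {
        "shared": sorted(a & b),
        "lost": sorted(a - b),
        "gained": sorted(b - a),
    }
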