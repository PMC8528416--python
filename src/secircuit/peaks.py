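"""Peak calling, collapsing and filtering ahead of super-enhancer stitching.

The built-in caller is deliberately simple plumbing — bins above a Poisson
upper-tail threshold, merged into runs — so the pipeline runs end-to-end on
simulated tracks; externally called peak files (e.g. MACS narrowPeak) are
accepted interchangeably through :func:`secircuit.formats.read_bed`.

The dual-parameter peak-calling convention (a strict and a lenient call whose
union is collapsed) and the removal of peaks contacting an amplified region
mirror common practice for H3K27ac input to enhancer stitching.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .coverage import RAW, CoverageTrack, region_signal
from .intervals import GenomicInterval, merge_intervals

__all__ = [
    "Peak",
    "call_peaks_simple",
    "call_peaks_dual",
    "collapse_peak_sets",
    "exclude_region",
]


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    score: float = 0.0  # mean signal within the peak, track units
    source: str = ""

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("peak score must be >= 0")


def call_peaks_simple(
    track: CoverageTrack,
    background_rate: float | str = "auto",
    p_threshold: float = 1e-9,
    min_len_bp: int = 100,
    source: str = "",
) -> list[Peak]:
    """Call peaks as runs of bins exceeding a Poisson upper-tail threshold.

    A bin is marked when its count exceeds the smallest k with
    ``P(Poisson(background_rate) >= k) <= p_threshold``; maximal runs of
    marked bins at least ``min_len_bp`` long become peaks. With
    ``background_rate="auto"`` the genome-wide mean bin count is used.
    """
    if track.units != RAW:
        raise ValueError("peak calling expects a raw-count track")
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    if background_rate == "auto":
        total_bins = sum(len(a) for a in track.bins.values())
        background_rate = track.total_signal() / total_bins if total_bins else 0.0
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    if track.total_signal() == 0:
        return []
    # isf gives the smallest k with sf(k-1) = P(X >= k) <= p; bins must reach it
    cutoff = float(stats.poisson.isf(p_threshold, max(background_rate, 1e-12)))
    bw = track.bin_width
    min_bins = max(1, int(np.ceil(min_len_bp / bw)))
    peaks: list[Peak] = []
    for chrom, arr in track.bins.items():
        marked = arr > cutoff
        if not marked.any():
            continue
        padded = np.concatenate([[False], marked, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_bins:
                iv = GenomicInterval(chrom, int(s) * bw, int(e) * bw)
                score = region_signal(track, iv) / (e - s)
                peaks.append(Peak(iv, score, source))
    return peaks


def call_peaks_dual(
    track: CoverageTrack,
    p_strict: float = 1e-9,
    p_lenient: float = 1e-4,
    min_len_bp: int = 100,
) -> list[Peak]:
    """Two calls at strict and lenient stringency, collapsed into one set —
    the dual-parameter convention used to seed enhancer stitching."""
    strict = call_peaks_simple(track, "auto", p_strict, min_len_bp, "strict")
    lenient = call_peaks_simple(track, "auto", p_lenient, min_len_bp, "lenient")
    return collapse_peak_sets([strict, lenient])


def collapse_peak_sets(sets: Sequence[Sequence[Peak]]) -> list[Peak]:
    """Collapsed union: overlapping or book-ended peaks across all sets are
    merged into maximal disjoint intervals, sorted; merged score is the max
    of constituent scores (advisory — signal is re-measured from tracks)."""
    all_peaks = [p for s in sets for p in s]
    merged = merge_intervals([p.interval for p in all_peaks], gap=0)
    out: list[Peak] = []
    for iv in merged:
        scores = [p.score for p in all_peaks if iv.overlaps(p.interval)]
        out.append(Peak(iv, max(scores) if scores else 0.0, "collapsed"))
    return out


def exclude_region(
    peaks: Sequence[Peak], exclusion: GenomicInterval
) -> list[Peak]:
    """Drop every peak contacting (>= 1 bp overlap) the exclusion region,
    e.g. an amplified locus whose copy number would dominate the ranking.
    Retained peaks are untouched."""
    return [p for p in peaks if not p.interval.overlaps(exclusion)]
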