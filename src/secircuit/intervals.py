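"""Genomic interval primitives.

Everything downstream — peaks, stitched enhancers, super-enhancer calls,
occupancy-matrix rows — is expressed in terms of :class:`GenomicInterval`.
Coordinates are 0-based half-open throughout the package; formats that use
other conventions (WIG, 1-based config strings) are converted at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "ReadPlacement",
    "GeneAnnotation",
    "extend_reads",
    "merge_intervals",
    "parse_region_string",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥1 bp overlap under half-open arithmetic ("contact")."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class ReadPlacement:
    """A sequenced read reduced to its 5' position and strand."""

    chrom: str
    position_5prime: int
    strand: str = "+"


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene, one transcription start site."""

    gene_id: str
    gene_name: str
    chrom: str
    tss: int
    strand: str = "+"


def extend_reads(
    reads: Sequence[ReadPlacement],
    extension_bp: int,
    chrom_sizes: Mapping[str, int],
) -> list[GenomicInterval]:
    """Artificially extend each read to ``extension_bp`` in its strand direction.

    A plus-strand read at position p becomes ``[p, p+ext)``; a minus-strand
    read becomes ``[p-ext, p)``. Intervals are clipped at chromosome ends.
    """
    if extension_bp <= 0:
        raise ValueError("extension_bp must be positive")
    out: list[GenomicInterval] = []
    for read in reads:
        size = chrom_sizes.get(read.chrom)
        if size is None:
            raise KeyError(f"unknown chromosome {read.chrom!r}")
        if not (0 <= read.position_5prime <= size):
            raise ValueError(
                f"read at {read.chrom}:{read.position_5prime} outside "
                f"chromosome bounds [0, {size}]"
            )
        if read.strand == "-":
            start = max(0, read.position_5prime - extension_bp)
            end = read.position_5prime
        else:
            start = read.position_5prime
            end = min(size, read.position_5prime + extension_bp)
        # A read exactly at a chromosome edge clips to an empty span; keep a
        # 1-bp stub so output length equals input length.
        if start == end:
            start, end = max(0, start - 1), max(1, end)
        out.append(GenomicInterval(read.chrom, start, end, read.strand))
    return out


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= ``gap`` bp (0 merges overlapping and
    book-ended intervals). Output is sorted and pairwise disjoint with
    inter-interval gaps strictly greater than ``gap``.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= gap
        ):
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end, strand=".")
        else:
            merged.append(replace(iv, strand="."))
    return merged


def parse_region_string(text: str) -> GenomicInterval:
    """Parse a ``chrom:start-end`` config string, 1-based inclusive, into the
    internal 0-based half-open convention.

    ``chr2: 14817188-17228298`` -> GenomicInterval("chr2", 14817187, 17228298).
    """
    chrom, _, span = text.replace(" ", "").partition(":")
    lo, _, hi = span.partition("-")
    if not (chrom and lo and hi):
        raise ValueError(f"cannot parse region string {text!r}")
    start1, end1 = int(lo.replace(",", "")), int(hi.replace(",", ""))
    return GenomicInterval(chrom, start1 - 1, end1)
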