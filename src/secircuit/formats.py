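"""Readers and writers for the plain-text genomics formats the pipeline
speaks: BED3/BED6, narrowPeak, fixedStep WIG, bedGraph, chrom.sizes, a TSS
annotation table and gene-by-sample count tables.

Coordinate conventions: BED, narrowPeak and bedGraph are 0-based half-open
(the internal convention); WIG fixedStep is 1-based and converted on I/O.
Malformed lines are rejected with their line number.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import RAW, RPM, CoverageTrack
from .intervals import GeneAnnotation, GenomicInterval

__all__ = [
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_annotation",
    "write_annotation",
    "read_counts",
    "write_counts",
    "read_wig",
    "write_wig",
    "read_bedgraph",
    "write_bedgraph",
]


class FormatError(ValueError):
    """Malformed line in a genomics text file."""


def _fail(path, lineno: int, msg: str) -> None:
    raise FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------- BED


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6/narrowPeak intervals (first 6 columns honored)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                _fail(path, lineno, "expected at least 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None:
                cols.append(names[i] if names is not None else f"region_{i + 1}")
                cols.append(f"{scores[i]:g}" if scores is not None else "0")
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


# -------------------------------------------------------------- chrom.sizes


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                _fail(path, lineno, "expected 'chrom<TAB>size'")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError:
                _fail(path, lineno, "non-integer size")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# --------------------------------------------------------------- annotation


_ANNOT_COLS = ["gene_id", "gene_name", "chrom", "tss", "strand"]


def read_annotation(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    return [
        GeneAnnotation(r.gene_id, r.gene_name, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples()
    ]


def write_annotation(genes: Sequence[GeneAnnotation], path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.gene_name, g.chrom, g.tss, g.strand) for g in genes],
        columns=_ANNOT_COLS,
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- count tables


def read_counts(path) -> pd.DataFrame:
    """Gene-by-sample integer count table; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------- WIG


def write_wig(track: CoverageTrack, path, name: str = "coverage") -> None:
    """fixedStep WIG with step = span = bin width (1-based starts)."""
    bw = track.bin_width
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom, arr in track.bins.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step={bw} span={bw}\n")
            fh.write("\n".join(f"{v:g}" for v in arr) + "\n")


def read_wig(
    path,
    chrom_sizes: Mapping[str, int] | None = None,
    units: str = RAW,
    mapped_reads: int = 0,
) -> CoverageTrack:
    """Read fixedStep WIG into a binned track (1-based WIG -> 0-based bins)."""
    values: dict[str, dict[int, float]] = {}
    bin_width = None
    chrom = None
    pos0 = step = span = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                kv = dict(
                    tok.split("=", 1) for tok in line.split()[1:] if "=" in tok
                )
                try:
                    chrom = kv["chrom"]
                    pos0 = int(kv["start"]) - 1  # 1-based -> 0-based
                    step = int(kv.get("step", kv.get("span", 1)))
                    span = int(kv.get("span", step))
                except (KeyError, ValueError):
                    _fail(path, lineno, "malformed fixedStep header")
                if pos0 % step != 0:
                    _fail(path, lineno, "fixedStep start not on the bin grid")
                if bin_width is None:
                    bin_width = span
                elif span != bin_width:
                    _fail(path, lineno, "inconsistent span across blocks")
                values.setdefault(chrom, {})
            elif line.startswith("variableStep"):
                _fail(path, lineno, "variableStep WIG is not supported")
            else:
                if chrom is None:
                    _fail(path, lineno, "data line before fixedStep header")
                try:
                    val = float(line)
                except ValueError:
                    _fail(path, lineno, f"non-numeric value {line!r}")
                values[chrom][pos0 // step] = val
                pos0 += step
    if bin_width is None:
        raise FormatError(f"{path}: no fixedStep blocks found")
    bins: dict[str, np.ndarray] = {}
    for c, d in values.items():
        if chrom_sizes is not None and c in chrom_sizes:
            n = max(1, math.ceil(chrom_sizes[c] / bin_width))
        else:
            n = max(d) + 1
        arr = np.zeros(n)
        idx = np.fromiter(d.keys(), dtype=int)
        arr[idx] = np.fromiter(d.values(), dtype=float)
        bins[c] = arr
    return CoverageTrack(bins, bin_width, units, mapped_reads)


# ----------------------------------------------------------------- bedGraph


def write_bedgraph(track: CoverageTrack, path) -> None:
    """bedGraph with runs of equal-valued bins collapsed (zeros omitted)."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom, arr in track.bins.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s * bw}\t{e * bw}\t{arr[s]:g}\n")


def read_bedgraph(
    path,
    chrom_sizes: Mapping[str, int],
    bin_width: int = 50,
    units: str = RAW,
    mapped_reads: int = 0,
) -> CoverageTrack:
    """Read bedGraph whose intervals align to the bin grid."""
    bins = {
        c: np.zeros(max(1, math.ceil(size / bin_width)))
        for c, size in chrom_sizes.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                _fail(path, lineno, "expected 4 bedGraph columns")
            chrom = fields[0]
            if chrom not in bins:
                _fail(path, lineno, f"unknown chromosome {chrom!r}")
            try:
                start, end, val = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                _fail(path, lineno, "malformed coordinates or value")
            if start % bin_width != 0 or (
                end % bin_width != 0 and end < len(bins[chrom]) * bin_width
            ):
                _fail(path, lineno, "interval not aligned to the bin grid")
            bins[chrom][start // bin_width : math.ceil(end / bin_width)] = val
    return CoverageTrack(bins, bin_width, units, mapped_reads)
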