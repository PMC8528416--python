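"""Spike-in normalized expression analysis.

External RNA spike-ins (ERCC) are added in amounts proportional to cell
number, so their counts report sequencing depth independently of the
biological transcriptome. Size factors computed from spike-in rows alone
(median-of-ratios against a geometric-mean pseudo-reference) therefore
preserve global expression shifts that library-size or TPM normalization
cancels by construction — the property that lets a treatment halving the
whole transcriptome show up as a median log2 fold change of -1 instead of 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPIKEIN_PREFIX",
    "spikein_mask",
    "spikein_size_factors",
    "library_size_factors",
    "tpm",
    "fold_changes",
]

SPIKEIN_PREFIX = "ERCC-"
DEFAULT_PSEUDOCOUNT = 0.5  # normalized counts, for log2 fold changes
DEFAULT_TPM_FILTER = 10.0  # base mean TPM must strictly exceed this


def spikein_mask(counts: pd.DataFrame, prefix: str = SPIKEIN_PREFIX) -> pd.Series:
    return counts.index.to_series().str.startswith(prefix)


def spikein_size_factors(
    counts: pd.DataFrame, prefix: str = SPIKEIN_PREFIX
) -> pd.Series:
    """Per-sample size factors from spike-in rows only.

    Median-of-ratios: each sample's factor is the median, over spike-ins with
    nonzero counts in every sample, of count / geometric-mean-across-samples.
    Factors are then rescaled so the median sample factor is 1, anchoring the
    unperturbed majority — this makes a sample whose counts are all doubled
    get a factor of exactly 2, and normalized counts invariant to per-sample
    rescaling.
    """
    spikes = counts.loc[spikein_mask(counts, prefix)]
    shared = spikes.loc[(spikes > 0).all(axis=1)]
    if shared.empty:
        raise ValueError("no spike-in row is nonzero in every sample")
    logs = np.log(shared.to_numpy(dtype=float))
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    factors = factors / np.median(factors)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def library_size_factors(
    counts: pd.DataFrame, prefix: str = SPIKEIN_PREFIX
) -> pd.Series:
    """Total-count (library size) factors over biological genes only — the
    relative normalization spike-ins are designed to outperform under global
    shifts; kept for head-to-head comparison."""
    totals = counts.loc[~spikein_mask(counts, prefix)].sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("a sample has zero biological counts")
    factors = totals / np.median(totals)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def tpm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    prefix: str = SPIKEIN_PREFIX,
) -> pd.DataFrame:
    """Transcripts per million: rate = count / effective length (kb-free,
    units cancel); TPM = rate * 1e6 / sum(rates). Spike-in rows are excluded
    from the denominator so TPM reflects the biological transcriptome; their
    rows still receive values on the same scale.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive effective length")
    rates = counts.div(lengths, axis=0)
    denom = rates.loc[~spikein_mask(counts, prefix)].sum(axis=0)
    if (denom <= 0).any():
        raise ValueError("a sample has zero total biological rate")
    return rates.div(denom, axis=1) * 1e6


def fold_changes(
    counts: pd.DataFrame,
    lengths: pd.Series,
    design: Mapping[str, Sequence[str]],
    factors: pd.Series | None = None,
    filter_tpm: float = DEFAULT_TPM_FILTER,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prefix: str = SPIKEIN_PREFIX,
) -> pd.DataFrame:
    """Per-gene spike-in-scaled log2 fold changes (treated vs control).

    ``design`` maps ``{"control": [samples...], "treated": [samples...]}``.
    Counts are divided by per-sample size factors (spike-in factors unless
    given), averaged within condition, and compared with a pseudocount.
    ``base_mean_tpm`` is the mean TPM across all samples; ``passes_filter``
    is the strict base-mean TPM > ``filter_tpm`` rule used to restrict the
    fold-change distribution to highly expressed genes. Spike-in rows are
    dropped from the result.
    """
    for cond in ("control", "treated"):
        if cond not in design or not design[cond]:
            raise ValueError(f"design is missing samples for {cond!r}")
        missing = [s for s in design[cond] if s not in counts.columns]
        if missing:
            raise ValueError(f"samples {missing} not in count table")
    if factors is None:
        factors = spikein_size_factors(counts, prefix)
    normalized = counts.div(factors, axis=1)
    mean_control = normalized[list(design["control"])].mean(axis=1)
    mean_treated = normalized[list(design["treated"])].mean(axis=1)
    lfc = np.log2((mean_treated + pseudocount) / (mean_control + pseudocount))
    base_mean = tpm(counts, lengths, prefix).mean(axis=1)
    result = pd.DataFrame(
        {
            "gene": counts.index,
            "base_mean_tpm": base_mean.to_numpy(),
            "log2_fold_change": lfc.to_numpy(),
            "passes_filter": (base_mean > filter_tpm).to_numpy(),
        }
    ).set_index("gene")
    return result.loc[~spikein_mask(counts, prefix).to_numpy()]
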