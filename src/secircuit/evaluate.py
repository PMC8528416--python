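"""Recovery metrics against a planted ground-truth manifest.

Used by the test suite, the acceptance script and the ``run-all`` report to
score each pipeline stage on synthetic data: super-enhancer identification
(F1 against planted spans), differential gained/lost classification
(sensitivity and precision), and circuit membership (exact set recovery).
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .intervals import GenomicInterval
from .landscape import DifferentialRegion
from .rose import SuperEnhancerCall

__all__ = [
    "jaccard",
    "se_recovery_f1",
    "differential_scores",
    "crc_recovered_exactly",
]


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    union = max(a.end, b.end) - min(a.start, b.start)
    return inter / union


def se_recovery_f1(
    calls: Sequence[SuperEnhancerCall],
    planted_spans: Sequence[GenomicInterval],
    min_jaccard: float = 0.5,
) -> float:
    """F1 of called super-enhancer regions against planted spans; a planted
    span counts as recovered when some called region matches it at Jaccard >=
    ``min_jaccard`` (one-to-one, greedy by overlap)."""
    called = [c.region for c in calls if c.is_super]
    unmatched = list(called)
    tp = 0
    for span in planted_spans:
        best_i, best_j = -1, 0.0
        for i, region in enumerate(unmatched):
            j = jaccard(region, span)
            if j > best_j:
                best_i, best_j = i, j
        if best_j >= min_jaccard:
            tp += 1
            unmatched.pop(best_i)
    fp = len(unmatched)
    fn = len(planted_spans) - tp
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def differential_scores(
    results: Sequence[DifferentialRegion],
    truth_spans: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, float]:
    """Sensitivity and precision of gained/lost calls.

    ``truth_spans`` maps label -> planted spans ("lost", "gained", "stable").
    Each result region inherits the label of the planted span it overlaps.
    A gained/lost call is correct when it matches its region's true label;
    sensitivity is over all truly gained/lost regions, precision over all
    gained/lost calls.
    """
    def true_label(region: GenomicInterval) -> str | None:
        for label, spans in truth_spans.items():
            if any(region.overlaps(s) for s in spans):
                return label
        return None

    tp = fp = fn = 0
    for r in results:
        truth = true_label(r.region)
        if truth in ("gained", "lost"):
            if r.status == truth:
                tp += 1
            else:
                fn += 1
                if r.status in ("gained", "lost"):
                    fp += 1
        elif r.status in ("gained", "lost"):
            fp += 1
    sensitivity = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    return {"sensitivity": sensitivity, "precision": precision}


def crc_recovered_exactly(
    members: Sequence[str], true_members: Sequence[str]
) -> bool:
    return sorted(members) == sorted(true_members)
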