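"""Evaluation metrics: discrimination accuracy and Jaccard similarity.

Discrimination accuracy treats screening as a binary segment classifier
(noisy vs clean) and reports ``100 * (TP + TN) / (TP + TN + FP + FN)`` to
two decimal places.

The Jaccard similarity coefficient (JSC) between two signals normalized to
[0, 1] uses the fuzzy-set reading of intersection and union:
``JSC = sum(min(f, g)) / sum(max(f, g))``, 1 when both sums vanish.  After
noise removal the processed record is shorter than the reference, so the
before/after comparison restricts both signals to the retained segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .screening import GroupStatistics, NoiseCallSet

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "accuracy_d",
    "normalize_unit",
    "jaccard_similarity",
    "compare_removal",
    "group_breakdown",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _truth_mask(truth_labels: Sequence) -> np.ndarray:
    """Noisy-segment mask from labels: anything but 'clean'/False counts as noise."""
    return np.array(
        [bool(lab) and lab != "clean" for lab in truth_labels], dtype=bool
    )


def confusion_counts(truth_labels: Sequence, calls: NoiseCallSet) -> ConfusionCounts:
    """Tally TP/TN/FP/FN; a segment is predicted noisy iff it is in P1 ∪ P2."""
    truth = _truth_mask(truth_labels)
    if truth.size != calls.n_segments:
        raise ValueError(
            f"{truth.size} truth labels but call set covers {calls.n_segments} segments"
        )
    predicted = np.zeros(calls.n_segments, dtype=bool)
    predicted[list(calls.removed)] = True
    return ConfusionCounts(
        tp=int(np.sum(truth & predicted)),
        tn=int(np.sum(~truth & ~predicted)),
        fp=int(np.sum(~truth & predicted)),
        fn=int(np.sum(truth & ~predicted)),
    )


def accuracy_d(counts: ConfusionCounts) -> float:
    """Discrimination accuracy in percent, rounded to 2 decimal places."""
    if counts.total < 1:
        raise ValueError("confusion counts are empty")
    return round(100.0 * (counts.tp + counts.tn) / counts.total, 2)


def normalize_unit(x) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant signal maps to all zeros."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def jaccard_similarity(f, f_hat) -> float:
    """Fuzzy Jaccard similarity of two [0, 1]-valued signals of equal length."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(f_hat, dtype=float)
    if f.shape != g.shape:
        raise ValueError(f"length mismatch: {f.shape} vs {g.shape}")
    for name, arr in (("f", f), ("f_hat", g)):
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValueError(f"{name} must be normalized to [0, 1]")
    union = np.maximum(f, g).sum()
    if union == 0.0:
        return 1.0
    return float(np.minimum(f, g).sum() / union)


def compare_removal(
    reference, noisy, calls: NoiseCallSet, segment_length: int
) -> Tuple[float, float]:
    """JSC of the noisy record before and after screen-based removal.

    Both coefficients are against the reference; the "processed" one keeps
    only the retained segments of both signals, each pair min-max normalized
    over the samples actually compared.  Returns
    ``(jsc_noisy, jsc_processed)``.
    """
    ref = np.asarray(reference, dtype=float).ravel()
    noi = np.asarray(noisy, dtype=float).ravel()
    if ref.size != noi.size:
        raise ValueError("reference and noisy records differ in length")
    m = calls.n_segments
    usable = m * segment_length
    if usable > ref.size:
        raise ValueError("call set covers more samples than the records hold")
    ref, noi = ref[:usable], noi[:usable]

    jsc_noisy = jaccard_similarity(normalize_unit(ref), normalize_unit(noi))

    keep = np.ones(m, dtype=bool)
    keep[list(calls.removed)] = False
    mask = np.repeat(keep, segment_length)
    jsc_processed = jaccard_similarity(
        normalize_unit(ref[mask]), normalize_unit(noi[mask])
    )
    return jsc_noisy, jsc_processed


def group_breakdown(
    truth_labels: Sequence, calls: NoiseCallSet, groups: Optional[GroupStatistics]
) -> pd.DataFrame:
    """Per-group confusion table with the columns of the method's summary
    table: group number (1-based), correctly and incorrectly discriminated
    counts, TP/TN/FP/FN, accuracy and error percentages; a final row gives
    the totals."""
    truth = _truth_mask(truth_labels)
    predicted = np.zeros(calls.n_segments, dtype=bool)
    predicted[list(calls.removed)] = True
    if groups is None:
        assignment = np.zeros(calls.n_segments, dtype=int)
        n_groups = 1
    else:
        assignment = groups.group_of_segment
        n_groups = groups.group_count

    rows = []
    for g in range(n_groups):
        sel = assignment == g
        c = ConfusionCounts(
            tp=int(np.sum(truth[sel] & predicted[sel])),
            tn=int(np.sum(~truth[sel] & ~predicted[sel])),
            fp=int(np.sum(~truth[sel] & predicted[sel])),
            fn=int(np.sum(truth[sel] & ~predicted[sel])),
        )
        acc = accuracy_d(c)
        rows.append(
            {
                "no": g + 1,
                "correct": c.tp + c.tn,
                "incorrect": c.fp + c.fn,
                "tp": c.tp,
                "tn": c.tn,
                "fp": c.fp,
                "fn": c.fn,
                "accuracy_pct": acc,
                "error_pct": round(100.0 - acc, 2),
            }
        )
    total = confusion_counts(truth_labels, calls)
    acc = accuracy_d(total)
    rows.append(
        {
            "no": "total",
            "correct": total.tp + total.tn,
            "incorrect": total.fp + total.fn,
            "tp": total.tp,
            "tn": total.tn,
            "fp": total.fp,
            "fn": total.fn,
            "accuracy_pct": acc,
            "error_pct": round(100.0 - acc, 2),
        }
    )
    return pd.DataFrame(rows)
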