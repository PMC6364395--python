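"""Edge-detection scoring of inferred networks against a reference.

Edges are binary calls (|weight| above a tolerance); detection quality is
summarized by accuracy, sensitivity, specificity and Matthews correlation
coefficient over the elementwise confusion counts, plus a squared-Frobenius
reconstruction error on the weighted matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "ConfusionCounts",
    "edge_support",
    "confusion",
    "metrics",
    "reconstruction_error",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN of edge detection; positives are edges present in the reference."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def edge_support(A: ArrayLike, tol: float = 0.0) -> NDArray[np.bool_]:
    """Binary support of a weighted matrix: ``|A_ij| > tol`` (strict)."""
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    return np.abs(np.asarray(A, dtype=float)) > tol


def confusion(
    ref: ArrayLike,
    est: ArrayLike,
    mask_diagonal: bool = False,
) -> ConfusionCounts:
    """Elementwise 2x2 tabulation of estimated vs reference edge calls.

    Self-loop (diagonal) entries are scored by default; ``mask_diagonal``
    excludes them.
    """
    r = np.asarray(ref, dtype=bool)
    e = np.asarray(est, dtype=bool)
    if r.shape != e.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {e.shape}")
    if mask_diagonal:
        keep = ~np.eye(r.shape[0], dtype=bool)
        r, e = r[keep], e[keep]
    return ConfusionCounts(
        tp=int(np.count_nonzero(r & e)),
        tn=int(np.count_nonzero(~r & ~e)),
        fp=int(np.count_nonzero(~r & e)),
        fn=int(np.count_nonzero(r & ~e)),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and MCC from confusion counts.

    acc = (TP + TN) / (TP + TN + FP + FN), sen = TP / (TP + FN),
    spe = TN / (TN + FP), mcc = (TP*TN - FP*FN) / sqrt of the product of the
    four marginal totals.  Any zero factor in the MCC denominator yields
    mcc = 0 by convention, and an empty sensitivity/specificity denominator
    yields 0 as well.
    """
    if c.total == 0:
        raise ValueError("cannot score empty counts")
    tp, tn, fp, fn = (float(v) for v in (c.tp, c.tn, c.fp, c.fn))
    acc = (tp + tn) / (tp + tn + fp + fn)
    sen = tp / (tp + fn) if tp + fn > 0 else 0.0
    spe = tn / (tn + fp) if tn + fp > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return {"acc": acc, "sen": sen, "spe": spe, "mcc": mcc}


def reconstruction_error(
    ref: Sequence[ArrayLike],
    est: Sequence[ArrayLike],
) -> float:
    """Squared Frobenius reconstruction error summed over epochs.

    ``sum_k ||A_ref(k) - A_est(k)||_F^2``; symmetric in its arguments and
    zero iff the sequences are equal.
    """
    if len(ref) != len(est):
        raise ValueError(f"sequence length mismatch: {len(ref)} vs {len(est)}")
    total = 0.0
    for k, (a, b) in enumerate(zip(ref, est)):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch at epoch {k}: {a.shape} vs {b.shape}")
        total += float(np.sum((a - b) ** 2))
    return total
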