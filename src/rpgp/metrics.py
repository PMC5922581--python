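"""Confusion-count metrics: MCC, standardized fitness, accuracy measures.

The Matthews correlation coefficient (MCC) over confusion counts is the
fitness backbone of the GP classifier::

    MCC = (Ntp*Ntn - Nfp*Nfn) /
          sqrt((Ntn+Nfn)(Ntn+Nfp)(Ntp+Nfn)(Ntp+Nfp))

with MCC defined as exactly 0 whenever the denominator is 0. MCC equals
the Pearson correlation between the 0/1 prediction and truth vectors and
is robust to class imbalance. The standardized fitness maps it affinely
onto [0, 1]::

    fitness = (1 + MCC) / 2

Two accuracy conventions are exposed, matching how training and test
performance are conventionally reported for this classifier family:

* ``training_accuracy`` = MCC x 100 (can be negative by construction);
* ``test_accuracy``     = balanced accuracy x 100, the mean of sensitivity
  and specificity — which requires both classes present in the test fold.

``percent_correct`` (plain fraction correct x 100) is also provided for
sanity checks; it is deliberately a distinct name so the two "training
accuracy" notions cannot be confused.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "mcc",
    "standardized_fitness",
    "training_accuracy",
    "test_accuracy",
    "percent_correct",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of true/false positives/negatives for one classifier output."""

    n_tp: int
    n_tn: int
    n_fp: int
    n_fn: int

    def __post_init__(self) -> None:
        for name in ("n_tp", "n_tn", "n_fp", "n_fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total < 1:
            raise ValueError("confusion counts must cover at least one sample")

    @property
    def total(self) -> int:
        return self.n_tp + self.n_tn + self.n_fp + self.n_fn


def confusion(predictions, truth) -> ConfusionCounts:
    """Tabulate confusion counts of 0/1 predictions against 0/1 truth."""
    predictions = np.asarray(predictions, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predictions.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} predictions vs "
            f"{truth.shape} truth"
        )
    if predictions.size < 1:
        raise ValueError("need at least one sample")
    n_tp = int(np.sum((predictions == 1) & (truth == 1)))
    n_tn = int(np.sum((predictions == 0) & (truth == 0)))
    n_fp = int(np.sum((predictions == 1) & (truth == 0)))
    n_fn = int(np.sum((predictions == 0) & (truth == 1)))
    return ConfusionCounts(n_tp, n_tn, n_fp, n_fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when the denominator is 0."""
    tp, tn, fp, fn = float(c.n_tp), float(c.n_tn), float(c.n_fp), float(c.n_fn)
    denom = (tn + fn) * (tn + fp) * (tp + fn) * (tp + fp)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def standardized_fitness(mcc_value: float) -> float:
    """Map an MCC in [-1, 1] affinely onto [0, 1]; 1 is best."""
    if not -1.0 <= mcc_value <= 1.0:
        raise ValueError(f"MCC must lie in [-1, 1], got {mcc_value}")
    return (1.0 + mcc_value) / 2.0


def training_accuracy(c: ConfusionCounts) -> float:
    """Training-set performance: MCC x 100 (negative values possible)."""
    return mcc(c) * 100.0


def test_accuracy(c: ConfusionCounts) -> float:
    """Test-set performance: balanced accuracy x 100.

    Requires both classes in the evaluated set; use stratified folds.
    """
    pos = c.n_tp + c.n_fn
    neg = c.n_tn + c.n_fp
    if pos == 0 or neg == 0:
        raise ValueError(
            "balanced test accuracy needs both classes present in the fold; "
            "use stratified folds"
        )
    return 50.0 * (c.n_tp / pos + c.n_tn / neg)


def percent_correct(c: ConfusionCounts) -> float:
    """Plain fraction of correct predictions x 100 (sanity metric)."""
    return 100.0 * (c.n_tp + c.n_tn) / c.total
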