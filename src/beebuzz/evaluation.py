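"""Confusion counts, accuracy and F1-score.

Convention: the WORKER bee is the positive class. TP counts correctly
detected workers and TN correctly detected drones — the opposite of the
intuitive "detect the drone" framing, so metric code elsewhere must not
silently invert it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .exceptions import UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int  # workers called worker
    tn: int  # drones called drone
    fp: int  # drones called worker
    fn: int  # workers called drone

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionCounts:
    """Tally worker-positive confusion counts from parallel label lists."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    tp = tn = fp = fn = 0
    for truth, pred in zip(true_labels, predicted_labels):
        if truth not in ("worker", "drone") or pred not in ("worker", "drone"):
            raise ValueError(f"labels must be worker/drone, got ({truth!r}, {pred!r})")
        if truth == "worker":
            if pred == "worker":
                tp += 1
            else:
                fn += 1
        else:
            if pred == "drone":
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined for empty evaluation")
    return (c.tp + c.tn) / c.total


def f1_score(c: ConfusionCounts) -> float:
    """2 TP / (2 TP + FP + FN), worker as positive class."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise UndefinedMetricError("F1 undefined: no workers in truth or prediction")
    return 2 * c.tp / denom
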