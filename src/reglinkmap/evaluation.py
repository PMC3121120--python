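"""Binary-classifier evaluation of mapped sets against gold-standard lists.

A predicted id set is scored against a gold set within an explicit universe
(e.g. all target-genome sequences): true positives are predictions in the
gold set, false positives predictions outside it, false negatives gold
members missed, true negatives everything else.  Sensitivity and positive
predictive value follow; undefined ratios (empty denominators) are reported
as None, never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "ConfusionMatrix",
    "ComparisonDelta",
    "confusion",
    "summarize",
    "validate_confusion",
    "compare",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_predicted(self) -> int:
        return self.tp + self.fp

    @property
    def n_gold(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class ComparisonDelta:
    """Componentwise differences between two evaluations (A minus B)."""

    d_tp: int
    d_fp: int
    d_mapped: int


def confusion(predicted: Iterable, gold: Iterable, universe: Iterable) -> ConfusionMatrix:
    """Classify every universe element by membership in predicted/gold sets."""
    predicted, gold, universe = set(predicted), set(gold), set(universe)
    if not predicted <= universe:
        raise ValueError(
            f"predicted ids outside the universe: {sorted(predicted - universe)[:5]}"
        )
    if not gold <= universe:
        raise ValueError(
            f"gold ids outside the universe: {sorted(gold - universe)[:5]}"
        )
    tp = len(predicted & gold)
    return ConfusionMatrix(
        tp=tp,
        fp=len(predicted) - tp,
        fn=len(gold) - tp,
        tn=len(universe) - len(predicted | gold),
    )


def summarize(cm: ConfusionMatrix) -> dict:
    """Sensitivity TP/(TP+FN) and PPV TP/(TP+FP); None when undefined."""
    return {
        "sensitivity": cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None,
        "ppv": cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else None,
    }


def validate_confusion(
    cm: ConfusionMatrix, n_predicted: int, n_gold: int, n_universe: int
) -> bool:
    """Check the identities TP+FP = predictions, TP+FN = gold, sum = universe."""
    return (
        cm.n_predicted == n_predicted
        and cm.n_gold == n_gold
        and cm.universe_size == n_universe
    )


def compare(
    cmA: ConfusionMatrix, cmB: ConfusionMatrix, mappedA: int, mappedB: int
) -> ComparisonDelta:
    """Differences (A minus B) in TP, FP and mapped-element counts."""
    if cmA.universe_size != cmB.universe_size:
        raise ValueError(
            f"universe mismatch: {cmA.universe_size} vs {cmB.universe_size}"
        )
    return ComparisonDelta(
        d_tp=cmA.tp - cmB.tp,
        d_fp=cmA.fp - cmB.fp,
        d_mapped=mappedA - mappedB,
    )
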