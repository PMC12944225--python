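"""Minute-level one-vs-rest evaluation: confusion counts, accuracy,
sensitivity, specificity, precision and Cohen's kappa.

Each behaviour is scored against the gold standard after binarising both
label streams (target vs everything else).  Chance agreement for kappa uses
the product of the binary marginals,

    Pc = [(TP+FN)(TP+FP) + (TN+FP)(TN+FN)] / N²,

which is the standard two-rater construction and reproduces published
halter-sensor validation kappas from their printed counts.  Metrics with a
zero denominator are reported as NaN (an explicit "undefined" sentinel)
rather than 0, so sparse per-animal rows do not silently deflate a report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .io import BehaviourLabel, MinuteLabelSeries

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_counts",
    "compute_metrics",
    "per_animal_report",
    "TARGET_BEHAVIOURS",
]

TARGET_BEHAVIOURS = (
    BehaviourLabel.RUMINATION,
    BehaviourLabel.RESTING_IDLING,
    BehaviourLabel.EATING,
)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for one behaviour."""

    behaviour: BehaviourLabel
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def observed(self) -> int:
        """Minutes the gold standard assigned to the behaviour."""
        return self.tp + self.fn

    @property
    def detected(self) -> int:
        """Minutes the classifier assigned to the behaviour."""
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricSet:
    """Performance fractions; NaN marks an undefined (0-denominator) value."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    po: float
    pc: float
    kappa: float


def confusion_counts(
    observed: MinuteLabelSeries,
    predicted: MinuteLabelSeries,
    behaviour: BehaviourLabel,
) -> ConfusionCounts:
    """Binarise both aligned minute series for ``behaviour`` and count."""
    if observed.n_minutes != predicted.n_minutes:
        raise DataError(
            f"length mismatch: observed {observed.n_minutes} vs "
            f"predicted {predicted.n_minutes} minutes"
        )
    o = observed.labels == int(behaviour)
    p = predicted.labels == int(behaviour)
    return ConfusionCounts(
        behaviour=behaviour,
        tp=int(np.sum(o & p)),
        tn=int(np.sum(~o & ~p)),
        fp=int(np.sum(~o & p)),
        fn=int(np.sum(o & ~p)),
    )


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity, precision and kappa from counts."""
    n = c.n
    if n == 0:
        raise DataError("empty confusion counts")
    po = (c.tp + c.tn) / n
    sensitivity = c.tp / c.observed if c.observed > 0 else float("nan")
    specificity = (
        c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    )
    precision = c.tp / c.detected if c.detected > 0 else float("nan")
    pc = (c.observed * c.detected + (c.tn + c.fp) * (c.tn + c.fn)) / n**2
    kappa = (po - pc) / (1 - pc) if pc < 1.0 else float("nan")
    return MetricSet(
        accuracy=po,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        po=po,
        pc=pc,
        kappa=kappa,
    )


def _report_row(animal: str, c: ConfusionCounts) -> dict:
    m = compute_metrics(c)
    return {
        "animal": animal,
        "behaviour": c.behaviour.name.lower(),
        "duration_min": c.n,
        "observed": c.observed,
        "detected": c.detected,
        "tp": c.tp,
        "tn": c.tn,
        "fp": c.fp,
        "fn": c.fn,
        "accuracy": m.accuracy,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "precision": m.precision,
        "kappa": m.kappa,
    }


def per_animal_report(
    pairs: list[tuple[MinuteLabelSeries, MinuteLabelSeries, str]],
    behaviours: tuple[BehaviourLabel, ...] = TARGET_BEHAVIOURS,
) -> pd.DataFrame:
    """Per-animal and pooled performance table.

    One row per animal × behaviour plus a ``pooled`` row per behaviour that
    accumulates counts over all animals (the whole-dataset view).
    """
    if not pairs:
        raise DataError("need at least one (observed, predicted, animal) pair")
    rows = []
    for behaviour in behaviours:
        total = ConfusionCounts(behaviour, 0, 0, 0, 0)
        for observed, predicted, animal in pairs:
            c = confusion_counts(observed, predicted, behaviour)
            rows.append(_report_row(animal, c))
            total = ConfusionCounts(
                behaviour,
                total.tp + c.tp,
                total.tn + c.tn,
                total.fp + c.fp,
                total.fn + c.fn,
            )
        rows.append(_report_row("pooled", total))
    return pd.DataFrame(rows)


def write_report_csv(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, index=False, float_format="%.4f")
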