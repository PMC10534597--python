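"""Confusion-matrix accounting and metrics for fall detectors.

Per-trial scoring follows the multiple-detection rule: every detection
beyond the first on a fall trial, and every detection at all on a non-fall
trial, is a false positive — so FP can exceed the number of trials.
Metrics are the four standard quotients (accuracy, sensitivity/recall,
specificity, precision); an undefined denominator yields ``None``, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ThresholdSet
from .validator import run_pipeline

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "score_trial",
    "score_stream",
    "compute_metrics",
    "evaluate_trials",
    "subclass_table",
    "sweep",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    def __iadd__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return self + other


@dataclass(frozen=True)
class MetricSet:
    """Fractions in [0, 1]; ``None`` where the denominator is zero."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None

    def as_percent(self, digits: int = 2) -> dict[str, float | None]:
        return {
            k: (None if v is None else round(100.0 * v, digits))
            for k, v in self.__dict__.items()
        }


def score_trial(trial_label: str, n_detections: int) -> ConfusionCounts:
    """Confusion increment for one labelled trial.

    A fall trial with k >= 1 detections scores one TP and k-1 FPs; with none,
    one FN.  A non-fall trial scores one TN with no detections, else k FPs.
    """
    if n_detections < 0:
        raise ValueError("n_detections must be >= 0")
    if trial_label == "fall":
        if n_detections == 0:
            return ConfusionCounts(fn=1)
        return ConfusionCounts(tp=1, fp=n_detections - 1)
    if trial_label == "non-fall":
        if n_detections == 0:
            return ConfusionCounts(tn=1)
        return ConfusionCounts(fp=n_detections)
    raise ValueError(f"trial_label must be 'fall' or 'non-fall', got {trial_label!r}")


def score_stream(
    truth: list[tuple[int, int, str]],
    detections,
    is_fall_class=None,
) -> ConfusionCounts:
    """Score detections against labelled intervals of a continuous stream.

    Overlap means at least one shared sample.  The first detection
    overlapping a fall interval scores it TP; further detections on the same
    interval, and detections overlapping no fall interval, are FPs.
    Unmatched fall intervals are FNs; non-fall intervals untouched by any
    detection are TNs.

    ``is_fall_class`` maps a class label to ground-truth polarity; the
    default treats labels containing the word "fall" (but not "near fall")
    as positives.
    """
    if is_fall_class is None:
        def is_fall_class(label: str) -> bool:
            return "fall" in label.lower() and "near" not in label.lower()

    spans = [(s, e) for s, e, _ in truth]
    for (s, e) in spans:
        if s > e:
            raise ValueError("truth interval with start > end")
    fall_idx = [i for i, (_, _, lab) in enumerate(truth) if is_fall_class(lab)]
    det_spans = [(d.start_index, d.end_index) for d in detections]

    def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
        return a[0] <= b[1] and b[0] <= a[1]

    counts = ConfusionCounts()
    matched: set[int] = set()
    for d in det_spans:
        hit = [i for i in fall_idx if overlaps(d, spans[i])]
        new = [i for i in hit if i not in matched]
        if new:
            matched.add(new[0])
            counts += ConfusionCounts(tp=1)
        else:
            counts += ConfusionCounts(fp=1)
    counts += ConfusionCounts(fn=len(fall_idx) - len(matched))
    for i, (s, e, lab) in enumerate(truth):
        if i in fall_idx:
            continue
        if not any(overlaps(d, (s, e)) for d in det_spans):
            counts += ConfusionCounts(tn=1)
    return counts


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """The four standard quotients; undefined denominators give ``None``."""

    def frac(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    total = c.tp + c.fp + c.tn + c.fn
    return MetricSet(
        accuracy=frac(c.tp + c.tn, total),
        sensitivity=frac(c.tp, c.tp + c.fn),
        specificity=frac(c.tn, c.tn + c.fp),
        precision=frac(c.tp, c.tp + c.fp),
    )


def evaluate_trials(
    trials,
    thresholds: ThresholdSet | None = None,
    apply_final_checks: bool = True,
) -> ConfusionCounts:
    """Run the full pipeline on each trial and accumulate the confusion."""
    thresholds = thresholds if thresholds is not None else ThresholdSet()
    counts = ConfusionCounts()
    for trial in trials:
        report = run_pipeline(trial.series, thresholds, apply_final_checks=apply_final_checks)
        counts += score_trial(trial.label, len(report.accepted))
    return counts


def subclass_table(trials, thresholds: ThresholdSet | None = None) -> pd.DataFrame:
    """Per-sub-class tallies: Totals, True, False, and False-2.

    "False-2" is the error count with the final validation checks disabled,
    quantifying how much the last stage contributes per activity class.
    """
    thresholds = thresholds if thresholds is not None else ThresholdSet()
    rows: dict[str, dict[str, int]] = {}
    for trial in trials:
        key = trial.sub_class or trial.label
        row = rows.setdefault(key, {"Totals": 0, "True": 0, "False": 0, "False-2": 0})
        row["Totals"] += 1
        k = len(run_pipeline(trial.series, thresholds).accepted)
        k2 = len(run_pipeline(trial.series, thresholds, apply_final_checks=False).accepted)
        if trial.label == "fall":
            row["True"] += int(k >= 1)
            row["False"] += int(k == 0) + max(0, k - 1)
            row["False-2"] += int(k2 == 0) + max(0, k2 - 1)
        else:
            row["True"] += int(k == 0)
            row["False"] += k
            row["False-2"] += k2
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def sweep(threshold_sets, trials) -> pd.DataFrame:
    """Evaluate a grid of threshold combinations over labelled trials.

    One row per combination with the confusion counts, the four metrics (as
    percentages) and the ROC pair (TPR, FPR = 1 − specificity).  Ordering
    follows the grid.
    """
    threshold_sets = list(threshold_sets)
    if not threshold_sets:
        raise ValueError("threshold grid must be non-empty")
    records = []
    for ts in threshold_sets:
        c = evaluate_trials(trials, ts)
        m = compute_metrics(c)
        pct = m.as_percent()
        records.append(
            {
                "min_limit": ts.min_limit,
                "max_limit": str(ts.max_limit),
                "sub_1": ts.sub_1,
                "fall_duration": ts.fall_duration,
                "fall_limitation": ts.fall_limitation,
                "max_limit_2": str(ts.max_limit_2),
                "TP": c.tp,
                "FP": c.fp,
                "TN": c.tn,
                "FN": c.fn,
                "accuracy_pct": pct["accuracy"],
                "sensitivity_pct": pct["sensitivity"],
                "specificity_pct": pct["specificity"],
                "precision_pct": pct["precision"],
                "tpr": m.sensitivity,
                "fpr": None if m.specificity is None else 1.0 - m.specificity,
            }
        )
    return pd.DataFrame.from_records(records)
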