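"""Stage one: turn a magnitude series into candidate falls.

A fall leaves a characteristic signature in the magnitude signal: a dip well
below gravity as the body drops (the *lows*), followed within about a second
by an impact spike (the *highs*), after which the signal settles back near g.
Stage one finds every low/high pairing compatible with that morphology:

1. classify each magnitude as low (< ``min_limit``) or high (> ``max_limit``);
2. cluster each class into *extreme sets* — maximal runs whose consecutive
   entry gaps never exceed ``sub_1`` — keeping each set's first and last member;
3. connect every low set to every high set whose finish-high entry lies at
   most ``fall_duration`` entry units after the start-low entry.

The output is deliberately permissive (one extreme set may appear in several
candidates); stage two (:mod:`accelfall.validator`) prunes it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .config import ResolvedThresholds, ThresholdSet, resolve_thresholds
from .core import AccelSeries, MagnitudeSeries, magnitude_series

__all__ = [
    "ExtremeSet",
    "CandidateFall",
    "CandidateStatus",
    "classify_extremes",
    "cluster_extremes",
    "connect_candidates",
    "detect",
    "detect_series",
]


@dataclass(frozen=True)
class ExtremeSet:
    """A maximal run of consecutive lows (or highs), kept as first/last only."""

    kind: str  # "low" | "high"
    first_index: int
    last_index: int
    first_entry: float
    last_entry: float

    def __post_init__(self) -> None:
        if self.first_index > self.last_index:
            raise ValueError("first_index must be <= last_index")
        if self.first_entry > self.last_entry:
            raise ValueError("first_entry must be <= last_entry")


class CandidateStatus(str, Enum):
    CANDIDATE = "candidate"
    KEPT_SHORTER = "kept-shorter"
    SHRUNK = "shrunk"
    REJECTED_SHARED = "rejected-shared"
    REJECTED_LONG = "rejected-long"
    REJECTED_CHECKS = "rejected-checks"
    ACCEPTED = "accepted"


@dataclass(frozen=True)
class CandidateFall:
    """A (start-low, finish-high) pairing: the span of a possible fall.

    ``start_index`` is the first member of the low set, ``end_index`` the
    last member of the high set; ``peak_index`` locates the maximum
    magnitude inside the span.  ``low_set`` / ``high_set`` identify which
    extreme sets formed the pairing, which the validator needs to detect
    shared extremes.
    """

    start_index: int
    end_index: int
    start_entry: float
    end_entry: float
    peak_index: int
    peak_magnitude: float
    low_set: ExtremeSet
    high_set: ExtremeSet
    status: CandidateStatus = CandidateStatus.CANDIDATE

    @property
    def span(self) -> float:
        """Entry span, finish-high minus start-low."""
        return self.end_entry - self.start_entry

    def with_status(self, status: CandidateStatus) -> "CandidateFall":
        return replace(self, status=status)


def classify_extremes(magnitudes, min_limit: float, max_limit: float):
    """Indices of low (< min_limit) and high (> max_limit) magnitudes.

    Comparisons are strict on both sides; a magnitude exactly at a limit is
    neither low nor high.
    """
    m = np.asarray(magnitudes, dtype=float)
    lows = np.flatnonzero(m < min_limit)
    highs = np.flatnonzero(m > max_limit)
    return lows, highs


def cluster_extremes(indices, entries, sub_1: float, kind: str) -> list[ExtremeSet]:
    """Partition sorted extreme indices into sets by entry gaps.

    A new set starts wherever the entry gap between consecutive extremes is
    strictly greater than ``sub_1``; a set may consist of a single sample.
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        return []
    entries = np.asarray(entries, dtype=float)
    e = entries[idx]
    # boundaries where the gap exceeds sub_1
    breaks = np.flatnonzero(np.diff(e) > sub_1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [
        ExtremeSet(
            kind=kind,
            first_index=int(idx[s]),
            last_index=int(idx[t]),
            first_entry=float(e[s]),
            last_entry=float(e[t]),
        )
        for s, t in zip(starts, ends)
    ]


def connect_candidates(
    low_sets: list[ExtremeSet],
    high_sets: list[ExtremeSet],
    fall_duration: float,
    magnitudes,
) -> list[CandidateFall]:
    """Pair low sets with high sets into candidate falls.

    A pairing requires the low set to precede the high set (positive span)
    and the span — finish-high entry minus start-low entry — to be at most
    ``fall_duration``.  Every admissible pairing is emitted; a set may
    participate in several candidates, to be resolved by the validator.
    Candidates are ordered by (start_entry, end_entry).
    """
    m = np.asarray(magnitudes, dtype=float)
    out: list[CandidateFall] = []
    for low in low_sets:
        for high in high_sets:
            span = high.last_entry - low.first_entry
            if 0 < span <= fall_duration:
                s, t = low.first_index, high.last_index
                peak = s + int(np.argmax(m[s : t + 1]))
                out.append(
                    CandidateFall(
                        start_index=s,
                        end_index=t,
                        start_entry=low.first_entry,
                        end_entry=high.last_entry,
                        peak_index=peak,
                        peak_magnitude=float(m[peak]),
                        low_set=low,
                        high_set=high,
                    )
                )
    out.sort(key=lambda c: (c.start_entry, c.end_entry))
    return out


def detect_series(
    mseries: MagnitudeSeries, resolved: ResolvedThresholds
) -> list[CandidateFall]:
    """Stage one on an already-reduced magnitude series."""
    lows, highs = classify_extremes(mseries.magnitudes, resolved.min_limit, resolved.max_limit)
    if lows.size == 0 or highs.size == 0:
        return []
    low_sets = cluster_extremes(lows, mseries.entries, resolved.sub_1, "low")
    high_sets = cluster_extremes(highs, mseries.entries, resolved.sub_1, "high")
    return connect_candidates(low_sets, high_sets, resolved.fall_duration, mseries.magnitudes)


def detect(series: AccelSeries, thresholds: ThresholdSet | None = None) -> list[CandidateFall]:
    """Run stage one on a raw tri-axial series.

    Returns the pre-validation candidate list; empty means "no fall".
    """
    thresholds = thresholds if thresholds is not None else ThresholdSet()
    ms = magnitude_series(series)
    resolved = resolve_thresholds(thresholds, ms.magnitudes)
    return detect_series(ms, resolved)
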