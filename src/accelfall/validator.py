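"""Stage two: validate candidate falls.

Three checks, applied in order, turn the permissive candidate list of
stage one into the final detections:

1. **Shared extremes** — when one low or high set participates in several
   candidates, only the candidate with the smallest entry span survives
   (a real fall is the tightest low→high pairing; the longer connections
   are artefacts of the many-to-many pairing).
2. **Long falls** — a candidate whose span exceeds ``fall_limitation`` is
   shrunk by moving its start to the classified-low sample closest to the
   impact that brings the span back within the limit; if no such low
   exists the candidate is rejected (real falls are short).
3. **Final assumptions** — a surviving candidate is accepted if at least
   one of the following holds:

   A. *post-fall stability*: over the window of ``stability_window`` entry
      units after the fall, the magnitude mean is within ``mean_tol`` of g
      and the standard deviation is at most ``std_tol`` (the person is on
      the ground, the sensor reads gravity);
   B. *peak dominance*: the fall's peak magnitude strictly exceeds every
      magnitude above ``max_limit_2`` within ``dist_1`` entries before the
      start or ``dist_2`` after the end (the impact is the dominant event
      in its neighbourhood).

Candidates failing both are rejected; everything that survives is an
accepted fall with concrete start/end timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import ResolvedThresholds, ThresholdSet, resolve_thresholds
from .core import STANDARD_GRAVITY, AccelSeries, MagnitudeSeries, magnitude_series
from .detector import CandidateFall, CandidateStatus, classify_extremes, detect_series

__all__ = [
    "AcceptedFall",
    "ValidationReport",
    "resolve_shared_extremes",
    "shrink_or_reject_long",
    "final_checks",
    "validate",
    "run_pipeline",
]


@dataclass(frozen=True)
class AcceptedFall:
    """A validated fall with its concrete time range."""

    start_index: int
    end_index: int
    start_time_s: float
    end_time_s: float
    start_entry: float
    end_entry: float
    peak_index: int
    peak_magnitude: float


@dataclass
class ValidationReport:
    """Outcome of stage two: accepted falls plus a per-candidate audit trail.

    ``trail`` records every status transition as
    ``(candidate, check, resulting status)`` where check is one of
    shared-extreme | long-shrunk | long-rejected | stability-pass |
    peak-pass | rejected-checks.
    """

    accepted: list[AcceptedFall] = field(default_factory=list)
    trail: list[tuple[CandidateFall, str, CandidateStatus]] = field(default_factory=list)
    n_candidates: int = 0

    @property
    def is_fall(self) -> bool:
        return len(self.accepted) > 0

    def log(self, cand: CandidateFall, check: str, status: CandidateStatus) -> CandidateFall:
        cand = cand.with_status(status)
        self.trail.append((cand, check, status))
        return cand


def _shares_extreme(a: CandidateFall, b: CandidateFall) -> bool:
    return a.low_set == b.low_set or a.high_set == b.high_set


def resolve_shared_extremes(
    candidates: list[CandidateFall], report: ValidationReport | None = None
) -> list[CandidateFall]:
    """Keep only the shortest candidate among those sharing an extreme set.

    Deterministic fixpoint: repeatedly take the globally shortest remaining
    candidate (ties broken by earlier start, then earlier end), keep it, and
    discard every other candidate sharing its low or high set.
    """
    pool = sorted(candidates, key=lambda c: (c.span, c.start_entry, c.end_entry))
    kept: list[CandidateFall] = []
    while pool:
        winner = pool.pop(0)
        losers = [c for c in pool if _shares_extreme(winner, c)]
        if losers and report is not None:
            winner = report.log(winner, "shared-extreme", CandidateStatus.KEPT_SHORTER)
            for c in losers:
                report.log(c, "shared-extreme", CandidateStatus.REJECTED_SHARED)
        kept.append(winner)
        pool = [c for c in pool if not _shares_extreme(winner, c)]
    kept.sort(key=lambda c: (c.start_entry, c.end_entry))
    return kept


def shrink_or_reject_long(
    candidates: list[CandidateFall],
    low_indices,
    entries,
    magnitudes,
    fall_limitation: float,
    report: ValidationReport | None = None,
) -> list[CandidateFall]:
    """Shrink long candidates toward their impact, or reject them.

    A candidate is *long* when its entry span exceeds ``fall_limitation``.
    Among classified-low samples strictly inside the candidate whose entry
    brings the span within the limit, the start is shifted to the one
    closest to the end (largest entry); with no such low the candidate is
    rejected.
    """
    lows = np.asarray(low_indices, dtype=int)
    entries = np.asarray(entries, dtype=float)
    m = np.asarray(magnitudes, dtype=float)
    out: list[CandidateFall] = []
    for cand in candidates:
        if cand.span <= fall_limitation:
            out.append(cand)
            continue
        if lows.size:
            le = entries[lows]
            ok = (
                (le > cand.start_entry)
                & (le < cand.end_entry)
                & (cand.end_entry - le <= fall_limitation)
            )
        else:
            ok = np.zeros(0, dtype=bool)
        if np.any(ok):
            j = int(lows[ok][np.argmax(entries[lows[ok]])])
            s = j
            peak = s + int(np.argmax(m[s : cand.end_index + 1]))
            cand = replace(
                cand,
                start_index=s,
                start_entry=float(entries[j]),
                peak_index=peak,
                peak_magnitude=float(m[peak]),
            )
            if report is not None:
                cand = report.log(cand, "long-shrunk", CandidateStatus.SHRUNK)
            out.append(cand)
        else:
            if report is not None:
                report.log(cand, "long-rejected", CandidateStatus.REJECTED_LONG)
    return out


def _stability_ok(
    cand: CandidateFall,
    magnitudes: np.ndarray,
    entries: np.ndarray,
    window: float,
    mean_tol: float,
    std_tol: float,
    g: float,
) -> bool:
    # samples with entry in (end_entry, end_entry + window]
    lo = np.searchsorted(entries, cand.end_entry, side="right")
    hi = np.searchsorted(entries, cand.end_entry + window, side="right")
    win = magnitudes[lo:hi]
    if win.size == 0:
        return False  # no evidence of settling
    return abs(float(win.mean()) - g) <= mean_tol and float(win.std()) <= std_tol


def _peak_dominates(
    cand: CandidateFall,
    magnitudes: np.ndarray,
    entries: np.ndarray,
    dist_1: float,
    dist_2: float,
    max_limit_2: float,
) -> bool:
    # neighbourhood: [start-dist_1, start) before and (end, end+dist_2] after
    before = (entries >= cand.start_entry - dist_1) & (entries < cand.start_entry)
    after = (entries > cand.end_entry) & (entries <= cand.end_entry + dist_2)
    idx = np.arange(len(magnitudes))
    outside = (idx < cand.start_index) | (idx > cand.end_index)
    neighbours = magnitudes[(before | after) & outside]
    rivals = neighbours[neighbours > max_limit_2]
    return bool(np.all(cand.peak_magnitude > rivals))


def final_checks(
    candidates: list[CandidateFall],
    magnitudes,
    entries,
    resolved: ResolvedThresholds,
    g: float = STANDARD_GRAVITY,
    report: ValidationReport | None = None,
) -> list[CandidateFall]:
    """Accept candidates passing post-fall stability or peak dominance."""
    m = np.asarray(magnitudes, dtype=float)
    e = np.asarray(entries, dtype=float)
    out: list[CandidateFall] = []
    for cand in candidates:
        stable = _stability_ok(
            cand, m, e, resolved.stability_window, resolved.mean_tol, resolved.std_tol, g
        )
        dominant = _peak_dominates(cand, m, e, resolved.dist_1, resolved.dist_2, resolved.max_limit_2)
        if stable or dominant:
            check = "stability-pass" if stable else "peak-pass"
            if report is not None:
                cand = report.log(cand, check, CandidateStatus.ACCEPTED)
            else:
                cand = cand.with_status(CandidateStatus.ACCEPTED)
            out.append(cand)
        elif report is not None:
            report.log(cand, "rejected-checks", CandidateStatus.REJECTED_CHECKS)
    return out


def validate(
    series: AccelSeries,
    candidates: list[CandidateFall],
    thresholds: ThresholdSet | None = None,
) -> ValidationReport:
    """Run the three validation checks on stage-one candidates.

    An empty accepted list means "no fall".
    """
    thresholds = thresholds if thresholds is not None else ThresholdSet()
    ms = magnitude_series(series)
    resolved = resolve_thresholds(thresholds, ms.magnitudes)
    return _validate_series(ms, candidates, resolved)


def _validate_series(
    ms: MagnitudeSeries,
    candidates: list[CandidateFall],
    resolved: ResolvedThresholds,
    g: float = STANDARD_GRAVITY,
    apply_final_checks: bool = True,
) -> ValidationReport:
    report = ValidationReport(n_candidates=len(candidates))
    survivors = resolve_shared_extremes(candidates, report)
    lows, _ = classify_extremes(ms.magnitudes, resolved.min_limit, resolved.max_limit)
    survivors = shrink_or_reject_long(
        survivors, lows, ms.entries, ms.magnitudes, resolved.fall_limitation, report
    )
    if apply_final_checks:
        accepted = final_checks(survivors, ms.magnitudes, ms.entries, resolved, g, report)
    else:
        accepted = [c.with_status(CandidateStatus.ACCEPTED) for c in survivors]
    accepted.sort(key=lambda c: (c.start_entry, c.end_entry))
    report.accepted = [
        AcceptedFall(
            start_index=c.start_index,
            end_index=c.end_index,
            start_time_s=float(ms.timestamps[c.start_index]),
            end_time_s=float(ms.timestamps[c.end_index]),
            start_entry=c.start_entry,
            end_entry=c.end_entry,
            peak_index=c.peak_index,
            peak_magnitude=c.peak_magnitude,
        )
        for c in accepted
    ]
    return report


def run_pipeline(
    series: AccelSeries,
    thresholds: ThresholdSet | None = None,
    apply_final_checks: bool = True,
) -> ValidationReport:
    """Full two-stage pipeline: detect candidates, then validate them.

    With ``apply_final_checks=False`` the stability/peak-dominance stage is
    skipped, which quantifies how many false detections that last stage
    removes (the "False-2" tally of the evaluation module).
    """
    thresholds = thresholds if thresholds is not None else ThresholdSet()
    ms = magnitude_series(series)
    resolved = resolve_thresholds(thresholds, ms.magnitudes)
    candidates = detect_series(ms, resolved)
    return _validate_series(ms, candidates, resolved, apply_final_checks=apply_final_checks)
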