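from __future__ import annotations

import numpy as np
import pytest

from accelfall.config import ResolvedThresholds
from accelfall.core import MagnitudeSeries
from accelfall.detector import detect_series
from accelfall.validator import _validate_series


def resolved_from(th: dict) -> ResolvedThresholds:
    return ResolvedThresholds(**th)


def run_impl(magnitudes, timestamps, entries, frequency_hz, th):
    """Run the package pipeline on a raw magnitude/entry series.

    Returns (candidate spans, accepted spans) as (start_index, end_index)
    lists, the same shape the brute-force oracle reports.
    """
    ms = MagnitudeSeries(
        magnitudes=np.asarray(magnitudes, dtype=float),
        entries=np.asarray(entries, dtype=float),
        timestamps=np.asarray(timestamps, dtype=float),
        frequency_hz=frequency_hz,
    )
    resolved = resolved_from(th)
    candidates = detect_series(ms, resolved)
    report = _validate_series(ms, candidates, resolved)
    cand_spans = [(c.start_index, c.end_index) for c in candidates]
    acc_spans = [(a.start_index, a.end_index) for a in report.accepted]
    return cand_spans, acc_spans


@pytest.fixture
def rng():
    return np.random.default_rng(20230918)
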