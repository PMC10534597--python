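"""The eight-threshold configuration driving both pipeline stages.

Magnitude thresholds (m/s²):

* ``min_limit`` — magnitudes strictly below are *low* (fall onset / free-fall dip).
* ``max_limit`` — magnitudes strictly above are *high* (impact spike).  By default
  adaptive: ``max(mean(magnitudes), 20) + 10``, resolved once over the whole
  input series so the detector self-scales to the activity level of the trace.
* ``max_limit_2`` — the high threshold used when scanning the fall's
  neighbourhood for competing peaks; by default equal to ``max_limit``.

Temporal thresholds (entry units, ~100 per second):

* ``sub_1`` — a run of lows/highs is split where consecutive entries differ by
  more than this (50 ≈ 0.5 s).
* ``fall_duration`` — maximum finish-high minus start-low entry span for a
  low/high pairing to count as a candidate fall (105 ≈ 1 s).
* ``fall_limitation`` — span above which a candidate is *long* and must be
  shrunk toward its impact or rejected (85).
* ``dist_1`` / ``dist_2`` — how far before/after the fall to search for
  competing peaks during the final checks (100 each).

The post-fall stability check ("magnitudes settle near g") needs three extra
numbers the detector's authors left qualitative; they default to a window of
``dist_2`` entries, a mean tolerance of 1.5 m/s² and a standard-deviation
ceiling of 2.0 m/s², and are deliberately exposed here rather than buried.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "AdaptiveMaxLimit",
    "ThresholdSet",
    "ResolvedThresholds",
    "resolve_thresholds",
    "load_thresholds",
    "save_thresholds",
]

_ADAPTIVE_RE = re.compile(
    r"^\s*max\(\s*(?:mean|avg|average)(?:\(magnitudes\))?\s*,\s*"
    r"([0-9]+(?:\.[0-9]+)?)\s*\)\s*\+\s*([0-9]+(?:\.[0-9]+)?)\s*$"
)


@dataclass(frozen=True)
class AdaptiveMaxLimit:
    """The rule ``max(mean(magnitudes), floor) + offset`` in m/s²."""

    floor: float = 20.0
    offset: float = 10.0

    def __call__(self, magnitudes: np.ndarray) -> float:
        m = np.asarray(magnitudes, dtype=float)
        if m.size == 0:
            raise ValueError("cannot resolve adaptive max_limit on an empty series")
        return max(float(m.mean()), self.floor) + self.offset

    def __str__(self) -> str:
        def fmt(v: float) -> str:
            return f"{v:g}"

        return f"max(mean(magnitudes), {fmt(self.floor)}) + {fmt(self.offset)}"


def parse_max_limit(value) -> "float | AdaptiveMaxLimit":
    """Accept a number or the literal adaptive-rule string."""
    if isinstance(value, AdaptiveMaxLimit):
        return value
    if isinstance(value, (int, float)):
        return float(value)
    m = _ADAPTIVE_RE.match(str(value))
    if m:
        return AdaptiveMaxLimit(float(m.group(1)), float(m.group(2)))
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"max_limit must be a number or 'max(mean(magnitudes), F) + O', got {value!r}"
        ) from None


@dataclass
class ThresholdSet:
    """Configuration as written; resolve against a series to get numbers."""

    min_limit: float = 6.5
    max_limit: "float | AdaptiveMaxLimit" = field(default_factory=AdaptiveMaxLimit)
    sub_1: float = 50.0
    fall_duration: float = 105.0
    fall_limitation: float = 85.0
    dist_1: float = 100.0
    dist_2: float = 100.0
    #: a number, or "max_limit" to track the resolved max_limit
    max_limit_2: "float | str" = "max_limit"
    #: post-fall stability check: window (entry units; None -> dist_2) and tolerances
    stability_window: float | None = None
    mean_tol: float = 1.5
    std_tol: float = 2.0

    def __post_init__(self) -> None:
        self.max_limit = parse_max_limit(self.max_limit)
        for name in ("min_limit", "sub_1", "fall_duration", "fall_limitation", "dist_1", "dist_2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if isinstance(self.max_limit_2, str) and self.max_limit_2 != "max_limit":
            self.max_limit_2 = float(self.max_limit_2)
        if self.fall_limitation > self.fall_duration:
            warnings.warn(
                "fall_limitation > fall_duration: no candidate can ever be 'long', "
                "the shrink stage is vacuous",
                stacklevel=2,
            )

    def replace(self, **kwargs) -> "ThresholdSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ResolvedThresholds:
    """All eight thresholds as plain numbers, valid for one input series."""

    min_limit: float
    max_limit: float
    sub_1: float
    fall_duration: float
    fall_limitation: float
    dist_1: float
    dist_2: float
    max_limit_2: float
    stability_window: float
    mean_tol: float
    std_tol: float


def resolve_thresholds(config: ThresholdSet, magnitudes) -> ResolvedThresholds:
    """Evaluate the adaptive rules against a concrete magnitude series.

    ``max_limit`` is resolved once over the entire series; ``max_limit_2``
    inherits it unless overridden with a number; the stability window falls
    back to ``dist_2``.
    """
    m = np.asarray(magnitudes, dtype=float)
    if m.size == 0:
        raise ValueError("magnitudes must be non-empty to resolve thresholds")
    max_limit = config.max_limit(m) if isinstance(config.max_limit, AdaptiveMaxLimit) else float(config.max_limit)
    if config.max_limit_2 == "max_limit":
        max_limit_2 = max_limit
    else:
        max_limit_2 = float(config.max_limit_2)
    if config.min_limit >= max_limit:
        warnings.warn(
            f"min_limit ({config.min_limit}) >= resolved max_limit ({max_limit}): "
            "low/high classification degenerates",
            stacklevel=2,
        )
    return ResolvedThresholds(
        min_limit=float(config.min_limit),
        max_limit=max_limit,
        sub_1=float(config.sub_1),
        fall_duration=float(config.fall_duration),
        fall_limitation=float(config.fall_limitation),
        dist_1=float(config.dist_1),
        dist_2=float(config.dist_2),
        max_limit_2=max_limit_2,
        stability_window=float(config.stability_window if config.stability_window is not None else config.dist_2),
        mean_tol=float(config.mean_tol),
        std_tol=float(config.std_tol),
    )


def save_thresholds(config: ThresholdSet, path) -> None:
    """Write a flat key/value YAML document mirroring the threshold names."""
    doc = {
        "min_limit": config.min_limit,
        "max_limit": str(config.max_limit) if isinstance(config.max_limit, AdaptiveMaxLimit) else config.max_limit,
        "sub_1": config.sub_1,
        "fall_duration": config.fall_duration,
        "fall_limitation": config.fall_limitation,
        "dist_1": config.dist_1,
        "dist_2": config.dist_2,
        "max_limit_2": config.max_limit_2,
        "stability_window": config.stability_window,
        "mean_tol": config.mean_tol,
        "std_tol": config.std_tol,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_thresholds(path) -> ThresholdSet:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"threshold config {path} must be a flat key/value document")
    known = {f for f in ThresholdSet.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown threshold keys in {path}: {sorted(unknown)}")
    return ThresholdSet(**doc)
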