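"""Core containers and the two foundational computations.

A tri-axial accelerometer stream is reduced to a scalar *sum vector
magnitude* per sample, ``sqrt(x**2 + y**2 + z**2)`` — orientation-invariant,
so the detector never needs to know how the sensor was worn.  Time is
re-expressed as a frequency-normalised pseudo-timestamp, the *entry*::

    entry[0] = 0
    entry[i] = (t[i] - t[i-1]) / 10 + entry[i-1] + 100 / f

with ``t`` in seconds and ``f`` the nominal sampling rate in Hz.  At any
rate, entries advance by roughly 100 units per second of signal (100.1 at an
ideal 100 Hz), so every temporal threshold downstream is stated in entry
units: 100 entries correspond to about one second.  The small ``dt/10`` term
absorbs timestamp jitter and gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard gravity, m/s^2 — the resting magnitude baseline.
STANDARD_GRAVITY: float = 9.80665

#: Unit-conversion factor for datasets recorded in g (KFall-style files).
G_DATASET: float = 9.807


class InvalidSeriesError(ValueError):
    """Raised when an input series violates a structural invariant."""


def _as_1d_float(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise InvalidSeriesError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class AccelSeries:
    """Raw tri-axial acceleration samples with timestamps.

    Parameters
    ----------
    timestamps
        Sample times in seconds, strictly increasing.
    x, y, z
        Per-axis acceleration in m/s^2, same length as ``timestamps``.
    frequency_hz
        Nominal sampling rate in Hz (> 0).  Used by the entry recursion,
        not to resample the data.
    source_label
        Optional ground-truth tag (``"fall"`` / ``"non-fall"`` or an
        activity sub-class name).
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    frequency_hz: float
    source_label: str | None = None

    def __post_init__(self) -> None:
        self.timestamps = _as_1d_float(self.timestamps, "timestamps")
        self.x = _as_1d_float(self.x, "x")
        self.y = _as_1d_float(self.y, "y")
        self.z = _as_1d_float(self.z, "z")
        n = len(self.timestamps)
        if n < 1:
            raise InvalidSeriesError("series must contain at least one sample")
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if len(arr) != n:
                raise InvalidSeriesError(
                    f"{name} has length {len(arr)}, expected {n} to match timestamps"
                )
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise InvalidSeriesError("timestamps must be strictly increasing")
        if not self.frequency_hz > 0:
            raise InvalidSeriesError(f"frequency_hz must be > 0, got {self.frequency_hz}")

    def __len__(self) -> int:
        return len(self.timestamps)

    @classmethod
    def from_frequency(
        cls,
        x,
        y,
        z,
        frequency_hz: float,
        source_label: str | None = None,
    ) -> "AccelSeries":
        """Build a series with timestamps synthesised as ``i / frequency_hz``.

        Used for dataset dialects that ship no time column (UR-style,
        MMsys-style) and for generated traces.
        """
        if not frequency_hz > 0:
            raise InvalidSeriesError(f"frequency_hz must be > 0, got {frequency_hz}")
        x = _as_1d_float(x, "x")
        t = np.arange(len(x), dtype=float) / frequency_hz
        return cls(t, x, y, z, frequency_hz, source_label)


@dataclass
class MagnitudeSeries:
    """The detector's working representation: magnitudes plus entries."""

    magnitudes: np.ndarray
    entries: np.ndarray
    timestamps: np.ndarray
    frequency_hz: float = field(default=0.0)

    def __len__(self) -> int:
        return len(self.magnitudes)


def compute_magnitudes(series: AccelSeries) -> np.ndarray:
    """Per-sample sum vector magnitude ``sqrt(x² + y² + z²)`` in m/s².

    Invariant under any joint rotation of the three axes, which is what
    makes a threshold detector viable on an arbitrarily oriented sensor.
    """
    return np.sqrt(series.x**2 + series.y**2 + series.z**2)


def compute_entries(timestamps, frequency_hz: float) -> np.ndarray:
    """Frequency-normalised pseudo-timestamps (entry units).

    ``entries[0] = 0``; each step adds ``100 / frequency_hz`` plus a tenth
    of the observed inter-sample gap in seconds.  Non-decreasing by
    construction for strictly increasing timestamps.
    """
    t = _as_1d_float(timestamps, "timestamps")
    if len(t) == 0:
        raise InvalidSeriesError("timestamps must be non-empty")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise InvalidSeriesError("timestamps must be strictly increasing")
    if not frequency_hz > 0:
        raise InvalidSeriesError(f"frequency_hz must be > 0, got {frequency_hz}")
    increments = np.diff(t) / 10.0 + 100.0 / frequency_hz
    entries = np.empty_like(t)
    entries[0] = 0.0
    np.cumsum(increments, out=entries[1:])
    return entries


def magnitude_series(series: AccelSeries) -> MagnitudeSeries:
    """Reduce an :class:`AccelSeries` to magnitudes + entries."""
    return MagnitudeSeries(
        magnitudes=compute_magnitudes(series),
        entries=compute_entries(series.timestamps, series.frequency_hz),
        timestamps=series.timestamps,
        frequency_hz=series.frequency_hz,
    )
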