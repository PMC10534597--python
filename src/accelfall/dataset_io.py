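"""CSV readers/writers for the three supported dataset dialects.

* ``kfall`` — per-trial files, acceleration in g (converted to m/s² with the
  factor 9.807 the dataset documents), a time column in seconds, 100 Hz.
* ``ur`` — per-trial files, acceleration already in m/s², no time column;
  timestamps are synthesised as ``i / 60`` s from the sensor's 60 Hz rate.
* ``mmsys`` — one continuous file per subject at 100 Hz with an integer
  class label per sample; contiguous equal labels are merged into intervals.

The datasets' public documentation does not pin down exact CSV headers, so
every dialect is a :class:`DialectSpec` value the caller can override;
the shipped defaults follow the public datasets' documented layouts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import G_DATASET, AccelSeries
from .validator import ValidationReport

__all__ = [
    "DialectSpec",
    "Trial",
    "LabeledStream",
    "DIALECTS",
    "MMSYS_CLASSES",
    "MMSYS_FALL_CLASSES",
    "read_trial_csv",
    "read_stream_csv",
    "write_trial_csv",
    "write_detections",
]


class FormatError(ValueError):
    """Raised when a CSV file does not match its dialect."""


@dataclass(frozen=True)
class DialectSpec:
    """Column layout and units for one CSV dialect.

    Columns are named (header present) or integer positions (no header).
    ``unit`` is ``"g"`` (multiplied by 9.807 on read) or ``"m/s2"``.
    ``time_col`` of None means timestamps are synthesised at ``frequency_hz``.
    """

    name: str
    x_col: "str | int"
    y_col: "str | int"
    z_col: "str | int"
    time_col: "str | int | None" = None
    label_col: "str | int | None" = None
    unit: str = "m/s2"
    frequency_hz: float = 100.0
    has_header: bool = True


#: MMsys per-sample class labels (label 14 is absent in the source dataset).
MMSYS_CLASSES: dict[int, str] = {
    1: "standing",
    2: "fall forward",
    3: "lying",
    4: "sitting on a bed",
    5: "sitting on a chair",
    6: "fall backward",
    7: "near fall",
    8: "walking",
    9: "crouching",
    10: "fall right",
    11: "fall left",
    12: "real fall forward",
    13: "real fall backward",
    15: "ascending and descending a staircase",
}

MMSYS_FALL_CLASSES: frozenset[str] = frozenset(
    {"fall forward", "fall backward", "fall right", "fall left",
     "real fall forward", "real fall backward"}
)

DIALECTS: dict[str, DialectSpec] = {
    "kfall": DialectSpec(
        name="kfall", time_col="TimeStamp(s)", x_col="AccX", y_col="AccY", z_col="AccZ",
        unit="g", frequency_hz=100.0,
    ),
    "ur": DialectSpec(
        name="ur", x_col=0, y_col=1, z_col=2, unit="m/s2",
        frequency_hz=60.0, has_header=False,
    ),
    "mmsys": DialectSpec(
        name="mmsys", x_col="x", y_col="y", z_col="z", label_col="label",
        unit="m/s2", frequency_hz=100.0,
    ),
}


@dataclass
class Trial:
    """One labelled per-trial recording."""

    series: AccelSeries
    label: str  # "fall" | "non-fall"
    sub_class: str = ""
    dataset_id: str = ""
    subject_id: str = ""
    trial_id: str = ""


@dataclass
class LabeledStream:
    """One continuous recording with per-interval class labels."""

    series: AccelSeries
    intervals: list[tuple[int, int, str]]  # (start_index, end_index incl., class)


def _get_dialect(dialect) -> DialectSpec:
    if isinstance(dialect, DialectSpec):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise FormatError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}") from None


def _read_frame(path, spec: DialectSpec) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, header=0 if spec.has_header else None, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df


def _column(df: pd.DataFrame, col, path) -> np.ndarray:
    if isinstance(col, int):
        if col >= df.shape[1]:
            raise FormatError(f"{path}: missing column index {col}")
        raw = df.iloc[:, col]
    else:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
        raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna()
    if bad.any() or vals.isna().any():
        row = int(np.flatnonzero(vals.isna())[0])
        raise FormatError(f"{path}: non-numeric value in column {col!r} at data row {row}")
    return vals.to_numpy(dtype=float)


def read_trial_csv(
    path,
    dialect="kfall",
    frequency_hz: float | None = None,
    label: str = "",
    sub_class: str = "",
) -> Trial:
    """Read one per-trial CSV file into a :class:`Trial`.

    ``frequency_hz`` overrides the dialect's nominal rate.  For dialects
    without a time column, timestamps are synthesised as ``i / f`` seconds.
    """
    spec = _get_dialect(dialect)
    f = frequency_hz if frequency_hz is not None else spec.frequency_hz
    df = _read_frame(path, spec)
    x = _column(df, spec.x_col, path)
    y = _column(df, spec.y_col, path)
    z = _column(df, spec.z_col, path)
    if spec.unit == "g":
        x, y, z = x * G_DATASET, y * G_DATASET, z * G_DATASET
    if spec.time_col is not None:
        t = _column(df, spec.time_col, path)
        series = AccelSeries(t, x, y, z, f, source_label=label or None)
    else:
        series = AccelSeries.from_frequency(x, y, z, f, source_label=label or None)
    p = Path(path)
    return Trial(series=series, label=label, sub_class=sub_class, trial_id=p.stem)


def read_stream_csv(
    path,
    dialect="mmsys",
    frequency_hz: float | None = None,
    label_map: dict[int, str] | None = None,
) -> LabeledStream:
    """Read one continuous labelled CSV into a :class:`LabeledStream`.

    Contiguous runs of equal labels become closed ``[start, end]`` intervals.
    """
    spec = _get_dialect(dialect)
    if spec.label_col is None:
        raise FormatError(f"dialect {spec.name!r} has no label column; not a stream dialect")
    label_map = label_map if label_map is not None else MMSYS_CLASSES
    f = frequency_hz if frequency_hz is not None else spec.frequency_hz
    df = _read_frame(path, spec)
    x = _column(df, spec.x_col, path)
    y = _column(df, spec.y_col, path)
    z = _column(df, spec.z_col, path)
    if spec.unit == "g":
        x, y, z = x * G_DATASET, y * G_DATASET, z * G_DATASET
    labels = _column(df, spec.label_col, path).astype(int)
    unknown = set(np.unique(labels)) - set(label_map)
    if unknown:
        raise FormatError(
            f"{path}: unknown label value(s) {sorted(unknown)}; known: {sorted(label_map)}"
        )
    series = AccelSeries.from_frequency(x, y, z, f)
    intervals: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            intervals.append((start, i - 1, label_map[int(labels[start])]))
            start = i
    return LabeledStream(series=series, intervals=intervals)


def write_trial_csv(series: AccelSeries, path, dialect="kfall") -> None:
    """Write a series back out in a per-trial dialect (inverse of read)."""
    spec = _get_dialect(dialect)
    x, y, z = series.x, series.y, series.z
    if spec.unit == "g":
        x, y, z = x / G_DATASET, y / G_DATASET, z / G_DATASET
    cols: dict = {}
    if spec.time_col is not None:
        cols[spec.time_col] = series.timestamps
    cols[spec.x_col] = x
    cols[spec.y_col] = y
    cols[spec.z_col] = z
    df = pd.DataFrame(cols)
    # 17 significant digits round-trip any float64 exactly
    df.to_csv(path, index=False, header=spec.has_header, float_format="%.17g")


def write_detections(report: ValidationReport, path, trial_id: str = "") -> None:
    """One row per accepted fall, sorted ascending by start time."""
    rows = sorted(report.accepted, key=lambda a: (a.start_time_s, a.end_time_s))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["trial_id", "start_time_s", "end_time_s", "start_entry", "end_entry", "peak_magnitude"]
        )
        for a in rows:
            w.writerow(
                [trial_id, repr(a.start_time_s), repr(a.end_time_s),
                 repr(a.start_entry), repr(a.end_entry), repr(a.peak_magnitude)]
            )
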