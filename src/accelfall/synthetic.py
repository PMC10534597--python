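"""Synthetic tri-axial accelerometer traces with ground truth.

The generator scripts a *magnitude profile* per scenario and then distributes
each magnitude over x/y/z via a random unit vector, so the scalar signal the
detector sees is exactly the scripted one.  The canonical fall morphology is:

* rest near g (9.80665 m/s²) plus optional Gaussian noise;
* a dip — magnitude uniform in [1, min_limit − 1] m/s² for 0.1–0.3 s — as
  the body drops;
* within ≤ 0.8 s, an impact spike — magnitude in [max_limit + 5, 60] m/s²
  for 1–3 samples;
* at least 1.5 s of post-impact settling back at g.

Daily-activity confounders: walking/jogging (sinusoid-plus-noise magnitudes
strictly inside the (min_limit, max_limit) band, so they never produce
extremes), sitting (a gentle sub-threshold dip-and-overshoot), and a gentle
jump (an impact-like spike *without* a preceding qualifying dip, preceded by
a smaller secondary peak).  These probe the false-positive behaviour of the
pipeline without ever constructing the full fall pattern.

Noise is i.i.d. Gaussian on the magnitude before axis decomposition.  All
randomness flows from a single seeded generator, so a spec plus seed fully
determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import STANDARD_GRAVITY, AccelSeries

__all__ = [
    "Event",
    "ScenarioSpec",
    "GroundTruthInterval",
    "generate",
    "fall_scenario",
    "rest_scenario",
    "walk_scenario",
    "mixed_scenario",
]

_G = STANDARD_GRAVITY


class ScenarioError(ValueError):
    """Raised for malformed scenario specifications."""


@dataclass(frozen=True)
class Event:
    """One scripted event: a fall or a daily-activity confounder.

    ``duration_s`` applies to sustained activities (walk, jog, sit, rest);
    falls and jumps have intrinsic durations drawn from the scenario's RNG
    unless pinned through ``params`` (keys: ``dip_magnitude``,
    ``dip_duration_s``, ``gap_s``, ``spike_magnitude``, ``spike_samples``).
    """

    kind: str  # fall | sit | walk | jog | jump | rest
    start_s: float
    duration_s: float | None = None
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ScenarioSpec:
    frequency_hz: float = 100.0
    duration_s: float = 10.0
    events: tuple[Event, ...] = ()
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0 or self.duration_s <= 0:
            raise ScenarioError("frequency_hz and duration_s must be positive")
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be >= 0")
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class GroundTruthInterval:
    start_index: int
    end_index: int  # inclusive
    label: str


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _half_sine(n: int, lo: float, hi: float) -> np.ndarray:
    """Smooth bump from lo up to hi and back, n samples."""
    return lo + (hi - lo) * np.sin(np.linspace(0, np.pi, n))


def _script_fall(mag, i0, f, rng, params):
    dip_m = params.get("dip_magnitude", rng.uniform(1.0, 5.5))
    dip_s = params.get("dip_duration_s", rng.uniform(0.1, 0.3))
    gap_s = params.get("gap_s", rng.uniform(0.05, 0.6))
    spike_m = params.get("spike_magnitude", rng.uniform(35.0, 60.0))
    spike_n = int(params.get("spike_samples", rng.integers(1, 4)))
    dip_n = max(1, int(round(dip_s * f)))
    gap_n = max(1, int(round(gap_s * f)))
    i_spike = i0 + dip_n + gap_n
    i_end = i_spike + spike_n  # exclusive
    if i_end > len(mag):
        raise ScenarioError("fall event extends past the end of the scenario")
    mag[i0 : i0 + dip_n] = dip_m
    mag[i_spike:i_end] = spike_m
    settle_n = int(round(1.5 * f))  # post-impact settling stays at baseline g
    return GroundTruthInterval(i0, i_end - 1, "fall"), i_end + settle_n


def _script_jump(mag, i0, f, rng, params):
    # impact-like spike without a qualifying dip; smaller secondary peak first
    spike_m = params.get("spike_magnitude", rng.uniform(35.0, 50.0))
    pre_m = params.get("secondary_magnitude", 0.5 * spike_m)
    lead_n = max(2, int(round(0.5 * f)))
    i_spike = i0 + lead_n
    i_end = i_spike + 2
    if i_end > len(mag):
        raise ScenarioError("jump event extends past the end of the scenario")
    mag[i0 : i0 + 2] = pre_m
    mag[i0 + 2 : i_spike] = _G + 2.0  # crouch-and-push elevation, no low
    mag[i_spike:i_end] = spike_m
    return GroundTruthInterval(i0, i_end - 1, "jump"), i_end + int(round(1.0 * f))


def _script_oscillation(mag, i0, n, f, freq_hz, amp):
    t = np.arange(n) / f
    mag[i0 : i0 + n] = _G + amp * np.sin(2 * np.pi * freq_hz * t)


def _script_sit(mag, i0, f, params):
    # gentle dip-and-overshoot strictly inside the (min_limit, max_limit) band
    dip_n = max(2, int(round(0.3 * f)))
    over_n = max(2, int(round(0.2 * f)))
    if i0 + dip_n + over_n > len(mag):
        raise ScenarioError("sit event extends past the end of the scenario")
    mag[i0 : i0 + dip_n] = _half_sine(dip_n, _G, params.get("dip_magnitude", 7.5))
    mag[i0 + dip_n : i0 + dip_n + over_n] = _half_sine(over_n, _G, params.get("overshoot", 14.0))
    return i0 + dip_n + over_n


def generate(spec: ScenarioSpec) -> tuple[AccelSeries, list[GroundTruthInterval]]:
    """Render a scenario to an :class:`AccelSeries` plus ground truth.

    Returns the series (timestamps synthesised as ``i / frequency_hz``) and
    the list of ground-truth intervals — one per event, falls spanning
    dip start to impact end inclusive.
    """
    rng = np.random.default_rng(spec.seed)
    f = spec.frequency_hz
    n = int(round(spec.duration_s * f))
    if n < 1:
        raise ScenarioError("scenario too short for a single sample")
    mag = np.full(n, _G)
    truth: list[GroundTruthInterval] = []
    occupied: list[tuple[int, int, np.ndarray]] = []  # (start, end_excl, direction)

    for ev in sorted(spec.events, key=lambda e: e.start_s):
        if not 0 <= ev.start_s < spec.duration_s:
            raise ScenarioError(f"event at {ev.start_s}s outside scenario duration")
        i0 = int(round(ev.start_s * f))
        direction = _unit_vector(rng)
        if ev.kind == "fall":
            interval, occ_end = _script_fall(mag, i0, f, rng, ev.params)
            truth.append(interval)
        elif ev.kind == "jump":
            interval, occ_end = _script_jump(mag, i0, f, rng, ev.params)
            truth.append(interval)
        elif ev.kind in ("walk", "jog"):
            if ev.duration_s is None:
                raise ScenarioError(f"{ev.kind} event requires duration_s")
            n_ev = int(round(ev.duration_s * f))
            if i0 + n_ev > n:
                raise ScenarioError(f"{ev.kind} event extends past the end of the scenario")
            amp, fo = (2.0, 2.0) if ev.kind == "walk" else (2.8, 3.0)
            _script_oscillation(mag, i0, n_ev, f, fo, amp)
            truth.append(GroundTruthInterval(i0, i0 + n_ev - 1, ev.kind))
            occ_end = i0 + n_ev
        elif ev.kind == "sit":
            occ_end = _script_sit(mag, i0, f, ev.params)
            truth.append(GroundTruthInterval(i0, occ_end - 1, "sit"))
        elif ev.kind == "rest":
            n_ev = int(round((ev.duration_s or 1.0) * f))
            truth.append(GroundTruthInterval(i0, min(i0 + n_ev, n) - 1, "rest"))
            occ_end = i0 + n_ev
        else:
            raise ScenarioError(f"unknown event kind {ev.kind!r}")
        for s, e, _ in occupied:
            if i0 < e and occ_end > s:
                raise ScenarioError("events overlap (including post-event settling)")
        occupied.append((i0, min(occ_end, n), direction))

    if spec.noise_sd > 0:
        mag = mag + rng.normal(0.0, spec.noise_sd, n)
        np.clip(mag, 0.01, None, out=mag)

    # axis decomposition: baseline along z, each event along its own unit vector
    directions = np.zeros((n, 3))
    directions[:, 2] = 1.0
    for s, e, d in occupied:
        directions[s:e] = d
    x, y, z = (mag * directions[:, k] for k in range(3))
    series = AccelSeries.from_frequency(x, y, z, f)
    return series, truth


# ---------------------------------------------------------------------------
# canned scenario builders


def fall_scenario(
    n_falls: int = 1,
    frequency_hz: float = 100.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    spacing_s: float = 3.0,
    lead_s: float = 2.0,
) -> ScenarioSpec:
    """``n_falls`` canonical falls separated by at least ``spacing_s`` of rest."""
    events = tuple(Event("fall", lead_s + i * spacing_s) for i in range(n_falls))
    duration = lead_s + n_falls * spacing_s + 2.0
    return ScenarioSpec(frequency_hz, duration, events, noise_sd, seed)


def rest_scenario(
    duration_s: float = 30.0,
    frequency_hz: float = 100.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> ScenarioSpec:
    return ScenarioSpec(frequency_hz, duration_s, (), noise_sd, seed)


def walk_scenario(
    duration_s: float = 30.0,
    frequency_hz: float = 100.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    kind: str = "walk",
) -> ScenarioSpec:
    ev = Event(kind, 1.0, duration_s=duration_s - 2.0)
    return ScenarioSpec(frequency_hz, duration_s, (ev,), noise_sd, seed)


def mixed_scenario(
    frequency_hz: float = 100.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> ScenarioSpec:
    """Walk, sit, a fall, a jump, then rest — one of everything."""
    events = (
        Event("walk", 1.0, duration_s=4.0),
        Event("sit", 6.0),
        Event("fall", 9.0),
        Event("jump", 13.0),
    )
    return ScenarioSpec(frequency_hz, 18.0, events, noise_sd, seed)
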