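import numpy as np
import pytest
from conftest import resolved_from, run_impl
from oracles import brute_pipeline, random_instance

from accelfall.core import STANDARD_GRAVITY, AccelSeries, MagnitudeSeries, magnitude_series
from accelfall.config import ThresholdSet, resolve_thresholds
from accelfall.detector import CandidateFall, CandidateStatus, ExtremeSet, detect_series
from accelfall.validator import (
    _validate_series,
    final_checks,
    resolve_shared_extremes,
    run_pipeline,
    shrink_or_reject_long,
    validate,
)

G = STANDARD_GRAVITY


def _cand(start_e, end_e, low_set, high_set, start_i=0, end_i=1, peak_m=40.0):
    return CandidateFall(
        start_index=start_i,
        end_index=end_i,
        start_entry=start_e,
        end_entry=end_e,
        peak_index=end_i,
        peak_magnitude=peak_m,
        low_set=low_set,
        high_set=high_set,
    )


def _mag_profile(profile, f=100.0):
    """AccelSeries whose magnitude equals the given profile (all along z)."""
    m = np.asarray(profile, dtype=float)
    return AccelSeries.from_frequency(np.zeros_like(m), np.zeros_like(m), m, f)


class TestSharedExtremes:
    def test_shared_high_keeps_shorter(self):
        high = ExtremeSet("high", 18, 18, 180.0, 180.0)
        a = _cand(90.0, 180.0, ExtremeSet("low", 9, 9, 90.0, 90.0), high)
        b = _cand(140.0, 180.0, ExtremeSet("low", 14, 14, 140.0, 140.0), high)
        kept = resolve_shared_extremes([a, b])
        assert kept == [b]  # span 40 beats span 90

    def test_disjoint_candidates_unchanged(self):
        a = _cand(0.0, 50.0, ExtremeSet("low", 0, 0, 0.0, 0.0), ExtremeSet("high", 5, 5, 50.0, 50.0))
        b = _cand(300.0, 360.0, ExtremeSet("low", 30, 30, 300.0, 300.0), ExtremeSet("high", 36, 36, 360.0, 360.0))
        assert resolve_shared_extremes([b, a]) == [a, b]

    def test_equal_span_tie_keeps_earlier_start(self):
        low = ExtremeSet("low", 15, 15, 150.0, 150.0)
        a = _cand(150.0, 200.0, low, ExtremeSet("high", 20, 20, 200.0, 200.0))
        b = _cand(160.0, 210.0, low, ExtremeSet("high", 21, 21, 210.0, 210.0))
        kept = resolve_shared_extremes([b, a])  # equal spans, shared low set
        assert kept == [a]  # earlier start wins the tie


class TestShrinkOrRejectLong:
    def test_long_fall_shrinks_to_low_nearest_impact(self):
        entries = np.arange(0.0, 200.0)
        m = np.full(200, G)
        m[100] = 3.0  # the rescuing low at entry end-60
        cand = _cand(65.0, 160.0, ExtremeSet("low", 65, 65, 65.0, 65.0),
                     ExtremeSet("high", 160, 160, 160.0, 160.0), 65, 160)
        out = shrink_or_reject_long([cand], [65, 100], entries, m, 85.0)
        assert len(out) == 1
        assert out[0].start_index == 100
        assert out[0].span == pytest.approx(60.0)

    def test_short_fall_passes_unchanged(self):
        entries = np.arange(0.0, 100.0)
        cand = _cand(10.0, 60.0, ExtremeSet("low", 10, 10, 10.0, 10.0),
                     ExtremeSet("high", 60, 60, 60.0, 60.0), 10, 60)
        out = shrink_or_reject_long([cand], [10], entries, np.full(100, G), 85.0)
        assert out == [cand]

    def test_long_fall_without_nearer_low_rejected(self):
        entries = np.arange(0.0, 200.0)
        cand = _cand(65.0, 160.0, ExtremeSet("low", 65, 65, 65.0, 65.0),
                     ExtremeSet("high", 160, 160, 160.0, 160.0), 65, 160)
        assert shrink_or_reject_long([cand], [65], entries, np.full(200, G), 85.0) == []


class TestFinalChecks:
    def _resolved(self, **over):
        th = dict(min_limit=6.5, max_limit=30.0, sub_1=50.0, fall_duration=105.0,
                  fall_limitation=85.0, dist_1=100.0, dist_2=100.0, max_limit_2=30.0,
                  stability_window=100.0, mean_tol=1.5, std_tol=2.0)
        th.update(over)
        return resolved_from(th)

    def test_stability_accepts_despite_bigger_neighbour(self):
        """Post-fall window flat at g -> accepted via stability even though a
        neighbouring peak tops the fall's own."""
        m = np.full(400, G)
        entries = np.arange(400.0)
        m[100] = 3.0
        m[150] = 40.0
        m[200] = 50.0  # rival peak 50 entries after the fall
        cand = _cand(100.0, 150.0, ExtremeSet("low", 100, 100, 100.0, 100.0),
                     ExtremeSet("high", 150, 150, 150.0, 150.0), 100, 150)
        cand = CandidateFall(**{**cand.__dict__, "peak_index": 150, "peak_magnitude": 40.0})
        m2 = m.copy()
        m2[200] = G  # keep the window clean for the stability check
        accepted = final_checks([cand], m2, entries, self._resolved())
        assert len(accepted) == 1

    def test_peak_dominance_accepts_with_noisy_tail(self):
        m = np.full(400, G)
        entries = np.arange(400.0)
        m[100], m[150] = 3.0, 40.0
        m[151:251] = G + 5.0 * np.sin(np.arange(100))  # unstable tail
        cand = _cand(100.0, 150.0, ExtremeSet("low", 100, 100, 100.0, 100.0),
                     ExtremeSet("high", 150, 150, 150.0, 150.0), 100, 150)
        cand = CandidateFall(**{**cand.__dict__, "peak_index": 150, "peak_magnitude": 40.0})
        accepted = final_checks([cand], m, entries, self._resolved())
        assert len(accepted) == 1  # fall peak is the neighbourhood maximum

    def test_rejected_when_both_assumptions_fail(self):
        m = np.full(400, G)
        entries = np.arange(400.0)
        m[100], m[150] = 3.0, 40.0
        m[151:251] += 5.0 * np.sin(np.arange(100))  # noisy tail...
        m[200] = 50.0  # ...and a dominating rival
        cand = _cand(100.0, 150.0, ExtremeSet("low", 100, 100, 100.0, 100.0),
                     ExtremeSet("high", 150, 150, 150.0, 150.0), 100, 150)
        cand = CandidateFall(**{**cand.__dict__, "peak_index": 150, "peak_magnitude": 40.0})
        assert final_checks([cand], m, entries, self._resolved()) == []

    def test_equal_neighbour_peak_defeats_dominance(self):
        m = np.full(400, G)
        entries = np.arange(400.0)
        m[100], m[150] = 3.0, 40.0
        m[151:251] += 5.0 * np.sin(np.arange(100))
        m[200] = 40.0  # equal rival: strict > fails
        cand = _cand(100.0, 150.0, ExtremeSet("low", 100, 100, 100.0, 100.0),
                     ExtremeSet("high", 150, 150, 150.0, 150.0), 100, 150)
        cand = CandidateFall(**{**cand.__dict__, "peak_index": 150, "peak_magnitude": 40.0})
        assert final_checks([cand], m, entries, self._resolved()) == []

    def test_empty_stability_window_is_insufficient_evidence(self):
        m = np.full(151, G)
        entries = np.arange(151.0)
        m[100], m[150] = 3.0, 40.0  # fall ends at the last sample
        cand = _cand(100.0, 150.0, ExtremeSet("low", 100, 100, 100.0, 100.0),
                     ExtremeSet("high", 150, 150, 150.0, 150.0), 100, 150)
        cand = CandidateFall(**{**cand.__dict__, "peak_index": 150, "peak_magnitude": 40.0})
        accepted = final_checks([cand], m, entries, self._resolved())
        assert len(accepted) == 1  # A is false, B still accepts


class TestValidatePipeline:
    def test_empty_candidates_mean_no_fall(self):
        series = _mag_profile(np.full(300, G))
        report = validate(series, [], ThresholdSet())
        assert report.accepted == [] and not report.is_fall

    def test_double_connection_keeps_shorter_pairing(self):
        """Two dips before one spike: only the shorter pairing is accepted."""
        m = np.full(500, G)
        m[100:120] = 3.0   # first dip
        m[175:185] = 4.0   # second dip (> sub_1 entries later), nearer the spike
        m[200:202] = 40.0  # impact
        series = _mag_profile(m)
        report = run_pipeline(series, ThresholdSet(max_limit=30.0))
        assert len(report.accepted) == 1
        assert report.accepted[0].start_index == 175

    def test_idempotence_on_accepted_output(self, rng):
        """Re-validating an already-accepted set reproduces it."""
        checked = 0
        for _ in range(80):
            m, t, e, f, th = random_instance(rng, max_len=250)
            ms = MagnitudeSeries(np.asarray(m), np.asarray(e), np.asarray(t), f)
            resolved = resolved_from(th)
            cands = detect_series(ms, resolved)
            rep1 = _validate_series(ms, cands, resolved)
            acc_cands = [c for c, _, s in rep1.trail if s == CandidateStatus.ACCEPTED]
            if not acc_cands:
                continue
            rep2 = _validate_series(ms, acc_cands, resolved)
            spans1 = [(a.start_index, a.end_index) for a in rep1.accepted]
            spans2 = [(a.start_index, a.end_index) for a in rep2.accepted]
            assert spans1 == spans2
            checked += 1
        assert checked > 10

    def test_conservation_never_creates_falls(self, rng):
        for _ in range(100):
            m, t, e, f, th = random_instance(rng, max_len=250)
            cand_spans, acc_spans = run_impl(m, t, e, f, th)
            assert len(acc_spans) <= len(cand_spans)
            cand_ends = {end for _, end in cand_spans}
            assert all(end in cand_ends for _, end in acc_spans)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(150):
            m, t, e, f, th = random_instance(rng, max_len=250)
            _, impl_acc = run_impl(m, t, e, f, th)
            _, brute_acc = brute_pipeline(m, e, th)
            assert impl_acc == brute_acc

    def test_tightening_never_accepts_more(self, rng):
        """Stricter stability tolerances or a lower max_limit_2 can only
        shrink the accepted set."""
        for _ in range(40):
            m, t, e, f, th = random_instance(rng, max_len=200)
            _, base = run_impl(m, t, e, f, th)
            tighter = {**th, "mean_tol": th["mean_tol"] / 2, "std_tol": th["std_tol"] / 2}
            _, acc_t = run_impl(m, t, e, f, tighter)
            assert len(acc_t) <= len(base)
            lower2 = {**th, "max_limit_2": th["max_limit_2"] * 0.5}
            _, acc_l = run_impl(m, t, e, f, lower2)
            assert len(acc_l) <= len(base)
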