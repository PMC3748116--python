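"""Schmitt-trigger detection: hand traces, oracle equivalence, detectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larva_etho.event_detection import (
    DEFAULT_CAST_THRESHOLDS,
    DEFAULT_HUNCH_THRESHOLDS,
    DEFAULT_ROLL_THRESHOLDS,
    EventRecord,
    SchmittThresholds,
    detect_casts,
    detect_hunches,
    detect_rolls,
    detection_rates,
    event_frequency,
    schmitt_detect,
    tune_thresholds,
)
from larva_etho.posture_metrics import PostureSeries
from larva_etho import synthetic_larvae as syn

from reference_impl import random_bump_signal, schmitt_reference

FPS = 15.0


def _series(values, fps=FPS):
    values = np.asarray(values, dtype=float)
    return np.arange(len(values)) / fps, values


def _rect(duration_s, level, total_s=10.0, start_s=3.0, fps=FPS):
    """Baseline-zero trace with one rectangular excursion."""
    t = np.arange(0, total_s, 1 / fps)
    y = np.zeros_like(t)
    y[(t >= start_s) & (t < start_s + duration_s)] = level
    return t, y


def _posture(times, crabspeed=None, head_angle=None, midline=None, larva_id="x"):
    n = len(times)
    fill = lambda v: np.full(n, np.nan) if v is None else np.asarray(v, dtype=float)
    return PostureSeries(
        larva_id=larva_id, times=np.asarray(times, dtype=float),
        speed=np.full(n, np.nan), crabspeed=fill(crabspeed),
        midline=fill(midline), width=np.full(n, np.nan), head_angle=fill(head_angle),
    )


class TestSchmittTrigger:
    def test_single_event_amplitude_and_duration(self):
        # rises to 3.0 for 0.5 s, then falls below the 1.8 mm/s lower bound
        t, y = _rect(0.5, 3.0)
        events, sig = schmitt_detect(t, y, DEFAULT_ROLL_THRESHOLDS)
        assert len(events) == 1
        ev = events[0]
        assert ev.amplitude == pytest.approx(3.0)
        assert ev.duration == pytest.approx(0.5, abs=1.5 / FPS)
        # event signal support equals the event interval
        inside = (t >= ev.t_start) & (t <= ev.t_end)
        assert np.all(sig.values[inside] == ev.amplitude)
        assert np.all(sig.values[~inside] == 0)

    def test_subthreshold_peak_ignored(self):
        t, y = _rect(0.5, 2.5)  # below the 2.8 upper threshold
        events, _ = schmitt_detect(t, y, DEFAULT_ROLL_THRESHOLDS)
        assert events == []

    def test_close_bursts_merge_into_one(self):
        # two 0.10 s bursts 0.5 s apart; each alone fails width 0.12 s but
        # the merged span passes
        t = np.arange(0, 5, 1 / FPS)
        y = np.zeros_like(t)
        for start in (1.0, 1.6):
            y[(t >= start) & (t < start + 0.10)] = 3.5
        thr = SchmittThresholds(2.8, 1.8, 0.12, 1.0)
        events, _ = schmitt_detect(t, y, thr)
        assert len(events) == 1
        assert events[0].duration >= thr.width

    def test_isolated_short_burst_rejected(self):
        t, y = _rect(0.05, 3.5)
        events, _ = schmitt_detect(t, y, SchmittThresholds(2.8, 1.8, 0.12, 1.0))
        assert events == []

    def test_open_event_truncated_at_track_end(self):
        t = np.arange(0, 3, 1 / FPS)
        y = np.where(t > 1.0, 3.5, 0.0)
        events, _ = schmitt_detect(t, y, DEFAULT_ROLL_THRESHOLDS)
        assert len(events) == 1
        assert events[0].truncated
        assert events[0].t_end == pytest.approx(t[-1])

    @pytest.mark.parametrize("polarity", ["peaks", "wells", "both"])
    def test_matches_bruteforce_state_machine(self, polarity, rng):
        thr = SchmittThresholds(1.0, 0.6, 0.15, 0.5)
        for _ in range(150):
            t, y = random_bump_signal(rng)
            events, _ = schmitt_detect(t, y, thr, polarity=polarity)
            got = [(e.t_start, e.t_end, e.amplitude, e.polarity, e.truncated) for e in events]
            expected = schmitt_reference(t, y, thr, polarity=polarity)
            assert len(got) == len(expected)
            for g, e in zip(got, expected):
                assert g[0] == pytest.approx(e[0]) and g[1] == pytest.approx(e[1])
                assert g[2] == pytest.approx(e[2])
                assert g[3:] == e[3:]

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_gap_monotonicity(self, seed):
        """A larger gap threshold can only merge more: never more events."""
        rng = np.random.default_rng(seed)
        t, y = random_bump_signal(rng, n_bumps=int(rng.integers(2, 8)))
        thr_small = SchmittThresholds(1.0, 0.6, 0.1, 0.3)
        thr_large = SchmittThresholds(1.0, 0.6, 0.1, 1.2)
        n_small = len(schmitt_detect(t, y, thr_small)[0])
        n_large = len(schmitt_detect(t, y, thr_large)[0])
        assert n_large <= n_small

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_upper_threshold_monotonicity_without_merging(self, seed):
        """With bursts too far apart to merge, raising the upper amplitude
        threshold never increases the event count."""
        rng = np.random.default_rng(seed)
        t = np.arange(0, 40, 1 / FPS)
        y = np.zeros_like(t)
        for k in range(6):
            start = 2.0 + 6.0 * k  # separations far exceed the 0.5 s gap
            amp = rng.uniform(0.5, 2.5)
            dur = rng.uniform(0.1, 1.0)
            inside = (t >= start) & (t <= start + dur)
            y[inside] = amp * np.sin(np.pi * (t[inside] - start) / dur)
        lo = SchmittThresholds(1.0, 0.6, 0.15, 0.5)
        hi = SchmittThresholds(1.8, 0.6, 0.15, 0.5)
        assert len(schmitt_detect(t, y, hi)[0]) <= len(schmitt_detect(t, y, lo)[0])


class TestRollDetector:
    def test_paper_scale_burst_is_one_roll(self):
        t = np.arange(0, 10, 1 / FPS)
        y = np.zeros_like(t)
        inside = (t >= 4.0) & (t <= 5.0)
        y[inside] = 4.66 * np.sin(np.pi * (t[inside] - 4.0) / 1.0)
        rolls = detect_rolls(_posture(t, crabspeed=y))
        assert len(rolls) == 1
        assert rolls[0].type == "roll"
        assert rolls[0].amplitude == pytest.approx(4.66, rel=0.02)

    def test_flat_crabspeed_no_rolls(self):
        t, y = _series(np.full(150, 0.2))
        assert detect_rolls(_posture(t, crabspeed=y)) == []

    def test_two_separated_bursts_two_rolls(self):
        t = np.arange(0, 10, 1 / FPS)
        y = np.zeros_like(t)
        for start in (2.0, 6.0):  # 2 s >> 1 s gap apart (end to start)
            y[(t >= start) & (t < start + 0.5)] = 4.0
        assert len(detect_rolls(_posture(t, crabspeed=y))) == 2

    def test_missing_crabspeed_warns_empty(self, caplog):
        import logging
        t = np.arange(0, 5, 1 / FPS)
        with caplog.at_level(logging.WARNING):
            assert detect_rolls(_posture(t)) == []
        assert any("crabspeed" in r.message for r in caplog.records)


class TestCastDetector:
    def _angle(self, excursion):
        t = np.arange(0, 8, 1 / FPS)
        y = np.zeros_like(t)
        y[(t >= 3.0) & (t < 3.3)] = excursion
        return t, y

    def test_positive_excursion_is_left_cast(self):
        t, y = self._angle(40.0)
        casts = detect_casts(_posture(t, head_angle=y))
        assert [c.type for c in casts] == ["cast_left"]

    def test_negative_excursion_is_right_cast(self):
        t, y = self._angle(-40.0)
        casts = detect_casts(_posture(t, head_angle=y))
        assert [c.type for c in casts] == ["cast_right"]

    def test_below_upper_threshold_rejected(self):
        t, y = self._angle(22.0)  # below the 27 deg upper threshold
        assert detect_casts(_posture(t, head_angle=y)) == []

    def test_cast_inside_roll_discarded(self):
        t, y = self._angle(40.0)
        roll = EventRecord("x", "roll", 2.8, 3.6, 0.8, 5.0)
        assert detect_casts(_posture(t, head_angle=y), concurrent_rolls=[roll]) == []


class TestHunchDetector:
    def _midline(self, dip, dur=0.4, length=4.0):
        t = np.arange(0, 20, 1 / FPS)
        y = np.full_like(t, length)
        y[(t >= 9.0) & (t < 9.0 + dur)] -= dip
        return t, y

    def test_dip_below_baseline_is_hunch(self):
        t, y = self._midline(0.25)
        hunches = detect_hunches(_posture(t, midline=y))
        assert [h.type for h in hunches] == ["hunch"]
        assert hunches[0].polarity == "well"

    def test_shallow_dip_rejected(self):
        t, y = self._midline(0.05)  # below the 0.19 mm upper threshold
        assert detect_hunches(_posture(t, midline=y)) == []

    def test_dip_during_roll_discarded(self):
        t, y = self._midline(0.25)
        roll = EventRecord("x", "roll", 8.5, 9.8, 1.3, 5.0)
        assert detect_hunches(_posture(t, midline=y), concurrent_rolls=[roll]) == []

    def test_baseline_removes_slow_drift(self):
        # a 0.25 mm dip remains detectable on top of a 0.3 mm slow drift
        t = np.arange(0, 30, 1 / FPS)
        y = 4.0 + 0.01 * t
        y[(t >= 14.0) & (t < 14.5)] -= 0.25
        hunches = detect_hunches(_posture(t, midline=y))
        assert len(hunches) == 1


class TestEventFrequency:
    def _rolls(self, starts):
        return [EventRecord("a", "roll", s, s + 0.5, 0.5, 4.0) for s in starts]

    def test_counts_starts_in_half_open_window(self):
        assert event_frequency(self._rolls([1.0, 2.0, 6.0]), 0.0, 5.0) == 2

    def test_empty(self):
        assert event_frequency([], 0.0, 5.0) == 0

    def test_boundary_start_excluded(self):
        assert event_frequency(self._rolls([5.0]), 0.0, 5.0) == 0
        assert event_frequency(self._rolls([5.0]), 5.0, 10.0) == 1


class TestDetectionRates:
    def _truth(self):
        return [EventRecord("a", "roll", float(k), float(k) + 0.5, 0.5, 4.0)
                for k in range(0, 20, 2)]

    def test_perfect_detection(self):
        truth = self._truth()
        r = detection_rates(truth, truth)
        assert (r["fdr"], r["fnr"]) == (0.0, 0.0)

    def test_one_spurious_detection_gives_10pct_fdr(self):
        truth = self._truth()[:9]
        detected = truth + [EventRecord("a", "roll", 50.0, 50.5, 0.5, 4.0)]
        r = detection_rates(detected, truth)
        assert r["fdr"] == pytest.approx(0.10)
        assert r["fnr"] == 0.0

    def test_insufficient_overlap_counts_fp_and_fn(self):
        truth = [EventRecord("a", "roll", 1.0, 2.0, 1.0, 4.0)]
        detected = [EventRecord("a", "roll", 1.6, 2.6, 1.0, 4.0)]  # 0.4 overlap
        r = detection_rates(detected, truth, match_overlap=0.5)
        assert (r["tp"], r["fp"], r["fn"]) == (0, 1, 1)


class TestThresholdTuning:
    def _signals_and_truth(self, preset, n=100, seed=11):
        schedule = syn.make_schedule(n_larvae=n, seed=seed, preset=preset)
        series, truth = syn.simulate_signals(schedule)
        signals = {lid: (s.times, s.crabspeed) for lid, s in series.items()}
        rolls = [ev for ev in truth if ev.type == "roll"]
        return signals, rolls

    def test_defaults_compliant_on_clean_labels(self):
        signals, rolls = self._signals_and_truth("noxious-heat", n=40)
        assert len(rolls) >= 30
        d = DEFAULT_ROLL_THRESHOLDS
        grid = {"upper": [d.upper, d.upper * 1.2], "lower": [d.lower],
                "width": [d.width], "gap": [d.gap]}
        result = tune_thresholds(signals, rolls, "peaks", grid, event_type="roll")
        assert result.compliant
        assert result.thresholds == d  # first grid point already qualifies

    def test_adversarial_noise_flagged_noncompliant(self):
        signals, rolls = self._signals_and_truth("adversarial", n=100)
        assert len(rolls) >= 30
        grid = {"upper": [2.8, 2.0], "lower": [1.8, 1.0],
                "width": [0.12], "gap": [1.0]}
        result = tune_thresholds(signals, rolls, "peaks", grid, event_type="roll")
        assert not result.compliant
        # at least one tuning criterion is genuinely violated
        assert result.fdr >= 0.05 or result.fnr >= 0.15

    def test_degenerate_grid_returns_its_point(self):
        signals, rolls = self._signals_and_truth("noxious-heat", n=40)
        grid = {"upper": [5.0], "lower": [4.0], "width": [0.12], "gap": [1.0]}
        result = tune_thresholds(signals, rolls, "peaks", grid, event_type="roll")
        assert result.thresholds == SchmittThresholds(5.0, 4.0, 0.12, 1.0)
        assert 0.0 <= result.fdr <= 1.0 and 0.0 <= result.fnr <= 1.0

    def test_empty_labels_error(self):
        with pytest.raises(ValueError):
            tune_thresholds({}, [], "peaks",
                            {"upper": [1], "lower": [1], "width": [0.1], "gap": [0.1]})
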