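"""Feedback event stream: bar colours and terminal beeps."""

import numpy as np
import pytest

from crutchload import (
    AccuracyStatus,
    SessionConfig,
    WalkProfile,
    classify_stride,
    detect_supports,
    pair_supports,
    session_event_log,
    simulate_walk,
    terminal_events,
)
from crutchload.classify import BalanceStatus, ClassifiedStride
from crutchload.core import NotApplicableError
from crutchload.detection import Stride, Support
from crutchload.feedback import (
    BeepCause,
    DisplayMode,
    Tone,
    balance_episodes,
    concurrent_bar_stream,
    read_event_log,
    write_event_log,
)


def _classified(pct, config, offset=1100.0):
    peak = pct / 100.0 * config.ideal_total
    left = Support("left", 0.0, offset, peak / 2, offset / 2)
    right = Support("right", 0.0, offset, peak / 2, offset / 2)
    stride = Stride(1, left, right, onset_lag=0.0)
    return classify_stride(stride, config)


def _analyzed(profile, config):
    left, right, truth = simulate_walk(profile, config)
    strides = pair_supports(detect_supports(left, config),
                            detect_supports(right, config), config)
    return left, right, [classify_stride(s, config) for s in strides]


class TestTerminalEvents:
    def test_correct_stride_is_silent(self, config100):
        assert terminal_events(_classified(100.0, config100), config100) == []

    def test_underload_beeps_high_tone(self, config100):
        beeps = terminal_events(_classified(61.09, config100), config100)
        assert len(beeps) == 1
        assert beeps[0].tone is Tone.HIGH
        assert beeps[0].cause is BeepCause.UNDERLOAD_CRUTCHES
        assert beeps[0].duration == 300.0

    def test_overload_beeps_standard_tone(self, config100):
        beeps = terminal_events(_classified(203.98, config100), config100)
        assert len(beeps) == 1
        assert beeps[0].tone is Tone.STANDARD
        assert beeps[0].cause is BeepCause.OVERLOAD_CRUTCHES

    def test_beep_at_later_support_offset(self, config100):
        cs = _classified(150.0, config100, offset=1250.0)
        assert terminal_events(cs, config100)[0].time == 1250.0


class TestBarStream:
    def test_all_correct_walk_is_all_green(self, clean_walk, clean_profile, config100):
        left, right, _ = clean_walk
        strides = pair_supports(detect_supports(left, config100),
                                detect_supports(right, config100), config100)
        classified = [classify_stride(s, config100) for s in strides]
        for mode in DisplayMode:
            states = concurrent_bar_stream(left, right, classified, mode, config100)
            assert len(states) == len(left)
            assert all(s.color == "green" for s in states)

    def test_overload_turns_red_until_support_end(self, config100):
        profile = WalkProfile(n_strides=3, target_pct_mean=150.0, target_pct_sd=0.0,
                              left_share_sd=0.0, asynchrony_ms_sd=0.0,
                              noise_sd=0.0, seed=1)
        left, right, classified = _analyzed(profile, config100)
        states = concurrent_bar_stream(left, right, classified, "single", config100)
        red_times = [s.time for s in states if s.color == "red"]
        assert red_times, "overloaded walk must show red states"
        # red persists to each support's end once triggered
        for cs in classified:
            in_sup = [s for s in states
                      if cs.stride.onset <= s.time <= cs.stride.offset]
            reds = [s.color == "red" for s in in_sup]
            assert any(reds)
            first_red = reds.index(True)
            assert all(reds[first_red:]), "red must be sticky until support end"

    def test_underload_revealed_terminally(self, config100):
        profile = WalkProfile(n_strides=3, target_pct_mean=70.0, target_pct_sd=0.0,
                              left_share_sd=0.0, asynchrony_ms_sd=0.0,
                              noise_sd=0.0, seed=1)
        left, right, classified = _analyzed(profile, config100)
        states = concurrent_bar_stream(left, right, classified, "single", config100)
        for cs in classified:
            during = [s for s in states
                      if cs.stride.onset <= s.time <= cs.stride.offset]
            after = [s for s in states
                     if cs.stride.offset < s.time <= cs.stride.offset + 300.0]
            assert all(s.color == "green" for s in during), \
                "underload cannot be confirmed during loading"
            assert after and all(s.color == "red" for s in after), \
                "underload must flash red for 300 ms after the support"

    def test_balance_mode_red_and_clamped_position(self, config100):
        n = 50
        t = 12.5 * np.arange(n)
        from crutchload import ForceSeries
        left = ForceSeries("left", 80.0, t, np.full(n, 26.3))
        right = ForceSeries("right", 80.0, t, np.full(n, 23.7))
        states = concurrent_bar_stream(left, right, [], "balance", config100)
        assert all(s.color == "red" for s in states)          # diff 2.6 > 2.5
        assert all(s.balance_position == pytest.approx(1.0) for s in states)

    def test_balance_mode_rejected_in_unilateral(self, config100):
        cfg = SessionConfig(body_weight=100.0, gait_mode="unilateral")
        from crutchload import ForceSeries
        t = 12.5 * np.arange(10)
        s = ForceSeries("left", 80.0, t, np.zeros(10))
        s2 = ForceSeries("right", 80.0, t, np.zeros(10))
        with pytest.raises(NotApplicableError):
            concurrent_bar_stream(s, s2, [], "balance", cfg)


class TestSessionEventLog:
    def test_empty_session_empty_log(self, config100):
        from crutchload import ForceSeries
        empty = ForceSeries("left", 80.0, [], [])
        empty_r = ForceSeries("right", 80.0, [], [])
        assert session_event_log(empty, empty_r, [], "double", config100) == []

    def test_all_correct_walk_no_beeps(self, clean_walk, config100):
        left, right, _ = clean_walk
        strides = pair_supports(detect_supports(left, config100),
                                detect_supports(right, config100), config100)
        classified = [classify_stride(s, config100) for s in strides]
        events = session_event_log(left, right, classified, "double", config100)
        assert sum(e["kind"] == "beep" for e in events) == 0

    @pytest.mark.parametrize("mode", ["double", "single"])
    @pytest.mark.parametrize("seed", [3, 17, 42])
    def test_beep_count_equals_error_count(self, config100, mode, seed):
        profile = WalkProfile(target_pct_mean=103.0, target_pct_sd=4.0, seed=seed)
        left, right, classified = _analyzed(profile, config100)
        n_errors = sum(cs.accuracy is not AccuracyStatus.CORRECT
                       for cs in classified)
        events = session_event_log(left, right, classified, mode, config100)
        assert sum(e["kind"] == "beep" for e in events) == n_errors

    def test_events_time_ordered_and_deterministic(self, config100):
        profile = WalkProfile(target_pct_mean=110.0, target_pct_sd=5.0, seed=8)
        left, right, classified = _analyzed(profile, config100)
        a = session_event_log(left, right, classified, "double", config100)
        b = session_event_log(left, right, classified, "double", config100)
        assert a == b
        times = [e["time"] for e in a]
        assert times == sorted(times)

    def test_beeps_never_overlap(self, config100):
        profile = WalkProfile(target_pct_mean=150.0, target_pct_sd=30.0, seed=21)
        left, right, classified = _analyzed(profile, config100)
        events = session_event_log(left, right, classified, "double", config100)
        beep_times = sorted(e["time"] for e in events if e["kind"] == "beep")
        assert all(b - a >= 300.0 for a, b in zip(beep_times, beep_times[1:]))

    def test_mode_equivalence_of_error_set(self, config100):
        """Displayed mode changes the bars, not which strides are wrong."""
        profile = WalkProfile(target_pct_mean=104.0, target_pct_sd=3.0, seed=5)
        left, right, classified = _analyzed(profile, config100)
        double = session_event_log(left, right, classified, "double", config100)
        single = session_event_log(left, right, classified, "single", config100)
        beeps_d = [(e["time"], e["cause"]) for e in double if e["kind"] == "beep"]
        beeps_s = [(e["time"], e["cause"]) for e in single if e["kind"] == "beep"]
        assert beeps_d == beeps_s

    def test_balance_mode_one_beep_per_episode(self, config100):
        profile = WalkProfile(n_strides=6, target_pct_mean=100.0, target_pct_sd=0.0,
                              left_share_mean=0.58, left_share_sd=0.0,
                              asynchrony_ms_sd=0.0, noise_sd=0.0, seed=2)
        left, right, classified = _analyzed(profile, config100)
        episodes = balance_episodes(left, right, config100)
        assert len(episodes) == 6  # one violation episode per stride (8 kgf diff)
        events = session_event_log(left, right, classified, "balance", config100)
        assert sum(e["kind"] == "beep" for e in events) == 6
        assert all(e["cause"] == "imbalance" for e in events if e["kind"] == "beep")

    def test_log_round_trip(self, tmp_path, config100):
        profile = WalkProfile(target_pct_mean=110.0, target_pct_sd=5.0, seed=8)
        left, right, classified = _analyzed(profile, config100)
        events = session_event_log(left, right, classified, "double", config100)
        p = tmp_path / "events.jsonl"
        write_event_log(events, p)
        back = read_event_log(p)
        assert len(back) == len(events)
        assert [e["time_ms"] for e in back] == [e["time"] for e in events]
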