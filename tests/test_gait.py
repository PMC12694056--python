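"""Straight-walking detection, gait events and spatiotemporal metrics."""

import numpy as np
import pytest

from headgait.gait import (
    compute_heading,
    detect_double_support,
    detect_heel_strikes_mdht,
    detect_straight_walking,
    max_gait_speed,
    step_metrics,
)
from headgait.segments import GaitEventList, MotorStateSegment

from conftest import make_series
from oracles import moving_average_max

RATE = 50.0


class TestComputeHeading:
    def test_straight_path_along_x(self):
        t = np.arange(0, 5, 1 / RATE)
        hs = compute_heading(1.2 * t, np.zeros_like(t), RATE)
        assert np.allclose(hs.heading, 0.0, atol=1e-6)
        assert np.allclose(hs.inst_speed[2:-2], 1.2, atol=1e-9)

    def test_straight_path_along_y(self):
        t = np.arange(0, 5, 1 / RATE)
        hs = compute_heading(np.zeros_like(t), 1.2 * t, RATE)
        assert np.allclose(hs.heading, 90.0, atol=1e-6)

    def test_quarter_circle_heading_range(self):
        # radius 2 m quarter circle: heading sweeps 90 degrees
        phi = np.linspace(0, np.pi / 2, 400)
        hs = compute_heading(2 * np.sin(phi), 2 * (1 - np.cos(phi)), RATE)
        rng = hs.heading.max() - hs.heading.min()
        assert rng == pytest.approx(90.0, abs=1.0)

    def test_stationary_trajectory_flagged(self):
        hs = compute_heading(np.zeros(100), np.zeros(100), RATE)
        assert hs.stationary
        assert np.all(np.isnan(hs.heading))

    def test_arc_length_non_decreasing(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(0, 0.02, 500))
        y = np.cumsum(rng.normal(0, 0.02, 500))
        hs = compute_heading(x, y, RATE)
        assert np.all(np.diff(hs.arc_length) >= 0)


def _walk_series(dist, speed=1.2, stand=3.0, yaw=None):
    """Stand - walk ``dist`` metres at ``speed`` along +x - stand."""
    t_walk = dist / speed
    t = np.arange(0, 2 * stand + t_walk, 1 / RATE)
    x = np.clip(t - stand, 0, t_walk) * speed
    yaw_arr = np.zeros_like(t) if yaw is None else yaw(t)
    return make_series(t, x=x, yaw=yaw_arr, rate=RATE)


class TestDetectStraightWalking:
    def test_single_bout_spans_moving_frames(self):
        s = _walk_series(5.0)
        segs = detect_straight_walking(s)
        assert len(segs) == 1
        (seg,) = segs
        assert seg.start / RATE == pytest.approx(3.0, abs=0.1)
        assert seg.end / RATE == pytest.approx(3.0 + 5 / 1.2, abs=0.1)

    def test_short_bout_rejected_by_length(self):
        segs = detect_straight_walking(_walk_series(1.5))
        assert segs == []

    def test_midcourse_turn_splits_bout(self):
        # 8 m path with a sharp 90-degree turn halfway, slowing to 0.4 m/s
        # through the turn: two straight segments, the turning frames in
        # neither (they fail the minimum-speed criterion)
        leg = 4.0
        speed = 1.2
        turn_speed = 0.4
        r = 0.3  # sharp arc radius
        t_leg = (leg - r) / speed
        t_arc = (np.pi / 2) * r / turn_speed
        t = np.arange(0, 2 * t_leg + t_arc + 6, 1 / RATE)
        x = np.empty_like(t)
        y = np.empty_like(t)
        for i, ti in enumerate(t):
            ti -= 3.0
            if ti < 0:
                x[i], y[i] = 0, 0
            elif ti < t_leg:
                x[i], y[i] = speed * ti, 0
            elif ti < t_leg + t_arc:
                a = (ti - t_leg) * turn_speed / r
                x[i] = (leg - r) + r * np.sin(a)
                y[i] = r * (1 - np.cos(a))
            elif ti < 2 * t_leg + t_arc:
                x[i], y[i] = leg, r + speed * (ti - t_leg - t_arc)
            else:
                x[i], y[i] = leg, r + speed * t_leg
        s = make_series(t, x=x, y=y, rate=RATE)
        segs = detect_straight_walking(s)
        assert len(segs) == 2
        arc_mid = 3.0 + t_leg + t_arc / 2
        for seg in segs:
            assert not (seg.start / RATE <= arc_mid < seg.end / RATE)

    def test_slow_frames_never_inside_segments(self):
        s = _walk_series(5.0)
        from headgait.gait import compute_heading as ch
        hs = ch(s.x, s.y, RATE)
        for seg in detect_straight_walking(s):
            assert np.all(hs.inst_speed[seg.start:seg.end] > 0.5)

    def test_yaw_scanning_splits_bout(self):
        # straight path but yaw sweeping 120 degrees: yaw-range criterion
        s = _walk_series(8.0, yaw=lambda t: 120.0 * np.clip((t - 3) / (8 / 1.2), 0, 1))
        segs = detect_straight_walking(s)
        assert len(segs) >= 2
        for seg in segs:
            yr = s.yaw[seg.start:seg.end]
            assert yr.max() - yr.min() < 45.0


class TestMaxGaitSpeed:
    def test_constant_speed(self):
        s = _walk_series(6.0)
        seg = MotorStateSegment("straight_walking", int(3.2 * RATE), int(7.5 * RATE))
        assert max_gait_speed(seg, s) == pytest.approx(1.2, abs=1e-6)

    def test_ramp_matches_moving_average_oracle(self):
        t = np.arange(0, 4, 1 / RATE)
        speed = 0.8 + 0.2 * t  # 0.8 -> 1.6 m/s
        x = np.concatenate([[0], np.cumsum(speed[:-1]) / RATE])
        s = make_series(t, x=x, rate=RATE)
        seg = MotorStateSegment("straight_walking", 0, len(t))
        got = max_gait_speed(seg, s)
        dx = np.gradient(x)
        dy = np.gradient(np.zeros_like(x))
        inst = np.hypot(dx, dy) * RATE
        assert got == pytest.approx(moving_average_max(inst, int(0.5 * RATE)), abs=1e-9)
        assert got < 1.6  # half-window slope loss

    def test_filtering_beats_raw_peak_under_noise(self):
        t = np.arange(0, 10, 1 / RATE)
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            speed = 1.2 + rng.normal(0, 0.2, len(t))
            x = np.concatenate([[0], np.cumsum(speed[:-1]) / RATE])
            s = make_series(t, x=x, rate=RATE)
            seg = MotorStateSegment("straight_walking", 0, len(t))
            filtered_peak = max_gait_speed(seg, s)
            raw_peak = (np.hypot(np.gradient(x), 0) * RATE).max()
            assert abs(filtered_peak - 1.2) < abs(raw_peak - 1.2)

    def test_short_segment_undefined(self):
        s = _walk_series(5.0)
        seg = MotorStateSegment("straight_walking", 150, 160)
        assert max_gait_speed(seg, s) is None


def _mdht_signal(hs_times, t, peak=0.12, delay=0.15, dip=0.01):
    sig = np.zeros_like(t)
    for th in hs_times:
        sig += (peak * np.exp(-((t - (th + delay)) ** 2) / (2 * 0.05 ** 2))
                - dip * np.exp(-((t - th) ** 2) / (2 * 0.04 ** 2)))
    return sig


class TestHeelStrikes:
    def test_events_on_truth_within_one_frame(self):
        t = np.arange(0, 12, 1 / RATE)
        hs_times = np.arange(1.0, 10.5, 0.55)
        left = _mdht_signal(hs_times[::2], t)
        right = _mdht_signal(hs_times[1::2], t)
        ev = detect_heel_strikes_mdht(np.column_stack([left, right]),
                                      np.zeros((len(t), 2)), RATE)
        assert len(ev) == len(hs_times)
        det_t = ev.frames / RATE
        # each true heel strike (MDHT minimum) found within one frame
        for th in hs_times:
            assert np.min(np.abs(det_t - th)) <= 1.5 / RATE

    def test_flat_signals_no_events(self):
        z = np.zeros(500)
        ev = detect_heel_strikes_mdht(z, z, RATE)
        assert len(ev) == 0

    def test_small_drop_rejected(self):
        # peak only 0.03 m above its preceding minimum: below the 0.04 m rule
        t = np.arange(0, 6, 1 / RATE)
        sig = _mdht_signal(np.arange(1.0, 5.0, 1.0), t, peak=0.03)
        ev = detect_heel_strikes_mdht(sig, np.zeros_like(sig), RATE)
        assert len(ev) == 0

    def test_minimum_with_large_absolute_value_rejected(self):
        t = np.arange(0, 6, 1 / RATE)
        sig = 0.06 + _mdht_signal(np.arange(1.0, 5.0, 1.0), t)  # |min| = 0.06
        ev = detect_heel_strikes_mdht(sig, np.zeros_like(sig), RATE)
        assert len(ev) == 0


class TestDoubleSupport:
    def test_two_hz_bounce_gives_half_second_spacing(self):
        t = np.arange(0, 6, 1 / RATE)
        ev = detect_double_support(0.02 * np.cos(2 * np.pi * 2 * t), RATE)
        spacing = np.diff(ev.frames) / RATE
        assert np.all(np.abs(spacing - 0.5) <= 1.5 / RATE)
        assert len(ev) >= 9

    def test_constant_z_no_events(self):
        assert len(detect_double_support(np.full(300, 1.5), RATE)) == 0

    def test_minimum_distance_rule_enforced(self):
        # 2 Hz bounce with a 4.5 Hz component creating nearby secondary minima
        t = np.arange(0, 6, 1 / RATE)
        z = 0.02 * np.cos(2 * np.pi * 2 * t) + 0.008 * np.cos(2 * np.pi * 4.5 * t)
        ev = detect_double_support(z, RATE)
        assert len(ev) > 0
        assert np.all(np.diff(ev.frames) >= 13)

    def test_short_segment_no_events(self):
        assert len(detect_double_support(np.zeros(30), RATE)) == 0


class TestStepMetrics:
    def test_regular_events_while_translating(self):
        t = np.arange(0, 10, 1 / RATE)
        s = make_series(t, x=1.2 * t, rate=RATE)
        frames = np.arange(25, 475, 25)  # every 0.5 s
        m = step_metrics(GaitEventList(frames, "heel_strike"), s)
        assert m.values["step_length_m"] == pytest.approx(0.6, abs=1e-9)
        assert m.values["cadence_spm"] == pytest.approx(120.0, abs=1e-9)

    def test_single_event_undefined(self):
        t = np.arange(0, 2, 1 / RATE)
        s = make_series(t, x=t, rate=RATE)
        assert step_metrics(GaitEventList([10], "heel_strike"), s) is None

    def test_cadence_from_median_interval(self):
        # irregular intervals {24, 26, 25, 40}: median 25.5 -> 117.6 steps/min
        t = np.arange(0, 10, 1 / RATE)
        s = make_series(t, x=1.2 * t, rate=RATE)
        frames = np.cumsum([30, 24, 26, 25, 40])
        m = step_metrics(GaitEventList(frames, "double_support"), s)
        assert m.values["cadence_spm"] == pytest.approx(60 * RATE / 25.5, abs=1e-9)
        assert m.values["cadence_spm"] == pytest.approx(117.6, abs=0.1)
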