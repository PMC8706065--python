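import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from extrema_oracle import oracle_extrema
from vorx.compliance import (
    ComplianceReport,
    Extremum,
    ExtremaList,
    GazeSeries,
    HeadAngleSeries,
    Prescription,
    analyze_series,
    classify_intervals,
    compute_rewards,
    detect_extrema,
    gaze_compliance,
    interval_bpm,
    smooth,
)
from vorx.signal_sim import simulate_head_motion


def series_from(values, dt=1.0 / 30.0):
    values = np.asarray(values, float)
    return HeadAngleSeries(np.arange(len(values)) * dt, values)


class TestHeadAngleSeries:
    def test_rejects_non_monotone_times(self):
        with pytest.raises(ValueError, match="strictly increase"):
            HeadAngleSeries([0.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_rejects_nan(self):
        with pytest.raises(ValueError, match="finite"):
            HeadAngleSeries([0.0, 1.0], [0.0, np.nan])

    def test_rejects_short(self):
        with pytest.raises(ValueError, match="at least 2"):
            HeadAngleSeries([0.0], [1.0])


class TestSmooth:
    def test_constant_signal_unchanged(self):
        s = series_from(np.full(50, 3.7))
        out = smooth(s, 0.15)
        np.testing.assert_allclose(out.angles, 3.7, atol=1e-12)

    def test_zero_window_is_identity(self):
        s = series_from(np.sin(np.arange(30)))
        assert smooth(s, 0.0) is s

    def test_white_noise_variance_reduced_by_window_factor(self, rng):
        # 0.15 s window at 30 fps covers 5 samples -> variance ~ sigma^2/5
        x = rng.normal(0.0, 1.0, size=6000)
        out = smooth(series_from(x), 0.15)
        interior = out.angles[10:-10]
        ratio = np.var(interior) / np.var(x)
        assert ratio == pytest.approx(1.0 / 5.0, rel=0.15)

    def test_truncated_endpoint_window(self):
        # dt=1 s, window 2.2 s: first output averages samples 0 and 1 only
        s = HeadAngleSeries(np.arange(5.0), [0.0, 2.0, 4.0, 6.0, 8.0])
        out = smooth(s, 2.2)
        assert out.angles[0] == pytest.approx(1.0)
        assert out.angles[2] == pytest.approx(4.0)

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError, match="window_s"):
            smooth(series_from(np.zeros(10)), -1.0)


class TestDetectExtrema:
    def test_sinusoid_counts_heights_alternation(self, noise_free):
        s = simulate_head_motion(noise_free(120.0, nominal_fps=40.0))
        ex = detect_extrema(s, 4.0)
        assert ex.n_peaks == 30
        assert ex.n_valleys == 30
        kinds = [e.kind for e in ex]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        np.testing.assert_allclose([abs(e.height) for e in ex], 15.0, atol=1e-9)

    def test_small_sinusoid_below_threshold_dropped(self, noise_free):
        s = simulate_head_motion(noise_free(120.0, amplitude_deg=3.0))
        ex = detect_extrema(s, 4.0)
        assert len(ex) == 0

    def test_threshold_boundary(self):
        # fps=40 samples the extrema exactly, so heights are the amplitude
        t = np.arange(0, 30.025, 0.025)
        just_above = HeadAngleSeries(t, 4.1 * np.sin(2.0 * np.pi * t))
        just_below = HeadAngleSeries(t, 3.9 * np.sin(2.0 * np.pi * t))
        assert detect_extrema(just_above, 4.0).n_peaks == 30
        assert detect_extrema(just_below, 4.0).n_peaks == 0

    def test_two_lobed_region_keeps_only_main_peak(self):
        # positive region with a 15 deg maximum and a 10 deg shoulder, no
        # baseline crossing between them: the shoulder's prominence (4) is
        # below its height (10), so only the main peak survives
        values = [-10.0, 2.0, 15.0, 6.0, 10.0, 3.0, -10.0, -16.0]
        assert np.mean(values) == 0.0
        ex = detect_extrema(series_from(values), 4.0)
        assert [(e.kind, e.height) for e in ex] == [("peak", 15.0)]

    def test_matches_brute_force_oracle_on_fixture(self, rng):
        x = np.cumsum(rng.normal(0, 5, size=150))
        s = series_from(x)
        got = [(e.time, e.height, e.prominence, e.kind) for e in detect_extrema(s, 4.0)]
        assert got == oracle_extrema(s.times, s.angles, 4.0)

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-30, max_value=30, allow_nan=False, width=32),
            min_size=3,
            max_size=60,
        ),
        st.sampled_from([0.0, 2.0, 4.0]),
    )
    def test_oracle_equivalence_property(self, values, min_height):
        s = series_from(values)
        got = [(e.time, e.height, e.prominence, e.kind) for e in detect_extrema(s, min_height)]
        assert got == oracle_extrema(s.times, s.angles, min_height)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=3,
            max_size=100,
        )
    )
    def test_alternation_invariant(self, values):
        ex = detect_extrema(series_from(values), 4.0)  # constructor enforces
        kinds = [e.kind for e in ex]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            detect_extrema(series_from([0.0, 1.0]), 4.0)


class TestIntervalBpm:
    @pytest.mark.parametrize(
        "dt,kind,expected",
        [
            (1.0, "peak_to_peak", 120.0),
            (0.375, "adjacent_extrema", 160.0),
            (1.5, "peak_to_peak", 80.0),
        ],
    )
    def test_examples(self, dt, kind, expected):
        assert interval_bpm(dt, kind) == pytest.approx(expected)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError, match="dt_s"):
            interval_bpm(0.0)


def extrema_with_peak_interval(dt: float) -> ExtremaList:
    return ExtremaList(
        (
            Extremum(0.0, 15.0, 20.0, "peak"),
            Extremum(dt / 2, -15.0, 20.0, "valley"),
            Extremum(dt, 15.0, 20.0, "peak"),
        )
    )


class TestClassifyIntervals:
    @pytest.mark.parametrize(
        "measured,label",
        [(130.0, "correct"), (136.0, "fast"), (104.0, "slow"), (105.0, "correct"), (135.0, "correct")],
    )
    def test_window_boundaries_at_goal_120(self, measured, label):
        rx = Prescription(goal_bpm=120.0)
        report = classify_intervals(extrema_with_peak_interval(120.0 / measured), rx)
        assert report.intervals[0].label == label
        assert report.intervals[0].measured_bpm == pytest.approx(measured)

    def test_noise_free_trial_fully_compliant(self, noise_free):
        s = simulate_head_motion(noise_free(120.0))
        report = analyze_series(s, Prescription(goal_bpm=120.0))
        assert report.percent_correct == 100.0

    def test_percent_correct_definition(self):
        rx = Prescription(goal_bpm=120.0)
        ex = ExtremaList(
            (
                Extremum(0.0, 15.0, 20.0, "peak"),
                Extremum(0.5, -15.0, 20.0, "valley"),
                Extremum(1.0, 15.0, 20.0, "peak"),  # peak interval 1.0 -> 120 correct
                Extremum(1.5, -15.0, 20.0, "valley"),  # valley interval 1.0 -> 120 correct
                Extremum(3.0, 15.0, 20.0, "peak"),  # peak interval 2.0 -> 60 slow
            )
        )
        report = classify_intervals(ex, rx)
        assert report.n_intervals == 3
        assert report.percent_correct == pytest.approx(100.0 * 2 / 3)

    def test_fewer_than_two_extrema_flagged(self):
        rx = Prescription(goal_bpm=120.0)
        ex = ExtremaList((Extremum(0.0, 15.0, 20.0, "peak"),))
        report = classify_intervals(ex, rx)
        assert report.n_intervals == 0
        assert report.percent_correct is None
        assert report.mean_bpm is None

    def test_widening_delta_never_decreases_percent_correct(self, rng):
        times = np.cumsum(rng.uniform(0.5, 2.0, size=20))
        items = []
        for i, t in enumerate(times):
            kind = "peak" if i % 2 == 0 else "valley"
            items.append(Extremum(float(t), 15.0 if kind == "peak" else -15.0, 20.0, kind))
        ex = ExtremaList(tuple(items))
        percents = []
        for delta in (5.0, 15.0, 30.0, 60.0):
            rx = Prescription(goal_bpm=120.0, compliance_delta_bpm=delta)
            percents.append(classify_intervals(ex, rx).percent_correct)
        assert all(b >= a for a, b in zip(percents, percents[1:]))


class TestGazeCompliance:
    def test_all_on_target(self):
        g = GazeSeries(np.arange(10) / 30.0, np.ones(10, bool))
        assert gaze_compliance(g) == 100.0

    def test_counting(self):
        labels = np.zeros(200, bool)
        labels[:50] = True
        assert gaze_compliance(GazeSeries(np.arange(200) / 30.0, labels)) == 25.0

    def test_alternating_even_length(self):
        labels = np.arange(100) % 2 == 0
        assert gaze_compliance(GazeSeries(np.arange(100) / 30.0, labels)) == 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least 1"):
            GazeSeries(np.array([]), np.array([], dtype=bool))


class TestComputeRewards:
    @pytest.mark.parametrize(
        "completed,head,gaze,coins",
        [
            (True, 0.0, 0.0, 5),
            (True, 100.0, 100.0, 15),
            (False, 100.0, 100.0, 10),
            (False, 0.0, 0.0, 0),
            (True, 50.0, 0.0, 8),  # 2.5 rounds half away from zero -> 3
            (True, 49.0, 0.0, 7),  # 2.45 -> 2
        ],
    )
    def test_examples(self, completed, head, gaze, coins):
        assert compute_rewards(completed, head, gaze) == coins

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="head_percent"):
            compute_rewards(True, 101.0, 0.0)
        with pytest.raises(ValueError, match="gaze_percent"):
            compute_rewards(True, 0.0, -1.0)

    @given(
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=0, max_value=100),
        st.booleans(),
    )
    def test_range_and_monotonicity(self, head, gaze, completed):
        c = compute_rewards(completed, head, gaze)
        assert isinstance(c, int) and 0 <= c <= 15
        assert compute_rewards(completed, min(head + 10, 100.0), gaze) >= c
        assert compute_rewards(completed, head, min(gaze + 10, 100.0)) >= c
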