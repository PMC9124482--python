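"""Strike kinematics, posture measures, and VeDBA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eelflume.exceptions import EelflumeError
from eelflume.kinematics import (
    BodyTrack3D,
    StrikeEvent,
    detect_strikes,
    eye_polar,
    length_out_of_burrow,
    quartile3,
    reactive_distance,
    strike_metrics,
    successful_strike_rate,
    vedba_series,
)

FPS = 60.0


def make_event(eye_init, eye_capture, prey_capture=None, t=0.25):
    return StrikeEvent(
        t_init=0.0,
        t_capture=t,
        eye_init=np.asarray(eye_init, float),
        eye_capture=np.asarray(eye_capture, float),
        prey_capture=np.asarray(
            prey_capture if prey_capture is not None else eye_capture, float
        ),
    )


finite3 = st.tuples(
    st.floats(-0.2, 0.2), st.floats(-0.2, 0.2), st.floats(0.0, 0.3)
)


class TestLengthAndQuartile:
    @pytest.mark.parametrize(
        "polyline, expected",
        [
            ([(0, 0, 0), (0, 0, 0.12)], 0.12),
            ([(0, 0, 0), (0, 0, 0.05), (0.02, 0, 0.09)], 0.05 + 0.04472135954999579),
            ([(0, 0, 0)], 0.0),
        ],
    )
    def test_arc_length(self, polyline, expected):
        assert length_out_of_burrow(polyline) == pytest.approx(expected, abs=1e-12)

    def test_empty_polyline_rejected(self):
        with pytest.raises(ValueError):
            length_out_of_burrow([])

    @pytest.mark.parametrize(
        "series, expected",
        [
            ([0.08, 0.10, 0.12, 0.14], 0.125),
            ([0.1] * 10, 0.1),
            ([0.07], 0.07),
        ],
    )
    def test_quartile3_linear_interpolation(self, series, expected):
        assert quartile3(series) == pytest.approx(expected, abs=1e-12)

    def test_quartile3_empty_rejected(self):
        with pytest.raises(ValueError):
            quartile3([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 0.3), min_size=1, max_size=40))
    def test_quartile3_bounded_and_above_median(self, series):
        q3 = quartile3(series)
        assert min(series) - 1e-12 <= q3 <= max(series) + 1e-12
        assert q3 >= np.median(series) - 1e-12


class TestEyePolar:
    def test_polar_coordinates(self):
        track = BodyTrack3D(
            fps=FPS,
            frames=np.arange(3),
            data={"eye": np.array([[0.03, 0.04, 0.0], [0.0, 0.0, 0.1],
                                   [0.05, 0.0, 0.0]])},
        )
        out = eye_polar(track)
        np.testing.assert_allclose(out["r_m"], [0.05, 0.1, 0.05])
        assert out["azimuth_deg"][0] == pytest.approx(53.13010235)
        assert out["elevation_deg"][0] == pytest.approx(0.0, abs=1e-12)
        assert out["elevation_deg"][1] == pytest.approx(90.0)
        assert out["azimuth_deg"][2] == pytest.approx(0.0, abs=1e-12)

    def test_origin_flagged(self):
        track = BodyTrack3D(
            fps=FPS, frames=np.arange(1), data={"eye": np.zeros((1, 3))}
        )
        out = eye_polar(track)
        assert bool(out["origin_flag"][0])
        assert out["azimuth_deg"][0] == 0.0


class TestStrikeMetrics:
    def test_worked_example(self):
        ev = make_event((0.05, 0, 0.10), (0.02, 0.01, 0.08), t=0.25)
        m = strike_metrics(ev, U=0.2)
        assert m.strike_distance == pytest.approx(0.037416573867739, rel=1e-9)
        assert m.strike_speed_earth == pytest.approx(0.14966629547096, rel=1e-9)
        assert m.strike_speed_water == pytest.approx(0.12, rel=1e-9)
        assert m.reactive_distance == pytest.approx(0.03, rel=1e-9)

    def test_zero_displacement_pure_drift(self):
        ev = make_event((0.05, 0, 0.1), (0.05, 0, 0.1), t=0.5)
        m = strike_metrics(ev, U=0.1)
        assert m.strike_distance == 0.0
        assert m.strike_speed_earth == 0.0
        assert m.strike_speed_water == pytest.approx(0.1)

    def test_invalid_strike_time_rejected(self):
        with pytest.raises(ValueError):
            StrikeEvent(0.5, 0.5, np.zeros(3), np.ones(3) * 0.1, np.ones(3) * 0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(eye_init=finite3, eye_cap=finite3, t=st.floats(0.05, 2.0))
    def test_still_water_frames_coincide(self, eye_init, eye_cap, t):
        """At U=0 the earth and water frames agree and reactive distance
        equals strike distance."""
        ev = make_event(eye_init, eye_cap, t=t)
        m = strike_metrics(ev, U=0.0)
        assert m.strike_speed_water == pytest.approx(m.strike_speed_earth, abs=1e-12)
        assert m.reactive_distance == pytest.approx(m.strike_distance, rel=1e-9,
                                                    abs=1e-12)

    def test_reactive_distance_pure_streamwise_offset(self):
        eye = np.array([0.03, 0.0, 0.08])
        ev = make_event(eye, eye + [0.01, 0, 0], prey_capture=eye, t=0.1)
        assert reactive_distance(ev, U=0.25) == pytest.approx(0.025)

    def test_reactive_distance_bounds_lateral_offset(self):
        ev = make_event((0.0, 0.0, 0.1), (0.0, 0.02, 0.05),
                        prey_capture=(0.0, 0.02, 0.05), t=0.2)
        rd = reactive_distance(ev, U=0.15)
        assert rd >= np.linalg.norm([0.02, 0.05]) - 1e-12


class TestVedba:
    def test_constant_velocity_gives_zero(self):
        t = np.arange(100) / FPS
        pos = np.column_stack([0.01 * t, -0.02 * t, 0.005 + 0.0 * t])
        v = vedba_series(pos, FPS)
        assert v.mean == pytest.approx(0.0, abs=1e-12)
        assert len(v.vedba) == 98

    def test_quadratic_track_exact_second_difference(self):
        t = np.arange(120) / FPS
        pos = np.column_stack([0.5 * 2.0 * t**2, np.zeros_like(t), np.zeros_like(t)])
        v = vedba_series(pos, FPS)
        np.testing.assert_allclose(v.accel[:, 0], 2.0, rtol=1e-9)
        assert v.mean == pytest.approx(2.0, rel=1e-9)

    def test_sinusoid_closed_form(self):
        A, f = 0.01, 1.0
        t = np.arange(int(10 * FPS)) / FPS
        pos = np.zeros((len(t), 3))
        pos[:, 1] = A * np.sin(2 * np.pi * f * t)
        v = vedba_series(pos, FPS)
        expected = (2 / np.pi) * A * (2 * np.pi * f) ** 2
        assert v.mean == pytest.approx(expected, rel=0.005)

    def test_agrees_with_analytic_second_derivative(self):
        """O(fps^-2) agreement with the analytic acceleration of a smooth track."""
        t = np.arange(int(5 * FPS)) / FPS
        pos = np.column_stack(
            [0.01 * np.sin(3 * t), 0.02 * np.cos(2 * t), 0.005 * t**3]
        )
        v = vedba_series(pos, FPS)
        tc = t[1:-1]  # stencil centered at i+1
        analytic = np.column_stack(
            [-0.01 * 9 * np.sin(3 * tc), -0.02 * 4 * np.cos(2 * tc), 0.03 * tc]
        )
        assert np.max(np.abs(v.accel - analytic)) < 5.0 / FPS**2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(vx=st.floats(-0.1, 0.1), vy=st.floats(-0.1, 0.1), vz=st.floats(-0.1, 0.1))
    def test_invariant_to_constant_velocity_drift(self, vx, vy, vz):
        rng = np.random.default_rng(42)
        pos = rng.normal(0, 0.01, (60, 3))
        t = np.arange(60)[:, None] / FPS
        drifted = pos + t * np.array([vx, vy, vz])
        v0 = vedba_series(pos, FPS)
        v1 = vedba_series(drifted, FPS)
        np.testing.assert_allclose(v1.vedba, v0.vedba, rtol=1e-6, atol=1e-8)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            vedba_series(np.zeros((2, 3)), FPS)

    def test_frame_gaps_error_unless_interpolated(self):
        pos = np.zeros((5, 3))
        frames = np.array([0, 1, 2, 5, 6])
        with pytest.raises(EelflumeError):
            vedba_series(pos, FPS, frames=frames)
        v = vedba_series(pos, FPS, frames=frames, interpolate_gaps=True)
        assert v.interpolated
        assert len(v.vedba) == 5  # frames 0..6 filled -> 7 - 2


class TestStrikeRate:
    @pytest.mark.parametrize(
        "captured, strikes, expected",
        [(12, 10, 1.2), (0, 10, 0.0), (9.5, 10, 0.95)],
    )
    def test_rate(self, captured, strikes, expected):
        assert successful_strike_rate(captured, strikes) == pytest.approx(expected)

    def test_zero_strikes_rejected(self):
        with pytest.raises(ValueError):
            successful_strike_rate(3, 0)


class TestStrikeDetector:
    def test_detects_injected_lunge(self):
        n = 600
        pos = np.zeros((n, 3))
        pos[:, 2] = 0.1 + 0.001 * np.sin(np.arange(n) / 20)
        pos[300:310, 0] += np.linspace(0, 0.03, 10)  # fast 10-frame lunge
        track = BodyTrack3D(fps=FPS, frames=np.arange(n), data={"eye": pos})
        spans = detect_strikes(track)
        assert any(start <= 305 <= end for start, end in spans)
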