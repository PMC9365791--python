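"""Kinematics chain: parsing, label averaging, calibration, orientation, velocity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazestab.core import (
    AccelTrace,
    AlignmentError,
    AngularTrace,
    FormatError,
    InvalidParameterError,
    QualityError,
    UndefinedResultError,
)
from gazestab.kinematics import (
    Calibration,
    accel_to_orientation,
    align_traces,
    estimate_velocity,
    eye_trajectory,
    pixels_to_degrees,
    read_tracker_table,
    subtract_body_motion,
    write_tracker_table,
)
from gazestab.synthetic import make_tracker_table


class TestTrackerIO:
    def test_round_trip_through_csv(self, roll_fixture_clean, tmp_path):
        eye, _, _ = roll_fixture_clean
        table = make_tracker_table(eye, seed=0)
        path = tmp_path / "tracker.csv"
        write_tracker_table(table, path)
        back = read_tracker_table(path)
        assert back.n_frames == table.n_frames
        assert back.eye_labels == table.eye_labels
        assert np.allclose(back.xy("eye_1"), table.xy("eye_1"))

    def test_two_header_rows_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("bodyparts,eye_1,eye_1\ncoords,x,y\n0,1.0,2.0\n")
        with pytest.raises(FormatError, match="scorer"):
            read_tracker_table(path)

    def test_non_numeric_cell_reported_with_frame(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "scorer,s,s,s\nbodyparts,eye_1,eye_1,eye_1\ncoords,x,y,likelihood\n"
            "0,1.0,2.0,0.95\n1,oops,2.0,0.95\n"
        )
        with pytest.raises(FormatError, match="frame 1"):
            read_tracker_table(path)

    def test_large_table_round_trips_frame_count(self, tmp_path):
        n = 10_000
        eye = AngularTrace(np.arange(n) / 100.0, np.zeros(n))
        table = make_tracker_table(eye, jitter_px=0.1, seed=0)
        path = tmp_path / "big.csv"
        write_tracker_table(table, path)
        assert read_tracker_table(path).n_frames == n


class TestEyeTrajectory:
    def _square_table(self, n=20, lik=None):
        cols = {}
        corners = [(0, 0), (2, 0), (2, 2), (0, 2)]
        for i, (x, y) in enumerate(corners):
            name = f"eye_{i + 1}"
            cols[(name, "x")] = np.full(n, float(x))
            cols[(name, "y")] = np.full(n, float(y))
            cols[(name, "likelihood")] = np.ones(n) if lik is None else lik[i]
        df = pd.DataFrame(cols)
        df.columns = pd.MultiIndex.from_tuples(df.columns)
        from gazestab.kinematics import TrackerTable

        return TrackerTable(df, [f"eye_{i + 1}" for i in range(4)], [])

    def test_square_labels_average_to_centroid(self):
        xy, frac = eye_trajectory(self._square_table())
        assert frac == 0.0
        assert np.allclose(xy, [1.0, 1.0])

    def test_masked_frames_linearly_interpolated(self):
        n = 20
        lik = [np.ones(n) for _ in range(4)]
        lik[0][5:10] = 0.1  # drop one label for 5 frames
        table = self._square_table(n, lik)
        # make x ramp so interpolation is visible
        table.data[("eye_1", "x")] = np.arange(n, dtype=float)
        xy, frac = eye_trajectory(table, min_likelihood=0.8)
        assert frac == pytest.approx(5 / n)
        expected = (np.arange(n) + 2 + 2 + 0) / 4.0
        assert np.allclose(xy[:, 0], expected, atol=1e-12)

    def test_majority_masked_raises(self):
        n = 20
        lik = [np.ones(n) for _ in range(4)]
        lik[0][:15] = 0.0
        with pytest.raises(QualityError):
            eye_trajectory(self._square_table(n, lik))


class TestBodySubtraction:
    def test_constant_body_is_identity(self):
        eye = np.random.default_rng(0).normal(size=(50, 2))
        body = np.full((50, 2), 7.0)
        assert np.allclose(subtract_body_motion(eye, body), eye)

    def test_shared_sinusoid_removed_exactly(self):
        t = np.arange(200) / 100.0
        s = np.sin(2 * np.pi * 0.5 * t)[:, None]
        eye = np.cumsum(np.ones((200, 2)), axis=0) * 0.01
        corrected = subtract_body_motion(eye + s, np.full((200, 2), 3.0) + s)
        assert np.max(np.abs(corrected - (eye + s.mean()))) < 1e-9

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            subtract_body_motion(np.zeros((10, 2)), np.zeros((9, 2)))


class TestPixelsToDegrees:
    def test_zero_maps_to_zero(self):
        assert pixels_to_degrees(0.0, Calibration()) == 0.0

    def test_half_diameter_chord_is_sixty_degrees(self):
        cal = Calibration(eye_diameter_mm=2.0, mm_per_px=1.0)
        assert pixels_to_degrees(1.0, cal) == pytest.approx(60.0)

    def test_chord_and_arc_agree_in_small_angle_limit(self):
        cal_c = Calibration(eye_diameter_mm=1.0, mm_per_px=1.0, angle_mode="chord")
        cal_a = Calibration(eye_diameter_mm=1.0, mm_per_px=1.0, angle_mode="arc")
        d = 0.01
        chord = pixels_to_degrees(d, cal_c)
        arc = pixels_to_degrees(d, cal_a)
        assert chord == pytest.approx(arc, rel=1e-4)

    @given(st.floats(-0.9, 0.9))
    @settings(max_examples=50, deadline=None)
    def test_conversion_is_odd(self, d):
        cal = Calibration(eye_diameter_mm=1.0, mm_per_px=1.0)
        assert pixels_to_degrees(-d, cal) == pytest.approx(-pixels_to_degrees(d, cal))

    def test_y_axis_down_inverts_vertical_sign(self):
        cal = Calibration(eye_diameter_mm=2.0, mm_per_px=1.0, y_axis_down=True)
        assert pixels_to_degrees(1.0, cal, axis="y") == pytest.approx(-60.0)

    def test_displacement_beyond_diameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            pixels_to_degrees(3.0, Calibration(eye_diameter_mm=1.0, mm_per_px=1.0))


class TestAccelOrientation:
    def test_level_gravity_is_zero_orientation(self):
        acc = AccelTrace(np.arange(10) / 100, *(np.zeros(10), np.zeros(10), -np.ones(10)))
        out = accel_to_orientation(acc, smoothing_window=1)
        assert np.allclose(out["roll"].angle_deg, 0)
        assert np.allclose(out["pitch"].angle_deg, 0)

    def test_thirty_degree_roll_recovered(self):
        n = 10
        th = np.radians(30.0)
        acc = AccelTrace(
            np.arange(n) / 100,
            np.zeros(n), np.full(n, np.sin(th)), np.full(n, -np.cos(th)),
        )
        out = accel_to_orientation(acc, smoothing_window=1)
        assert np.allclose(out["roll"].angle_deg, 30.0)

    @pytest.mark.parametrize("angle", [-80.0, -30.0, 0.0, 45.0, 80.0])
    def test_identity_on_synthetic_gravity_rotation(self, angle):
        n = 50
        th = np.radians(angle)
        acc = AccelTrace(
            np.arange(n) / 100,
            np.zeros(n), np.full(n, np.sin(th)), np.full(n, -np.cos(th)),
        )
        out = accel_to_orientation(acc, smoothing_window=1)
        assert np.allclose(out["roll"].angle_deg, angle, atol=1e-9)

    def test_fixture_roll_recovered_within_half_degree_rms(self, roll_fixture_clean):
        _, head, _ = roll_fixture_clean
        rec = accel_to_orientation(head.accel)["roll"]
        rms = np.sqrt(np.mean((rec.angle_deg - head.trace.angle_deg) ** 2))
        assert rms < 0.5

    def test_zero_accel_rejected(self):
        acc = AccelTrace(np.arange(5) / 100, np.zeros(5), np.zeros(5), np.zeros(5))
        with pytest.raises(UndefinedResultError):
            accel_to_orientation(acc)


class TestVelocity:
    def test_linear_ramp_constant_velocity(self):
        t = np.arange(200) / 100.0
        trace = AngularTrace(t, 10.0 * t)
        v = estimate_velocity(trace)
        assert np.allclose(v[5:-5], 10.0, atol=1e-6)

    def test_sinusoid_derivative_amplitude(self):
        # 1% accuracy holds while the 70-ms window stays short against the
        # oscillation period (passband attenuation grows as (f w)^2)
        rate, f, A = 100.0, 1.0, 5.0
        t = np.arange(500) / rate
        trace = AngularTrace(t, A * np.sin(2 * np.pi * f * t))
        v = estimate_velocity(trace)[10:-10]  # interior: one-sided edge fits excluded
        assert np.max(np.abs(v)) == pytest.approx(2 * np.pi * f * A, rel=0.01)

    def test_noise_variance_below_first_differences(self):
        rng = np.random.default_rng(0)
        t = np.arange(500) / 100.0
        trace = AngularTrace(t, rng.normal(size=500))
        v = estimate_velocity(trace)
        fd = np.diff(trace.angle_deg) * 100.0
        assert np.var(v) < np.var(fd)

    def test_window_validation(self):
        t = np.arange(20) / 100.0
        trace = AngularTrace(t, np.zeros(20))
        with pytest.raises(InvalidParameterError):
            estimate_velocity(trace, window=4)
        with pytest.raises(InvalidParameterError):
            estimate_velocity(trace, window=21)


class TestAlignment:
    def test_identical_traces_have_zero_lag(self, roll_fixture_clean):
        eye, head, _ = roll_fixture_clean
        lag, _, _ = align_traces(head.trace, head.trace)
        assert lag == 0.0

    def test_known_shift_recovered_within_one_sample(self):
        t = np.arange(500) / 100.0
        x = np.exp(-((t - 2.0) ** 2) / 0.1)
        a = AngularTrace(t, x)
        b = AngularTrace(t, np.interp(t - 0.15, t, x))
        lag, _, _ = align_traces(b, a)
        assert lag == pytest.approx(0.15, abs=0.0101)

    def test_generator_latency_recovered(self, roll_fixture_clean):
        eye, head, truth = roll_fixture_clean
        lag, _, _ = align_traces(eye, head.trace)
        assert lag == pytest.approx(truth.latency_s, abs=0.0101)

    def test_constant_trace_rejected(self):
        t = np.arange(100) / 100.0
        with pytest.raises(UndefinedResultError):
            align_traces(AngularTrace(t, np.ones(100)), AngularTrace(t, np.ones(100)))
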