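"""Generator-side checks: every fixture kind carries recoverable ground truth."""

import numpy as np
import pytest

from gazestab.core import (
    CANONICAL_PROTOCOLS,
    InfeasibleConstructionError,
    InvalidParameterError,
    Modality,
    Plane,
    StimulusProtocol,
)
from gazestab.emg import detect_spikes
from gazestab.kinematics import Calibration, eye_trajectory
from gazestab.stats import lagged_pearson
from gazestab.synthetic import (
    GroundTruth,
    PLANE_GAIN_DEFAULTS,
    QUICK_AMPLITUDE_DEG,
    QUICK_DURATION_S,
    insert_nystagmus,
    make_emg_trial,
    make_head_motion,
    make_psp_train,
    make_swim_coupling,
    make_tracker_table,
    make_vor_eye_trace,
    vor_fixture,
)

from gazestab import synthetic


class TestHeadMotion:
    @pytest.mark.parametrize("amplitude,speed", CANONICAL_PROTOCOLS)
    def test_reaches_commanded_amplitude(self, amplitude, speed):
        head = make_head_motion(
            StimulusProtocol(Modality.VES, Plane.ROLL, amplitude, speed), 200.0
        )
        assert np.max(head.trace.angle_deg) == pytest.approx(amplitude, abs=1e-9)
        # returns to level at the end
        assert head.trace.angle_deg[-1] == pytest.approx(0.0, abs=1e-9)

    def test_zero_amplitude_gives_flat_trace_and_plain_gravity(self):
        head = make_head_motion(
            StimulusProtocol(Modality.VES, Plane.ROLL, 0.0, 48.7), 100.0,
            accel_noise_g=0.0,
        )
        assert np.all(head.trace.angle_deg == 0)
        assert np.allclose(head.accel.ax, 0) and np.allclose(head.accel.ay, 0)
        assert np.allclose(head.accel.az, -1.0)

    def test_velocity_integrates_back_to_angle(self):
        # corner (acceleration-step) error of the central difference shrinks
        # as dt^2; at 20 kHz the trapezoid round trip is sub-microdegree
        head = make_head_motion(
            StimulusProtocol(Modality.VES, Plane.ROLL, 22.7, 112.94), 20_000.0
        )
        t, th = head.trace.t, head.trace.angle_deg
        v = np.gradient(th, t)
        recon = np.concatenate(([0.0], np.cumsum((v[1:] + v[:-1]) / 2 * np.diff(t))))
        assert np.max(np.abs(recon - th)) < 1e-6

    def test_peak_velocity_matches_profile(self):
        head = make_head_motion(
            StimulusProtocol(Modality.VES, Plane.ROLL, 22.7, 112.94), 1000.0
        )
        v = np.gradient(head.trace.angle_deg, head.trace.t)
        assert np.max(np.abs(v)) == pytest.approx(head.peak_velocity_deg_s, rel=0.02)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_head_motion(StimulusProtocol(), sample_rate=10.0)
        with pytest.raises(InvalidParameterError):
            StimulusProtocol(speed_deg_s=-1.0)


class TestVorEyeTrace:
    def test_unity_gains_mirror_the_head(self):
        head = make_head_motion(
            StimulusProtocol(Modality.VES, Plane.ROLL, 30.0, 120.0), 100.0,
            return_to_level=False,
        )
        truth = GroundTruth(position_gain=1.0, dynamic_gain=1.0)
        eye, out = make_vor_eye_trace(head, truth, noise_deg=0.0)
        assert out.latency_s == 0.0
        assert np.allclose(eye.angle_deg, -head.trace.angle_deg)

    @pytest.mark.parametrize("plane", ["roll", "pitch", "yaw"])
    def test_noise_free_estimators_recover_both_gains(self, plane):
        from gazestab.gaze import active_window, dynamic_gain, position_gain

        eye, head, truth = vor_fixture(plane, seed=1, noise_deg=0.0)
        dyn_true, pos_true = PLANE_GAIN_DEFAULTS[Plane(plane)]
        w = active_window(head.trace)
        assert position_gain(eye, head.trace, window=w).gain == pytest.approx(
            pos_true, abs=1e-3
        )
        assert dynamic_gain(eye, head.trace).gain == pytest.approx(dyn_true, abs=1e-3)

    def test_position_gain_above_dynamic_is_infeasible(self):
        head = make_head_motion(
            StimulusProtocol(Modality.VES, Plane.ROLL, 30.0, 120.0), 100.0,
            return_to_level=False,
        )
        with pytest.raises(InfeasibleConstructionError):
            make_vor_eye_trace(head, GroundTruth(position_gain=0.9, dynamic_gain=0.6))


class TestNystagmusInsertion:
    def test_orbit_beyond_excursion_means_no_quick_phases(self):
        head = make_head_motion(
            StimulusProtocol(Modality.VES, Plane.YAW, 180.0, 137.0), 100.0,
            return_to_level=False,
        )
        slow = head.trace.copy(angle_deg=-0.05 * head.trace.angle_deg)
        truth = GroundTruth(position_gain=0.05, dynamic_gain=0.05)
        _, seg, _ = insert_nystagmus(slow, truth, orbit_limit_deg=50.0, seed=1)
        assert seg.n_quick == 0
        assert len(seg.of_kind("slow")) == 1

    def test_events_recorded_and_slow_velocity_preserved_outside(self, nystagmus_clean):
        eye, head, seg, truth = nystagmus_clean
        assert seg.n_quick == truth.quick_durations_s.size > 0
        # outside quick intervals the first-difference velocity equals the
        # underlying slow-phase velocity (constant offset cannot change it)
        slow = -0.05 * np.interp(eye.t, head.t, head.angle_deg)
        v_slow = np.diff(slow)
        v_out = np.diff(eye.angle_deg)
        quick_mask = np.zeros(eye.t.size - 1, dtype=bool)
        for p in seg.of_kind("quick"):
            quick_mask |= (eye.t[:-1] >= p.start_s - 1e-9) & (eye.t[:-1] < p.end_s - 1e-9)
        assert np.allclose(v_out[~quick_mask], v_slow[~quick_mask], atol=1e-9)

    def test_event_jitter_respects_truncation_bounds(self, nystagmus_clean):
        _, _, _, truth = nystagmus_clean
        d, a = truth.quick_durations_s, truth.quick_amplitudes_deg
        assert np.all(a >= 0.5 * QUICK_AMPLITUDE_DEG) and np.all(a <= 1.5 * QUICK_AMPLITUDE_DEG)
        # durations are snapped to the 100-Hz grid within the bounds
        assert np.all(d >= 0.01) and np.all(d <= 0.04)

    def test_too_small_orbit_rejected(self, nystagmus_clean):
        eye, head, _, _ = nystagmus_clean
        with pytest.raises(InvalidParameterError):
            insert_nystagmus(eye, GroundTruth(), orbit_limit_deg=0.5)


class TestTrackerTable:
    def _recover(self, table, cal, plane="roll"):
        from gazestab.kinematics import subtract_body_motion, trajectory_to_trace

        traj, _ = eye_trajectory(table)
        body = 0.5 * (table.xy("body_1") + table.xy("body_2"))
        return trajectory_to_trace(subtract_body_motion(traj, body), cal, plane=plane)

    def test_exact_round_trip_without_noise(self, roll_fixture_clean):
        eye, _, _ = roll_fixture_clean
        cal = Calibration(frame_rate=eye.sample_rate)
        table = make_tracker_table(eye, cal, jitter_px=0.0, breathing_amp_px=0.0)
        rec = self._recover(table, cal)
        assert np.max(np.abs(rec.angle_deg - eye.angle_deg)) < 1e-9

    def test_breathing_artifact_cancelled_by_body_subtraction(self, roll_fixture_clean):
        eye, _, _ = roll_fixture_clean
        cal = Calibration(frame_rate=eye.sample_rate)
        table = make_tracker_table(eye, cal, jitter_px=0.0, breathing_amp_px=3.0)
        rec = self._recover(table, cal)
        assert np.max(np.abs(rec.angle_deg - eye.angle_deg)) < 1e-6

    def test_label_averaging_halves_jitter_sd(self):
        from gazestab.core import AngularTrace

        n = 1000
        flat = AngularTrace(np.arange(n) / 100.0, np.zeros(n))
        cal = Calibration(frame_rate=100.0)
        table = make_tracker_table(flat, cal, jitter_px=1.0, breathing_amp_px=0.0, seed=3)
        mean_x, _ = eye_trajectory(table)
        single_sd = np.std(table.xy("eye_1")[:, 0])
        mean_sd = np.std(mean_x[:, 0])
        assert mean_sd == pytest.approx(single_sd / 2.0, rel=0.10)

    def test_likelihoods_in_declared_range(self, roll_fixture_clean):
        eye, _, _ = roll_fixture_clean
        table = make_tracker_table(eye, seed=0)
        for lbl in table.eye_labels + table.body_labels:
            lik = table.likelihood(lbl)
            assert np.all((lik >= 0.9) & (lik <= 1.0))


class TestEmgTrial:
    def test_zero_rates_give_pure_noise(self):
        trial, truth = make_emg_trial(
            StimulusProtocol(Modality.VES, Plane.ROLL, 22.7, 48.7),
            drive_gain=0.0, baseline_rate=0.0, seed=0,
        )
        assert truth.spike_times.size == 0
        assert np.max(np.abs(trial.v)) < 5e-4  # noise only, well below spike peak

    def test_same_seed_visves_contains_at_least_ves_spikes(self):
        for seed in range(5):
            counts = {}
            for m in (Modality.VES, Modality.VISVES):
                _, truth = make_emg_trial(
                    StimulusProtocol(m, Plane.ROLL, 5.8, 112.94), seed=seed
                )
                counts[m] = truth.spike_times.size
            assert counts[Modality.VISVES] >= counts[Modality.VES]

    def test_truth_spike_train_respects_refractory(self, emg_pair):
        (_, truth), _ = emg_pair
        assert np.all(np.diff(truth.spike_times) >= 0.002 - 1e-12)

    def test_default_snr_at_least_five(self, emg_pair):
        (trial, truth), _ = emg_pair
        pre = trial.v[trial.epoch_slice("pre_stimulus")]
        sigma = np.std(pre)
        assert 5e-4 / sigma >= 5.0

    def test_negative_rates_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_emg_trial(StimulusProtocol(), drive_gain=-1.0)


class TestPspTrain:
    def test_single_pulse_peak_equals_amplitude(self):
        train, truth = make_psp_train(
            n_pulses=1, amplitudes_mv=1.3, noise_mv=0.0, seed=0
        )
        assert np.max(train.v) - train.resting_potential == pytest.approx(1.3, abs=1e-12)

    def test_superposed_second_peak_matches_closed_form(self, psp_clean):
        train, _ = psp_clean
        # amplitude 1.0, tau 0.05 s, ISI 0.1 s: peak 2 = 1 + exp(-2)
        t2 = train.pulse_times[1]
        i2 = np.searchsorted(train.t, t2)
        peak2 = train.v[i2] - train.resting_potential
        assert peak2 == pytest.approx(1.0 + np.exp(-2.0), abs=1e-6)

    def test_stored_amplitudes_are_increments_not_peaks(self, psp_clean):
        _, truth = psp_clean
        assert np.allclose(truth.epsp_amplitudes_mv, 1.0)


class TestSwimCoupling:
    def test_noise_free_identities(self):
        sc = make_swim_coupling(noise=0.0, lag_frames=0, seed=0)
        assert lagged_pearson(sc.left_eye, sc.right_eye, 0).statistic == pytest.approx(1.0)
        assert lagged_pearson(sc.tail, sc.left_eye, 0).statistic == pytest.approx(-1.0)

    def test_lag_shift_identity(self):
        sc = make_swim_coupling(noise=0.0, lag_frames=7, seed=0)
        at_lag = lagged_pearson(sc.tail, sc.left_eye, 7).statistic
        at_zero = lagged_pearson(sc.tail, sc.left_eye, 0).statistic
        assert abs(at_lag) == pytest.approx(1.0, abs=1e-6)
        assert abs(at_zero) < 1.0 - 1e-3

    def test_lag_precondition(self):
        with pytest.raises(InvalidParameterError):
            make_swim_coupling(n_frames=50, lag_frames=10)
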