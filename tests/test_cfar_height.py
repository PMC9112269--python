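"""CA-CFAR threshold calibration and ceiling-sensor height estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import uwbanthro as u
from uwbanthro.cfar_height import (NO_DETECTION, CalibrationBuffer,
                                   CalibrationError, EstimationError,
                                   calibrate_threshold, detect_first_crossing,
                                   estimate_height, evaluate_height_cohort,
                                   range_resolution)
from uwbanthro.signal_sim import ConfigurationError, SessionRecording


class TestRangeResolution:
    def test_matches_published_hardware_value(self):
        res = range_resolution(23.328e9)
        assert round(res * 1000, 1) == 6.4  # mm

    def test_unit_case(self):
        assert range_resolution(299792458.0 / 2.0) == pytest.approx(1.0)

    def test_inverse_proportionality(self):
        assert range_resolution(2e9) == pytest.approx(2 * range_resolution(4e9))

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            range_resolution(0.0)


class TestCalibrateThreshold:
    def test_identical_frames_give_zero_sigma(self):
        buf = CalibrationBuffer(H=np.tile(np.abs(np.arange(5.0)), (4, 1)))
        prof = calibrate_threshold(buf, beta=7.0)
        assert np.allclose(prof.sigma, 0.0)
        assert np.allclose(prof.T, prof.mu)

    def test_beta_zero_returns_mean(self):
        rng = np.random.default_rng(0)
        buf = CalibrationBuffer(H=rng.random((6, 10)))
        prof = calibrate_threshold(buf, beta=0.0)
        assert np.allclose(prof.T, buf.H.mean(axis=0))

    def test_hand_computed_three_frame_threshold(self):
        buf = CalibrationBuffer(H=np.array([[1.0], [2.0], [3.0]]))
        prof = calibrate_threshold(buf, beta=2.0)
        assert prof.T[0] == pytest.approx(2.0 + 2.0 * 1.0)  # mean 2, std(ddof=1)=1

    def test_literal_convention_swaps_roles(self):
        buf = CalibrationBuffer(H=np.array([[1.0], [2.0], [3.0]]))
        prof = calibrate_threshold(buf, beta=2.0, convention="literal")
        assert prof.T[0] == pytest.approx(2.0 * 2.0 + 1.0)

    def test_single_frame_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_threshold(CalibrationBuffer(H=np.ones((1, 4))))


def brute_force_first_crossing(env, T, min_run):
    for k in range(len(env) - min_run + 1):
        if all(env[k + j] > T[k + j] for j in range(min_run)):
            return k
    return NO_DETECTION


class TestDetectFirstCrossing:
    def test_all_below_threshold(self):
        env, T = np.zeros(20), np.ones(20)
        assert detect_first_crossing(env, T) == NO_DETECTION

    def test_single_run_detected_at_start(self):
        env = np.zeros(200)
        env[120:126] = 5.0
        assert detect_first_crossing(env, np.ones(200), min_run=2) == 120

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 4))
    def test_matches_brute_force_oracle(self, seed, min_run):
        rng = np.random.default_rng(seed)
        n = rng.integers(min_run, 40)
        env = rng.random(n)
        T = rng.random(n)
        assert detect_first_crossing(env, T, min_run=min_run) == \
            brute_force_first_crossing(env, T, min_run)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_first_crossing(np.zeros(4), np.zeros(5))


def pulse_recording(pulse, delays, amplitude=1.0, n_bins=400, fps=20.0):
    """Frames containing one echo at the given per-frame delays."""
    k = np.arange(n_bins, dtype=float)
    frames = np.stack([amplitude * pulse.waveform(k - d) for d in delays])
    return SessionRecording(frames=[frames], fps=fps, sensor_ids=("ceiling",))


class TestEstimateHeight:
    def test_height_arithmetic_from_detected_range(self, pulse):
        res = pulse.range_resolution()
        target_bin = 121
        rec = pulse_recording(pulse, [float(target_bin)] * 20)
        prof = u.ThresholdProfile(T=np.full(400, 0.05), mu=np.zeros(400),
                                  sigma=np.zeros(400), beta=3.0)
        est = estimate_height(rec, prof, room_height=2.5,
                              sampling_rate=pulse.sampling_rate)
        assert est.detected_bin == target_bin
        assert est.height == pytest.approx((2.5 - target_bin * res) * 100.0)

    def test_translation_consistency(self, pulse):
        prof = u.ThresholdProfile(T=np.full(400, 0.05), mu=np.zeros(400),
                                  sigma=np.zeros(400), beta=3.0)
        base = estimate_height(pulse_recording(pulse, [130.0] * 10), prof,
                               sampling_rate=pulse.sampling_rate)
        for d in (-7, 3, 25):
            shifted = estimate_height(pulse_recording(pulse, [130.0 + d] * 10),
                                      prof, sampling_rate=pulse.sampling_rate)
            assert shifted.detected_bin - base.detected_bin == d

    def test_simulated_subject_recovered_within_one_bin(self, subject, residuals,
                                                        threshold, pulse):
        est = estimate_height(residuals, threshold, room_height=2.5,
                              sampling_rate=pulse.sampling_rate)
        assert abs(est.height - subject.height) <= 100 * pulse.range_resolution()

    def test_floor_detection_rejected(self, pulse):
        res = pulse.range_resolution()
        floor_bin = int(2.5 / res) + 1  # echo at/beyond floor range
        rec = pulse_recording(pulse, [float(floor_bin)] * 10, n_bins=400)
        prof = u.ThresholdProfile(T=np.full(400, 0.05), mu=np.zeros(400),
                                  sigma=np.zeros(400), beta=3.0)
        with pytest.raises(EstimationError):
            estimate_height(rec, prof, room_height=2.5,
                            sampling_rate=pulse.sampling_rate)

    def test_majority_missing_detections_rejected(self, pulse):
        rec = SessionRecording(frames=[np.zeros((10, 400))], sensor_ids=("c",))
        prof = u.ThresholdProfile(T=np.full(400, 1.0), mu=np.zeros(400),
                                  sigma=np.zeros(400), beta=3.0)
        with pytest.raises(EstimationError):
            estimate_height(rec, prof)

    def test_false_alarm_rate_nonincreasing_in_beta(self, geometry, pulse):
        empty = u.simulate_empty_room(geometry, pulse, duration_s=20.0, seed=3)
        resid = u.subtract_background(empty)
        buf = CalibrationBuffer.from_recording(resid, sensor=0)
        probe = u.preprocess.envelope(
            u.subtract_background(
                u.simulate_empty_room(geometry, pulse, duration_s=5.0, seed=99)
            ).sensor(0))
        rates = []
        for beta in (0.5, 1.0, 2.0, 3.0, 4.0):
            prof = calibrate_threshold(buf, beta=beta)
            rates.append(np.mean(probe > prof.T[None, :]))
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestEvaluateHeightCohort:
    def test_identical_vectors_have_zero_rmse(self):
        report = evaluate_height_cohort([160.0, 170.0], [160.0, 170.0])
        assert report.rmse == 0.0

    def test_hand_computed_rmse(self):
        report = evaluate_height_cohort([160.0, 170.0], [163.0, 174.0])
        assert report.rmse == pytest.approx(np.sqrt((9 + 16) / 2))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_height_cohort([], [])
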