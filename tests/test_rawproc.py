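"""Signal-processing contracts: resampling, calibration, ENMO, epochs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristtime import rawproc
from wristtime.rawproc import (FEATURE_NAMES, CalibrationModel,
                               EmptyRecordingError, RawRecording,
                               UncalibratableError, borrow_calibration,
                               clipped_fraction, enmo, epochize,
                               extract_features, find_stationary,
                               fit_calibration, lowpass, resample)


def uniform_recording(xyz, rate=100.0, t0=0.0, **kw):
    n = len(xyz)
    t = t0 + np.arange(n) / rate
    return RawRecording(t, np.asarray(xyz, dtype=float), nominal_rate=rate, **kw)


class TestResample:
    def test_uniform_input_is_identity(self):
        rec = uniform_recording(np.tile([0.1, 0.2, 0.9], (500, 1)), rate=100.0)
        out = resample(rec, 100.0)
        assert np.array_equal(out.timestamps, rec.timestamps)
        assert np.array_equal(out.xyz, rec.xyz)

    def test_linear_ramp_interpolates_exactly(self):
        t = np.arange(100) / 50.0
        ramp = np.column_stack([t, 2 * t, 1 - t])
        rec = RawRecording(t, ramp, nominal_rate=50.0)
        out = resample(rec, 100.0)
        expect = np.column_stack([out.timestamps, 2 * out.timestamps,
                                  1 - out.timestamps])
        assert np.allclose(out.xyz, expect, atol=1e-12)
        assert out.nominal_rate == 100.0

    def test_long_gap_left_missing(self):
        t = np.concatenate([np.arange(100) / 100.0,
                            10.0 + np.arange(100) / 100.0])
        rec = RawRecording(t, np.ones((200, 3)), nominal_rate=100.0)
        out = resample(rec, 100.0)
        in_gap = (out.timestamps > 0.99) & (out.timestamps < 10.0)
        assert in_gap.sum() > 800
        assert np.isnan(out.xyz[in_gap]).all()
        assert not np.isnan(out.xyz[~in_gap]).any()

    def test_single_sample_rejected(self):
        rec = RawRecording(np.array([0.0]), np.array([[0, 0, 1.0]]))
        with pytest.raises(EmptyRecordingError, match="empty recording"):
            resample(rec)


class TestFindStationary:
    def test_noisy_recording_has_no_windows(self):
        rng = np.random.default_rng(0)
        rec = uniform_recording([0, 0, 1.0] + rng.normal(0, 0.020, (60000, 3)))
        assert len(find_stationary(rec).means) == 0

    def test_quiet_recording_keeps_all_windows(self):
        rng = np.random.default_rng(1)
        rec = uniform_recording([0, 0, 1.0] + rng.normal(0, 0.002, (60000, 3)))
        w = find_stationary(rec)
        assert len(w.means) == 60
        assert np.allclose(w.means, [0, 0, 1.0], atol=1e-3)

    def test_threshold_is_strict(self):
        # alternate +-13 mg about the mean: per-axis SD exactly 13.0 mg
        block = np.tile([0, 0, 1.0], (1000, 1))
        block[::2, 0] += 0.013
        block[1::2, 0] -= 0.013
        rec = uniform_recording(block)
        assert len(find_stationary(rec).means) == 0


def sphere_points(n, rng):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestCalibration:
    def test_unit_sphere_is_fixed_point(self):
        pts = sphere_points(40, np.random.default_rng(0))
        model = fit_calibration(pts)
        assert np.allclose(model.gain, 1.0, atol=1e-9)
        assert np.allclose(model.offset, 0.0, atol=1e-9)
        assert model.residual_error < 1e-6
        assert model.sphere_coverage_ok

    def test_recovers_device_gain_and_offset(self):
        rng = np.random.default_rng(2)
        true_gain = np.array([1.05, 0.97, 1.02])
        true_offset = np.array([0.02, -0.01, 0.005])
        pts = sphere_points(40, rng)
        measured = pts * true_gain + true_offset + rng.normal(0, 0.002, (40, 3))
        model = fit_calibration(measured)
        assert np.abs(model.device_gain - true_gain).max() < 0.01
        assert np.abs(model.device_offset - true_offset).max() * 1000 < 5.0

    def test_single_orientation_is_uncalibratable(self):
        pts = np.tile([0, 0, 1.0], (40, 1)) + np.random.default_rng(3).normal(
            0, 0.002, (40, 3))
        with pytest.raises(UncalibratableError) as err:
            fit_calibration(pts)
        assert err.value.model.sphere_coverage_ok is False

    def test_too_few_windows_rejected(self):
        with pytest.raises(UncalibratableError, match="stationary windows"):
            fit_calibration(sphere_points(5, np.random.default_rng(0)))

    def test_descent_is_monotone(self):
        rng = np.random.default_rng(4)
        pts = sphere_points(60, rng) * [1.04, 0.95, 1.03] + [0.03, -0.02, 0.01]
        pts += rng.normal(0, 0.003, pts.shape)
        residuals = []
        offset, gain = np.zeros(3), np.ones(3)
        for _ in range(30):
            curr = pts * gain + offset
            norms = np.linalg.norm(curr, axis=1)
            residuals.append(np.abs(norms - 1).mean())
            if len(residuals) > 1 and residuals[-2] - residuals[-1] < 1e-9:
                break   # the fitting loop's own convergence rule
            target = curr / norms[:, None]
            for a in range(3):
                X = np.column_stack([np.ones(len(pts)), curr[:, a]])
                b, *_ = np.linalg.lstsq(X, target[:, a], rcond=None)
                offset[a] = b[0] + b[1] * offset[a]
                gain[a] = b[1] * gain[a]
        # every accepted iteration strictly reduces the residual
        assert (np.diff(residuals[:-1]) < 0).all()
        assert residuals[-2] - residuals[-1] < 1e-9

    def test_borrow_matches_device(self):
        donor = CalibrationModel(offset=np.zeros(3), gain=np.ones(3),
                                 source="self", device_id="ax3-7")
        rec = uniform_recording(np.tile([0, 0, 1.0], (10, 1)),
                                device_id="ax3-7")
        out = borrow_calibration(rec, donor)
        assert out.source == "donor"
        other = uniform_recording(np.tile([0, 0, 1.0], (10, 1)),
                                  device_id="ax3-8")
        with pytest.raises(ValueError, match="device mismatch"):
            borrow_calibration(other, donor)
        with pytest.raises(UncalibratableError):
            borrow_calibration(rec, None)


class TestClipping:
    def test_clean_signal_unclipped(self):
        rec = uniform_recording(np.tile([0, 0, 1.0], (100, 1)))
        assert clipped_fraction(rec) == (0.0, 0.0)

    def test_pinned_samples_counted(self):
        xyz = np.tile([0, 0, 1.0], (1000, 1))
        xyz[:20, 0] = 8.0
        rec = uniform_recording(xyz)
        pre, _ = clipped_fraction(rec)
        assert pre == pytest.approx(0.02)

    def test_gain_can_push_readings_past_margin(self):
        xyz = np.tile([0, 0, 1.0], (1000, 1))
        xyz[:50, 0] = 6.7    # inside the margin pre-calibration
        rec = uniform_recording(xyz)
        cal = CalibrationModel(offset=np.zeros(3),
                               gain=np.array([1.2, 1.0, 1.0]))
        pre, post = clipped_fraction(rec, cal)
        assert pre == 0.0 and post > pre


class TestLowpass:
    def test_constant_signal_unchanged(self):
        rec = uniform_recording(np.tile([0.1, -0.2, 0.97], (2000, 1)))
        out = lowpass(rec, 20.0)
        assert np.allclose(out.xyz, rec.xyz, atol=1e-9)
        assert out.n_samples == rec.n_samples

    def test_high_frequency_attenuated_low_preserved(self):
        t = np.arange(20000) / 100.0
        hi = np.sin(2 * np.pi * 40.0 * t)
        lo = np.sin(2 * np.pi * 0.5 * t)
        rec = uniform_recording(np.column_stack([hi, lo, np.ones_like(t)]))
        out = lowpass(rec, 20.0)
        mid = slice(5000, 15000)
        assert np.abs(out.xyz[mid, 0]).max() < 0.1 * np.abs(hi[mid]).max()
        assert np.abs(np.abs(out.xyz[mid, 1]).max() - 1.0) < 0.01

    def test_rate_must_exceed_twice_cutoff(self):
        rec = uniform_recording(np.ones((1000, 3)), rate=25.0)
        with pytest.raises(ValueError, match="twice the cutoff"):
            lowpass(rec, 20.0)


class TestEnmo:
    @pytest.mark.parametrize("vec,expected", [
        ((0, 0, 1.0), 0.0),
        ((0, 0, 1.1), 100.0),
        ((0.3, 0, 0.4), 0.0),          # norm 0.5, truncated
    ])
    def test_exact_values(self, vec, expected):
        assert enmo(np.array(vec)) == pytest.approx(expected, abs=1e-9)

    @given(st.lists(st.floats(-8, 8), min_size=3, max_size=3))
    @settings(deadline=None, derandomize=True)
    def test_never_negative(self, vec):
        assert enmo(np.array(vec)) >= 0.0


class TestEpochize:
    def test_constant_enmo_per_epoch(self):
        rec = uniform_recording(np.tile([0, 0, 1.1], (6000, 1)))
        ep = epochize(rec)
        assert ep.n_epochs == 2
        assert np.allclose(ep.enmo_mean, 100.0, atol=1e-9)
        assert not ep.missing.any()

    def test_sparse_epoch_marked_missing(self):
        t = np.arange(300) / 100.0   # 3 s of data inside a 30-s epoch: 10%
        rec = RawRecording(t, np.tile([0, 0, 1.0], (300, 1)),
                           nominal_rate=100.0)
        ep = epochize(rec)
        assert ep.missing[0]
        assert np.isnan(ep.enmo_mean[0])

    def test_grid_anchored_to_whole_minute(self):
        t = 90.0 + np.arange(12000) / 100.0   # starts mid-minute
        rec = RawRecording(t, np.tile([0, 0, 1.0], (12000, 1)),
                           nominal_rate=100.0)
        ep = epochize(rec)
        assert ep.epoch_start[0] == 60.0
        assert np.all(np.diff(ep.epoch_start) == 30.0)

    def test_time_conservation(self):
        rec = uniform_recording(np.tile([0, 0, 1.0], (18011, 1)))
        ep = epochize(rec)
        assert ep.n_samples.sum() == rec.n_samples


class TestFeatures:
    def test_constant_epoch_degenerate_conventions(self):
        f = extract_features(np.tile([0, 0, 1.0], (750, 1)), rate=25.0)
        names = dict(zip(FEATURE_NAMES, f))
        for k in ("enmo_mean", "enmo_sd", "enmo_max", "corr_xy", "corr_xz",
                  "corr_yz", "enmo_skew", "enmo_kurt", "dom_freq"):
            assert names[k] == 0.0, k
        assert names["z_mean"] == 1.0

    def test_sinusoidal_enmo_dominant_frequency(self):
        t = np.arange(3000) / 100.0
        z = 1.05 + 0.02 * np.sin(2 * np.pi * 1.0 * t)   # ENMO oscillates at 1 Hz
        f = extract_features(np.column_stack([np.zeros_like(t),
                                              np.zeros_like(t), z]), rate=100.0)
        names = dict(zip(FEATURE_NAMES, f))
        assert names["dom_freq"] == pytest.approx(1.0, abs=0.05)
        assert names["band_power"] > 0.5 * names["total_power"]

    def test_feature_vector_length_contract(self):
        rng = np.random.default_rng(0)
        f = extract_features(rng.normal(0, 0.1, (750, 3)) + [0, 0, 1.0],
                             rate=25.0)
        assert len(f) == 26 == len(FEATURE_NAMES)
        assert np.isfinite(f).all()

    def test_sparse_epoch_yields_missing_markers(self):
        x = np.full((750, 3), np.nan)
        x[:10] = [0, 0, 1.0]
        f = extract_features(x, rate=25.0)
        assert np.isnan(f).all()
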