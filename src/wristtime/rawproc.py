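"""Raw-signal processing: resampling, autocalibration, ENMO and 30-s epochs.

The chain mirrors the established wrist-accelerometry processing scheme:
(1) resample the triaxial signal to a uniform grid; (2) autocalibrate
per-axis gain/offset against the unit gravity sphere using stationary
periods, borrowing parameters from another use of the same device when
stationary data are insufficient; (3) low-pass filter to remove sensor
noise; (4) compute the Euclidean Norm Minus One (ENMO) intensity metric
with negative values truncated to zero; (5) aggregate into half-open 30-s
epochs carrying ENMO, per-axis statistics and a 26-element feature vector
for behaviour classification.  Clipping (readings pinned near the rated
dynamic range) is quantified before and after calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt


class EmptyRecordingError(ValueError):
    pass


class UncalibratableError(ValueError):
    """Calibration failed; carries the partial model in ``.model``."""

    def __init__(self, message, model=None):
        super().__init__(message)
        self.model = model


@dataclass
class RawRecording:
    """Timestamped triaxial samples in gravitational units.

    ``timestamps`` are UTC seconds, strictly increasing.  After resampling,
    gaps longer than the permitted maximum appear as NaN rows on the uniform
    grid rather than being interpolated.
    """

    timestamps: np.ndarray
    xyz: np.ndarray
    temp: np.ndarray | None = None
    nominal_rate: float = 100.0
    dynamic_range: float = 8.0
    device_id: str = "dev-0"

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if len(self.timestamps) != len(self.xyz):
            raise ValueError("timestamps and xyz length mismatch")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be > 0")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def span(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.nominal_rate


@dataclass
class CalibrationModel:
    """Affine correction mapping measured onto true acceleration.

    Stored in "apply" convention: ``calibrated = gain * measured + offset``
    (plus an optional temperature term).  For a device that distorted the
    truth as ``measured = g_d * true + o_d`` the equivalent device-space
    parameters are exposed as :attr:`device_gain` = ``1/gain`` and
    :attr:`device_offset` = ``-offset/gain``.
    """

    offset: np.ndarray
    gain: np.ndarray
    temp_coeff: np.ndarray | None = None
    residual_error: float = np.nan     # mean | |v|-1 | of stationary points, mg
    n_stationary: int = 0
    sphere_coverage_ok: bool = False
    source: str = "self"               # {"self", "donor"}
    device_id: str = "dev-0"

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)

    @property
    def device_gain(self) -> np.ndarray:
        return 1.0 / self.gain

    @property
    def device_offset(self) -> np.ndarray:
        return -self.offset / self.gain

    def apply(self, recording: RawRecording) -> RawRecording:
        xyz = recording.xyz * self.gain + self.offset
        if self.temp_coeff is not None and recording.temp is not None:
            xyz = xyz + np.outer(recording.temp - 20.0, self.temp_coeff)
        return replace(recording, xyz=xyz)


@dataclass
class EpochSeries:
    """Half-open 30-s epochs: ENMO, per-axis statistics and features."""

    epoch_start: np.ndarray       # (n,) seconds, uniform 30-s grid
    enmo_mean: np.ndarray         # (n,) mg
    axis_mean: np.ndarray         # (n, 3) g
    axis_sd: np.ndarray           # (n, 3) mg
    n_samples: np.ndarray         # (n,) valid samples per epoch
    features: np.ndarray | None   # (n, 26) or None
    epoch_s: float = 30.0
    rate: float = 100.0

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_start)

    @property
    def expected_samples(self) -> float:
        return self.rate * self.epoch_s

    @property
    def missing(self) -> np.ndarray:
        """Epochs with fewer than half the expected samples."""
        return self.n_samples < 0.5 * self.expected_samples


@dataclass
class StationaryWindows:
    means: np.ndarray              # (k, 3) g
    temps: np.ndarray | None       # (k,) degC
    start: np.ndarray              # (k,) seconds


def resample(recording: RawRecording, target_rate: float = 100.0,
             max_gap_s: float = 1.0) -> RawRecording:
    """Linear interpolation onto a uniform grid at ``target_rate``.

    Grid points falling strictly inside an input gap longer than
    ``max_gap_s`` become NaN (explicit missing spans, never interpolated).
    """
    if recording.n_samples < 2:
        raise EmptyRecordingError("empty recording: need at least 2 samples")
    t = recording.timestamps
    n_out = int(np.floor((t[-1] - t[0]) * target_rate)) + 1
    grid = t[0] + np.arange(n_out) / target_rate
    xyz = np.column_stack([np.interp(grid, t, recording.xyz[:, a])
                           for a in range(3)])
    temp = np.interp(grid, t, recording.temp) if recording.temp is not None else None
    # mask gap interiors
    right = np.searchsorted(t, grid, side="right")
    right = np.clip(right, 1, len(t) - 1)
    gap = t[right] - t[right - 1]
    on_node = np.isin(grid, t, assume_unique=False)
    inside_gap = (gap > max_gap_s) & ~on_node
    if inside_gap.any():
        xyz[inside_gap] = np.nan
        if temp is not None:
            temp[inside_gap] = np.nan
    return replace(recording, timestamps=grid, xyz=xyz, temp=temp,
                   nominal_rate=target_rate)


def find_stationary(recording: RawRecording, window_s: float = 10.0,
                    sd_threshold_mg: float = 13.0) -> StationaryWindows:
    """Non-overlapping windows whose per-axis SD is strictly below threshold.

    Windows containing missing samples are skipped.  Each retained window is
    summarised by its mean 3-vector (and mean temperature when present) —
    the inputs to sphere autocalibration.
    """
    rate = recording.nominal_rate
    w = int(round(window_s * rate))
    n_win = recording.n_samples // w
    if n_win == 0:
        return StationaryWindows(np.empty((0, 3)), None, np.empty(0))
    x = recording.xyz[: n_win * w].reshape(n_win, w, 3)
    valid = ~np.isnan(x).any(axis=(1, 2))
    sd = np.zeros((n_win, 3))
    mean = np.zeros((n_win, 3))
    mean[valid] = x[valid].mean(axis=1)
    sd[valid] = x[valid].std(axis=1)
    keep = valid & (sd * 1000.0 < sd_threshold_mg).all(axis=1)
    temps = None
    if recording.temp is not None:
        tw = recording.temp[: n_win * w].reshape(n_win, w)
        temps = np.nanmean(tw[keep], axis=1) if keep.any() else np.empty(0)
    starts = recording.timestamps[np.arange(n_win) * w][keep]
    return StationaryWindows(mean[keep], temps, starts)


def fit_calibration(stationary_means: np.ndarray,
                    temps: np.ndarray | None = None,
                    min_windows: int = 10,
                    coverage_g: float = 0.3,
                    max_residual_mg: float = 10.0,
                    tol_g: float = 1e-9,
                    max_iter: int = 1000,
                    device_id: str = "dev-0") -> CalibrationModel:
    """Iterated closed-form sphere calibration.

    Each iteration projects the current calibrated stationary means onto the
    unit sphere and refits, per axis, an affine map (offset + gain, with an
    optional linear temperature term) by least squares toward those targets;
    iteration stops when the residual improves by less than ``tol_g`` (in g)
    or after ``max_iter`` rounds.  Success requires at least ``min_windows``
    stationary windows, sphere coverage (stationary means below
    ``-coverage_g`` and above ``+coverage_g`` on every axis) and a final
    residual below ``max_residual_mg``; otherwise the recording is
    uncalibratable and the caller may retry with donor parameters.
    """
    pts = np.asarray(stationary_means, dtype=float)
    n = len(pts)
    coverage = bool(n > 0 and
                    np.all(pts.min(axis=0) < -coverage_g) and
                    np.all(pts.max(axis=0) > coverage_g))
    failed = CalibrationModel(offset=np.zeros(3), gain=np.ones(3),
                              n_stationary=n, sphere_coverage_ok=coverage,
                              device_id=device_id)
    if n < min_windows:
        raise UncalibratableError(
            f"uncalibratable: only {n} stationary windows (< {min_windows})",
            model=failed)
    if not coverage:
        raise UncalibratableError(
            "uncalibratable: stationary means do not cover the sphere "
            f"(need < -{coverage_g:g} g and > +{coverage_g:g} g on every axis)",
            model=failed)

    use_temp = temps is not None and len(np.unique(temps)) > 1
    tc = np.asarray(temps, dtype=float) - 20.0 if use_temp else None
    offset = np.zeros(3)
    gain = np.ones(3)
    temp_coeff = np.zeros(3) if use_temp else None
    prev = np.inf
    residual = np.inf
    for _ in range(max_iter):
        curr = pts * gain + offset
        if use_temp:
            curr = curr + np.outer(tc, temp_coeff)
        norms = np.linalg.norm(curr, axis=1)
        residual = float(np.mean(np.abs(norms - 1.0)))
        if prev - residual < tol_g:
            break
        prev = residual
        target = curr / norms[:, None]
        for a in range(3):
            cols = [np.ones(n), curr[:, a]]
            if use_temp:
                cols.append(tc)
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, target[:, a], rcond=None)
            # compose the affine update with the running correction
            offset[a] = beta[0] + beta[1] * offset[a]
            gain[a] = beta[1] * gain[a]
            if use_temp:
                temp_coeff[a] = beta[1] * temp_coeff[a] + beta[2]

    residual_mg = residual * 1000.0
    model = CalibrationModel(offset=offset, gain=gain, temp_coeff=temp_coeff,
                             residual_error=residual_mg, n_stationary=n,
                             sphere_coverage_ok=coverage, source="self",
                             device_id=device_id)
    if residual_mg >= max_residual_mg:
        raise UncalibratableError(
            f"uncalibratable: residual {residual_mg:.2f} mg >= {max_residual_mg} mg",
            model=model)
    return model


def borrow_calibration(recording: RawRecording,
                       donor: CalibrationModel | None) -> CalibrationModel:
    """Reuse calibration from the previous/next use of the same device."""
    if donor is None:
        raise UncalibratableError(
            "uncalibratable: no donor calibration available")
    if donor.source != "self":
        raise UncalibratableError(
            "uncalibratable: donor calibration is itself borrowed")
    if donor.device_id != recording.device_id:
        raise ValueError(
            f"device mismatch: donor from {donor.device_id!r}, "
            f"recording from {recording.device_id!r}")
    return replace(donor, source="donor")


def clipped_fraction(recording: RawRecording,
                     calibration: CalibrationModel | None = None,
                     margin_g: float = 0.1) -> tuple[float, float]:
    """Fraction of readings pinned near the rated range, pre/post calibration.

    A reading is clipped when any axis magnitude is at or beyond
    ``dynamic_range - margin_g`` (saturated sensors read slightly inside the
    rated limit).
    """
    limit = recording.dynamic_range - margin_g
    valid = ~np.isnan(recording.xyz).any(axis=1)
    n = int(valid.sum())
    if n == 0:
        return 0.0, 0.0
    pre = float((np.abs(recording.xyz[valid]) >= limit).any(axis=1).sum()) / n
    if calibration is None:
        return pre, pre
    cal = calibration.apply(recording)
    post = float((np.abs(cal.xyz[valid]) >= limit).any(axis=1).sum()) / n
    return pre, post


def lowpass(recording: RawRecording, cutoff_hz: float = 20.0) -> RawRecording:
    """Zero-phase 4th-order Butterworth low-pass to remove sensor noise.

    Applied independently to each contiguous non-missing run; runs too short
    for the filter's edge padding pass through unchanged.
    """
    rate = recording.nominal_rate
    if rate <= 2 * cutoff_hz:
        raise ValueError(
            f"sample rate {rate} Hz must exceed twice the cutoff {cutoff_hz} Hz")
    sos = butter(4, cutoff_hz, btype="lowpass", fs=rate, output="sos")
    padlen = 6 * (sos.shape[0] + 1)
    xyz = recording.xyz.copy()
    valid = ~np.isnan(xyz).any(axis=1)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], valid.view(np.int8), [0]))))
    for i0, i1 in edges.reshape(-1, 2):
        if i1 - i0 > padlen:
            xyz[i0:i1] = sosfiltfilt(sos, xyz[i0:i1], axis=0)
    return replace(recording, xyz=xyz)


def enmo(xyz: np.ndarray) -> np.ndarray:
    """Euclidean Norm Minus One in mg, negatives truncated to zero."""
    xyz = np.asarray(xyz, dtype=float)
    norm = np.linalg.norm(xyz, axis=-1)
    return np.maximum(norm - 1.0, 0.0) * 1000.0


#: deterministic order of the 26 epoch features
FEATURE_NAMES = (
    "enmo_mean", "enmo_sd", "enmo_max", "enmo_median", "enmo_p25", "enmo_p75",
    "x_mean", "y_mean", "z_mean", "x_sd", "y_sd", "z_sd",
    "corr_xy", "corr_xz", "corr_yz",
    "enmo_mad", "enmo_skew", "enmo_kurt",
    "roll_mean", "roll_sd", "pitch_mean", "pitch_sd",
    "dom_freq", "dom_power", "total_power", "band_power",
)


def _features_block(x: np.ndarray, rate: float) -> np.ndarray:
    """Vectorised 26-feature extraction for an (n_epochs, spe, 3) block.

    Correlations, skewness and kurtosis are defined as 0 under zero
    variance.  Spectral features are computed on the mean-removed per-sample
    ENMO trace of each epoch; band power covers 0.3-3 Hz, the human-movement
    band.
    """
    n_ep, spe, _ = x.shape
    e = enmo(x)                                      # (n_ep, spe) mg
    e_mean = e.mean(axis=1)
    e_sd = e.std(axis=1)
    e_max = e.max(axis=1)
    e_med = np.median(e, axis=1)
    e_p25 = np.percentile(e, 25, axis=1)
    e_p75 = np.percentile(e, 75, axis=1)

    ax_mean = x.mean(axis=1)                         # (n_ep, 3)
    ax_sd = x.std(axis=1)

    xc = x - ax_mean[:, None, :]
    cov = np.einsum("nij,nik->njk", xc, xc) / spe
    sd_safe = np.where(ax_sd > 0, ax_sd, 1.0)
    denom = sd_safe[:, :, None] * sd_safe[:, None, :]
    corr = cov / denom
    zero_var = (ax_sd == 0)
    for i, j in ((0, 1), (0, 2), (1, 2)):
        corr[zero_var[:, i] | zero_var[:, j], i, j] = 0.0
    corr_xy, corr_xz, corr_yz = corr[:, 0, 1], corr[:, 0, 2], corr[:, 1, 2]

    ec = e - e_mean[:, None]
    mad = np.abs(ec).mean(axis=1)
    sd_e = np.where(e_sd > 0, e_sd, 1.0)
    skew = np.where(e_sd > 0, (ec ** 3).mean(axis=1) / sd_e ** 3, 0.0)
    kurt = np.where(e_sd > 0, (ec ** 4).mean(axis=1) / sd_e ** 4 - 3.0, 0.0)

    roll = np.arctan2(x[:, :, 1], x[:, :, 2])
    pitch = np.arctan2(-x[:, :, 0], np.hypot(x[:, :, 1], x[:, :, 2]))
    roll_mean, roll_sd = roll.mean(axis=1), roll.std(axis=1)
    pitch_mean, pitch_sd = pitch.mean(axis=1), pitch.std(axis=1)

    pxx = np.abs(np.fft.rfft(ec, axis=1)) ** 2 / spe
    freqs = np.fft.rfftfreq(spe, d=1.0 / rate)
    pxx = pxx[:, 1:]                               # drop DC (mean removed)
    freqs = freqs[1:]
    if pxx.shape[1] == 0:
        dom_freq = dom_power = total_power = band_power = np.zeros(n_ep)
    else:
        k = pxx.argmax(axis=1)
        dom_freq = freqs[k]
        dom_power = pxx[np.arange(n_ep), k]
        total_power = pxx.sum(axis=1)
        band = (freqs >= 0.3) & (freqs <= 3.0)
        band_power = pxx[:, band].sum(axis=1)
        quiet = e_sd == 0
        dom_freq = np.where(quiet, 0.0, dom_freq)

    return np.column_stack([
        e_mean, e_sd, e_max, e_med, e_p25, e_p75,
        ax_mean[:, 0], ax_mean[:, 1], ax_mean[:, 2],
        ax_sd[:, 0] * 1000.0, ax_sd[:, 1] * 1000.0, ax_sd[:, 2] * 1000.0,
        corr_xy, corr_xz, corr_yz,
        mad, skew, kurt,
        roll_mean, roll_sd, pitch_mean, pitch_sd,
        dom_freq, dom_power, total_power, band_power,
    ])


def extract_features(epoch_xyz: np.ndarray, rate: float = 100.0) -> np.ndarray:
    """26-element feature vector for one epoch of calibrated samples.

    An epoch with fewer than half its expected samples present (NaN rows)
    yields a vector of NaN missing markers.
    """
    epoch_xyz = np.asarray(epoch_xyz, dtype=float)
    valid = ~np.isnan(epoch_xyz).any(axis=1)
    if valid.sum() < 0.5 * len(epoch_xyz):
        return np.full(len(FEATURE_NAMES), np.nan)
    return _features_block(epoch_xyz[valid][None, :, :], rate)[0]


def epochize(recording: RawRecording, epoch_s: float = 30.0,
             features: bool = True) -> EpochSeries:
    """Aggregate a uniform-grid recording into half-open 30-s epochs.

    The grid is anchored at the first sample's timestamp floored to the
    whole minute, aligning epochs with the minute-of-day imputation grid.
    Epochs with fewer than 50% of expected samples are marked missing
    (NaN statistics and features).
    """
    if recording.n_samples == 0:
        return EpochSeries(np.empty(0), np.empty(0), np.empty((0, 3)),
                           np.empty((0, 3)), np.empty(0, dtype=int),
                           np.empty((0, len(FEATURE_NAMES))) if features else None,
                           epoch_s, recording.nominal_rate)
    rate = recording.nominal_rate
    spe = int(round(epoch_s * rate))
    t0 = np.floor(recording.timestamps[0] / 60.0) * 60.0
    end = recording.timestamps[-1] + 1.0 / rate
    n_ep = int(np.ceil((end - t0) / epoch_s))
    starts = t0 + np.arange(n_ep) * epoch_s

    # place samples into a dense (n_ep, spe, 3) block padded with NaN
    block = np.full((n_ep * spe, 3), np.nan)
    pos = np.round((recording.timestamps - t0) * rate).astype(np.int64)
    inside = (pos >= 0) & (pos < n_ep * spe)
    block[pos[inside]] = recording.xyz[inside]
    block = block.reshape(n_ep, spe, 3)

    valid = ~np.isnan(block).any(axis=2)
    n_samples = valid.sum(axis=1)
    ok = n_samples >= 0.5 * spe

    enmo_mean = np.full(n_ep, np.nan)
    axis_mean = np.full((n_ep, 3), np.nan)
    axis_sd = np.full((n_ep, 3), np.nan)
    feats = np.full((n_ep, len(FEATURE_NAMES)), np.nan) if features else None

    if ok.any():
        full = valid.all(axis=1) & ok
        # fast path: complete epochs handled as one vectorised block
        if full.any():
            sub = block[full]
            enmo_mean[full] = enmo(sub).mean(axis=1)
            axis_mean[full] = sub.mean(axis=1)
            axis_sd[full] = sub.std(axis=1) * 1000.0
            if features:
                feats[full] = _features_block(sub, rate)
        for i in np.flatnonzero(ok & ~full):
            sub = block[i][valid[i]]
            enmo_mean[i] = enmo(sub).mean()
            axis_mean[i] = sub.mean(axis=0)
            axis_sd[i] = sub.std(axis=0) * 1000.0
            if features:
                feats[i] = _features_block(sub[None], rate)[0]

    return EpochSeries(epoch_start=starts, enmo_mean=enmo_mean,
                       axis_mean=axis_mean, axis_sd=axis_sd,
                       n_samples=n_samples, features=feats,
                       epoch_s=epoch_s, rate=rate)
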