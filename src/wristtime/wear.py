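"""Non-wear detection, eligibility screening and minute-of-day imputation.

Non-wear is an unbroken episode of at least 60 minutes during which the
standard deviation of every axis is below 13.0 mg; it is evaluated on a
1-minute aggregation of the 30-s epoch statistics.  A recording is eligible
for behaviour analysis when it calibrated, has at most 1% clipped readings
before and after calibration, accumulates at least 72 h of wear, covers
every hour of the 24-h cycle somewhere in the recording, and its imputed
mean acceleration lies in the plausible 1.5-100 mg range.  Interruptions
and non-wear time are imputed from the average of the corresponding minute
of the day over the remaining worn days, which removes diurnal wear bias
from the 24-h summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rawproc import CalibrationModel, EpochSeries
from .synth import BEHAVIOURS

WORN, NONWEAR, MISSING = 0, 1, 2
_MINUTES_PER_DAY = 1440


class IneligibleRecordingError(ValueError):
    pass


@dataclass
class WearMask:
    """Per-epoch flag in {worn, nonwear, missing}, on the epoch grid."""

    flags: np.ndarray            # (n_epochs,) int8 codes

    @property
    def worn(self) -> np.ndarray:
        return self.flags == WORN

    @property
    def nonwear(self) -> np.ndarray:
        return self.flags == NONWEAR

    @property
    def missing(self) -> np.ndarray:
        return self.flags == MISSING


@dataclass
class QualityReport:
    calibrated: bool
    clipped_ok: bool
    wear_hours: float
    hour_coverage: np.ndarray      # (24,) bool
    mean_accel: float              # mg, imputed overall mean
    eligible: bool
    failure_reasons: list[str] = field(default_factory=list)


@dataclass
class MinuteProfile:
    """1440 minute-of-day slots of imputed ENMO and behaviour fractions."""

    enmo: np.ndarray               # (1440,) mg
    fractions: np.ndarray          # (1440, 4) sleep/sedentary/LIPA/MVPA
    n_days_observed: np.ndarray    # (1440,) int

    @property
    def complete(self) -> bool:
        return not np.isnan(self.enmo).any()


def _minute_stats(epochs: EpochSeries, wear_flags: np.ndarray | None = None):
    """Pool epoch statistics into whole minutes of the recording.

    Returns (minute_index_from_grid_start, per-axis SD in mg, minute state).
    The pooled SD combines each epoch's within-epoch variance with the
    spread of epoch means, i.e. it is the SD over the raw samples of the
    minute.  Minutes with no valid epoch are missing.
    """
    per_min = int(round(60.0 / epochs.epoch_s))
    n_min = int(np.ceil(epochs.n_epochs / per_min))
    pad = n_min * per_min - epochs.n_epochs

    def padded(a, fill=np.nan):
        if pad == 0:
            return a
        shape = (pad,) + a.shape[1:]
        return np.concatenate([a, np.full(shape, fill, dtype=float)])

    n = padded(epochs.n_samples.astype(float), 0.0).reshape(n_min, per_min)
    mean = padded(epochs.axis_mean).reshape(n_min, per_min, 3)
    sd = padded(epochs.axis_sd).reshape(n_min, per_min, 3) / 1000.0  # g
    valid = ~np.isnan(mean).any(axis=2) & (n > 0)

    w = np.where(valid, n, 0.0)
    tot = w.sum(axis=1)
    has = tot > 0
    w3 = w[:, :, None]
    m = np.where(valid[:, :, None], mean, 0.0)
    s = np.where(valid[:, :, None], sd, 0.0)
    pooled_mean = np.full((n_min, 3), np.nan)
    pooled_sd = np.full((n_min, 3), np.nan)
    with np.errstate(invalid="ignore"):
        pm = (w3 * m).sum(axis=1) / tot[:, None]
        second = (w3 * (s ** 2 + m ** 2)).sum(axis=1) / tot[:, None]
        pv = np.maximum(second - pm ** 2, 0.0)
    pooled_mean[has] = pm[has]
    pooled_sd[has] = np.sqrt(pv[has])
    return n_min, per_min, pooled_sd * 1000.0, has


def detect_nonwear(epochs: EpochSeries, sd_threshold_mg: float = 13.0,
                   min_minutes: int = 60) -> WearMask:
    """Flag maximal runs of >= 60 consecutive quiet minutes as non-wear.

    A minute is quiet when all three pooled axis SDs are strictly below the
    threshold.  Missing minutes break runs; shorter stationary runs remain
    worn.
    """
    n_min, per_min, minute_sd, observed = _minute_stats(epochs)
    quiet = observed & np.all(minute_sd < sd_threshold_mg, axis=1)

    minute_state = np.full(n_min, WORN, dtype=np.int8)
    minute_state[~observed] = MISSING
    q = np.concatenate(([0], quiet.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(q)).reshape(-1, 2)
    for i0, i1 in edges:
        if i1 - i0 >= min_minutes:
            minute_state[i0:i1] = NONWEAR

    flags = np.repeat(minute_state, per_min)[: epochs.n_epochs].copy()
    flags[epochs.missing] = MISSING
    return WearMask(flags)


def _minute_of_day(epochs: EpochSeries) -> np.ndarray:
    return ((epochs.epoch_start // 60).astype(np.int64)) % _MINUTES_PER_DAY


def _impute_profile(epochs: EpochSeries, mask: WearMask,
                    behaviours: np.ndarray | None) -> MinuteProfile:
    mod = _minute_of_day(epochs)
    worn = mask.worn & ~np.isnan(epochs.enmo_mean)

    enmo_sum = np.zeros(_MINUTES_PER_DAY)
    enmo_n = np.zeros(_MINUTES_PER_DAY)
    np.add.at(enmo_sum, mod[worn], epochs.enmo_mean[worn])
    np.add.at(enmo_n, mod[worn], 1.0)

    frac_sum = np.zeros((_MINUTES_PER_DAY, len(BEHAVIOURS)))
    frac_n = np.zeros(_MINUTES_PER_DAY)
    if behaviours is not None:
        behaviours = np.asarray(behaviours)
        for k, b in enumerate(BEHAVIOURS):
            sel = worn & (behaviours == b)
            np.add.at(frac_sum[:, k], mod[sel], 1.0)
        labelled = worn & np.isin(behaviours, BEHAVIOURS)
        np.add.at(frac_n, mod[labelled], 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        slot_enmo = enmo_sum / enmo_n
        slot_frac = frac_sum / frac_n[:, None]

    # days observed per slot: worn occurrences / at most one per day handled
    # by counting distinct days
    days = (epochs.epoch_start[worn] // 86400).astype(np.int64)
    n_days = np.zeros(_MINUTES_PER_DAY, dtype=int)
    for m in np.unique(mod[worn]):
        n_days[m] = len(np.unique(days[mod[worn] == m]))

    # hour-of-day fallback for slots observed on zero days
    hours = np.arange(_MINUTES_PER_DAY) // 60
    for h in range(24):
        sel = hours == h
        have = sel & (enmo_n > 0)
        need = sel & (enmo_n == 0)
        if need.any():
            if not have.any():
                raise IneligibleRecordingError(
                    f"hour {h:02d} of the 24-h cycle has no worn data; "
                    "recording fails hour coverage and cannot be imputed")
            slot_enmo[need] = slot_enmo[have].mean()
            if behaviours is not None:
                src = have & (frac_n > 0)
                if src.any():
                    slot_frac[need] = slot_frac[src].mean(axis=0)
        if behaviours is not None:
            lonely = sel & (enmo_n > 0) & (frac_n == 0)
            src = sel & (frac_n > 0)
            if lonely.any() and src.any():
                slot_frac[lonely] = slot_frac[src].mean(axis=0)

    if behaviours is None:
        slot_frac = np.full((_MINUTES_PER_DAY, len(BEHAVIOURS)), np.nan)
    else:
        s = slot_frac.sum(axis=1, keepdims=True)
        slot_frac = np.where(s > 0, slot_frac / s, slot_frac)
    return MinuteProfile(enmo=slot_enmo, fractions=slot_frac,
                         n_days_observed=n_days)


def quality_check(epochs: EpochSeries, mask: WearMask,
                  calibration: CalibrationModel | None,
                  clip_fractions: tuple[float, float],
                  clip_limit: float = 0.01,
                  min_wear_h: float = 72.0,
                  min_mean_mg: float = 1.5,
                  max_mean_mg: float = 100.0) -> QualityReport:
    """Apply the four pre-defined exclusion criteria to one recording."""
    reasons: list[str] = []
    calibrated = calibration is not None
    if not calibrated:
        reasons.append("uncalibratable")
    pre, post = clip_fractions
    clipped_ok = pre <= clip_limit and post <= clip_limit
    if not clipped_ok:
        reasons.append("excess clipping")

    worn = mask.worn
    wear_hours = float(worn.sum()) * epochs.epoch_s / 3600.0
    hour_of_day = ((epochs.epoch_start // 3600).astype(np.int64)) % 24
    hour_coverage = np.zeros(24, dtype=bool)
    hour_coverage[np.unique(hour_of_day[worn])] = True
    if wear_hours < min_wear_h:
        reasons.append("insufficient wear-time")
    if not hour_coverage.all():
        reasons.append("incomplete hour coverage")

    mean_accel = np.nan
    if hour_coverage.all() and worn.any():
        profile = _impute_profile(epochs, mask, None)
        mean_accel = float(np.nanmean(profile.enmo))
    elif worn.any():
        mean_accel = float(np.nanmean(epochs.enmo_mean[worn]))
    if not (min_mean_mg <= mean_accel <= max_mean_mg):
        reasons.append("implausible acceleration")

    return QualityReport(calibrated=calibrated, clipped_ok=clipped_ok,
                         wear_hours=wear_hours, hour_coverage=hour_coverage,
                         mean_accel=mean_accel, eligible=not reasons,
                         failure_reasons=reasons)


def impute(epochs: EpochSeries, mask: WearMask,
           behaviours: np.ndarray | None = None,
           quality: QualityReport | None = None) -> MinuteProfile:
    """Minute-of-day imputation of ENMO (and behaviour fractions).

    For each of the 1440 clock minutes the profile holds the mean over worn
    days of that minute's ENMO and, when per-epoch behaviour labels are
    given, the mean one-hot behaviour vector.  Slots worn on zero days fall
    back to their hour-of-day mean (guaranteed non-empty by the hour
    coverage criterion).  Raises when called on a recording known to be
    ineligible.
    """
    if quality is not None and not quality.eligible:
        raise IneligibleRecordingError(
            "recording is ineligible: " + ", ".join(quality.failure_reasons))
    return _impute_profile(epochs, mask, behaviours)


def overall_acceleration(profile: MinuteProfile) -> float:
    """Unweighted mean ENMO over the 1440 minute-of-day slots, in mg."""
    if not profile.complete:
        raise IneligibleRecordingError("profile has unimputed slots")
    return float(profile.enmo.mean())
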