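"""Shared fixtures: all data is generated programmatically at test time.

The heavy 7-day end-to-end chain (synthesis at a reduced 25 Hz rate,
processing, wear screening, classifier training and prediction) lives in
session-scoped fixtures so the whole suite pays for it once.
"""

import numpy as np
import pytest

import wristtime as wt
from wristtime import classify, wear


@pytest.fixture(scope="session")
def cfg25():
    return wt.PipelineConfig(sample_rate_hz=25.0, seed=1)


@pytest.fixture(scope="session")
def week_raw(cfg25):
    """7-day ckb_like recording through a miscalibrated device, with truth."""
    schedule = wt.synth.make_schedule("ckb_like", days=7, seed=7)
    device = wt.synth.DeviceModel(gain=np.array([1.02, 0.98, 1.01]),
                                  offset=np.array([0.015, -0.01, 0.005]),
                                  sample_rate=25.0, device_id="ax3-042")
    rec, truth = wt.synth.synthesize_recording(schedule, device, seed=3)
    return schedule, rec, truth


@pytest.fixture(scope="session")
def week_processed(week_raw, cfg25):
    _, rec, _ = week_raw
    epochs, calibration, clip = wt.process_recording(rec, cfg25)
    return epochs, calibration, clip


@pytest.fixture(scope="session")
def week_wear(week_processed, cfg25):
    epochs, calibration, clip = week_processed
    mask = wear.detect_nonwear(epochs, cfg25.nonwear_sd_mg,
                               cfg25.nonwear_min_minutes)
    quality = wear.quality_check(epochs, mask, calibration, clip)
    return mask, quality


@pytest.fixture(scope="session")
def trained_model(cfg25):
    train_set = wt.pipeline.build_training_set(cfg25, days=1)
    model = classify.train(train_set, n_trees=100, seed=5)
    return train_set, model


@pytest.fixture(scope="session")
def week_prediction(week_processed, trained_model):
    epochs, _, _ = week_processed
    _, model = trained_model
    return classify.predict(epochs, model)


def make_epochs(axis_sd_mg, enmo_mg=None, start_s=0.0, epoch_s=30.0,
                rate=25.0):
    """Construct an EpochSeries directly from per-epoch axis SD values."""
    axis_sd_mg = np.asarray(axis_sd_mg, dtype=float)
    n = len(axis_sd_mg)
    if axis_sd_mg.ndim == 1:
        axis_sd_mg = np.repeat(axis_sd_mg[:, None], 3, axis=1)
    if enmo_mg is None:
        enmo_mg = axis_sd_mg[:, 0].copy()
    spe = int(epoch_s * rate)
    return wt.rawproc.EpochSeries(
        epoch_start=start_s + np.arange(n) * epoch_s,
        enmo_mean=np.asarray(enmo_mg, dtype=float),
        axis_mean=np.tile([0.0, 0.0, 1.0], (n, 1)),
        axis_sd=axis_sd_mg,
        n_samples=np.full(n, spe),
        features=None, epoch_s=epoch_s, rate=rate)
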