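"""End-to-end orchestration of the processing chain.

``run_pipeline`` executes synth -> process -> wear -> train -> predict ->
summarise under one configuration with deterministic sub-seeding, writes
per-stage text outputs plus a manifest with checksums, and logs record
counts at each filter.  Re-running with an identical config and inputs
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, rawproc, synth, wear
from .config import PipelineConfig
from .summarise import summarize_participant, waking_shares

log = logging.getLogger("wristtime")


class PipelineError(RuntimeError):
    pass


def _subseed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2 ** 31)


def derive_calibration(recording: rawproc.RawRecording,
                       config: PipelineConfig,
                       donor: rawproc.CalibrationModel | None = None):
    """Self-calibrate; fall back to donor parameters when that fails."""
    windows = rawproc.find_stationary(
        recording, window_s=config.stationary_window_s,
        sd_threshold_mg=config.stationary_sd_mg)
    try:
        return rawproc.fit_calibration(
            windows.means, windows.temps,
            min_windows=config.calib_min_windows,
            coverage_g=config.calib_coverage_g,
            max_residual_mg=config.calib_max_residual_mg,
            device_id=recording.device_id)
    except rawproc.UncalibratableError:
        if donor is None:
            raise
        return rawproc.borrow_calibration(recording, donor)


def process_recording(recording: rawproc.RawRecording,
                      config: PipelineConfig,
                      donor: rawproc.CalibrationModel | None = None):
    """Raw signal -> calibrated, filtered 30-s epoch series.

    Returns ``(epochs, calibration, clip_fractions)``.  The 20 Hz noise
    filter is skipped when the grid rate is at or below twice the cutoff
    (nothing above the pass band survives such sampling).
    """
    rec = rawproc.resample(recording, target_rate=recording.nominal_rate,
                           max_gap_s=config.max_gap_s)
    calibration = derive_calibration(rec, config, donor)
    clip = rawproc.clipped_fraction(rec, calibration,
                                    margin_g=config.clip_margin_g)
    cal = calibration.apply(rec)
    if cal.nominal_rate > 2 * config.lowpass_hz:
        cal = rawproc.lowpass(cal, cutoff_hz=config.lowpass_hz)
    epochs = rawproc.epochize(cal, epoch_s=config.epoch_s)
    return epochs, calibration, clip


def build_training_set(config: PipelineConfig, n_participants: int = 5,
                       days: int = 1, rate: float | None = None,
                       seed: int | None = None) -> classify.LabelledEpochSet:
    """Synthesise a labelled 3-class epoch set emulating a camera-annotated
    free-living validation study (ground-truth labels stand in for the
    image annotations)."""
    seed = config.seed if seed is None else seed
    rate = rate or config.sample_rate_hz
    feats, labels, pids = [], [], []
    for p in range(n_participants):
        s = _subseed(seed, 100 + p)
        schedule = synth.make_schedule("ckb_like", days=days, seed=s)
        device = synth.DeviceModel(sample_rate=rate, device_id=f"train-{p}")
        rec, truth = synth.synthesize_recording(schedule, device, seed=s + 1)
        # short validation-study recordings may lack sphere coverage; the
        # well-calibrated study devices supply donor (identity) parameters
        donor = rawproc.CalibrationModel(offset=np.zeros(3), gain=np.ones(3),
                                         residual_error=0.0, source="self",
                                         sphere_coverage_ok=True,
                                         device_id=device.device_id)
        epochs, _, _ = process_recording(rec, config, donor=donor)
        n = min(epochs.n_epochs, len(truth.epoch_label))
        keep = (~epochs.missing[:n]) & np.isin(truth.epoch_label[:n],
                                               list(classify.TO3))
        keep &= ~np.isnan(epochs.features[:n]).any(axis=1)
        feats.append(epochs.features[:n][keep])
        labels.append(np.array([classify.TO3[b]
                                for b in truth.epoch_label[:n][keep]]))
        pids.append(np.full(int(keep.sum()), p))
    return classify.LabelledEpochSet(features=np.vstack(feats),
                                     labels=np.concatenate(labels),
                                     participant=np.concatenate(pids))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 raw_path: str | Path | None = None,
                 model_dir: str | Path | None = None) -> dict:
    """Run the full stage chain and write versioned outputs.

    Without ``raw_path`` a synthetic recording is generated from the
    configured preset.  Outputs: epoch table, wear/quality report, minute
    profile, behaviour sequence, participant summary, and a manifest with a
    config hash and per-file checksums.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artefacts: dict[str, Path] = {}

    if raw_path is not None:
        raw_path = Path(raw_path)
        if not raw_path.exists():
            raise PipelineError(f"missing input path: {raw_path}")
        rec = synth.read_fixture(raw_path, nominal_rate=config.sample_rate_hz)
        truth = None
    else:
        schedule = synth.make_schedule(config.synth_preset, config.synth_days,
                                       seed=_subseed(config.seed, 1))
        device = synth.DeviceModel(
            gain=np.array([1.02, 0.98, 1.01]),
            offset=np.array([0.015, -0.01, 0.005]),
            sample_rate=config.sample_rate_hz)
        rec, truth = synth.synthesize_recording(schedule, device,
                                                seed=_subseed(config.seed, 2))
        log.info("synth: %d samples at %.0f Hz over %.1f days",
                 rec.n_samples, rec.nominal_rate, schedule.span / 86400)

    epochs, calibration, clip = process_recording(rec, config)
    log.info("process: %d epochs, calibration residual %.2f mg, clip %.4f/%.4f",
             epochs.n_epochs, calibration.residual_error, *clip)
    epoch_table = pd.DataFrame({
        "epoch_start": epochs.epoch_start, "enmo_mg": epochs.enmo_mean,
        "xsd": epochs.axis_sd[:, 0], "ysd": epochs.axis_sd[:, 1],
        "zsd": epochs.axis_sd[:, 2], "n_samples": epochs.n_samples})
    if epochs.features is not None:
        for j, name in enumerate(rawproc.FEATURE_NAMES):
            epoch_table[name] = epochs.features[:, j]
    artefacts["epochs"] = out / "epochs.csv"
    _write_with_header(epoch_table, artefacts["epochs"], config)

    mask = wear.detect_nonwear(epochs, sd_threshold_mg=config.nonwear_sd_mg,
                               min_minutes=config.nonwear_min_minutes)
    quality = wear.quality_check(
        epochs, mask, calibration, clip,
        clip_limit=config.clip_limit, min_wear_h=config.min_wear_h,
        min_mean_mg=config.min_mean_mg, max_mean_mg=config.max_mean_mg)
    log.info("wear: %.1f h worn, eligible=%s %s", quality.wear_hours,
             quality.eligible, quality.failure_reasons or "")
    artefacts["quality"] = out / "quality.txt"
    with open(artefacts["quality"], "w") as fh:
        fh.write(f"# config_hash = {config.config_hash}\n")
        fh.write(f"calibrated = {quality.calibrated}\n")
        fh.write(f"clipped_ok = {quality.clipped_ok}\n")
        fh.write(f"wear_hours = {quality.wear_hours:.3f}\n")
        fh.write(f"hour_coverage = {''.join('1' if v else '0' for v in quality.hour_coverage)}\n")
        fh.write(f"mean_accel_mg = {quality.mean_accel:.4f}\n")
        fh.write(f"eligible = {quality.eligible}\n")
        fh.write(f"failure_reasons = {','.join(quality.failure_reasons)}\n")
    if not quality.eligible:
        (out / "FAILED").write_text("ineligible recording\n")
        raise PipelineError(
            "recording ineligible: " + ", ".join(quality.failure_reasons))

    if model_dir is not None:
        model = classify.BehaviourModel.load(model_dir)
    else:
        train_set = build_training_set(config)
        model = classify.train(train_set, n_trees=config.n_trees,
                               seed=_subseed(config.seed, 3),
                               intensity_threshold=config.intensity_threshold_mg,
                               smoothing=config.hmm_smoothing)
        model.save(out / "model")
        log.info("train: %d epochs, OOB accuracy %.3f",
                 len(train_set.labels), model.forest.oob_accuracy(train_set.labels))

    sequence = classify.predict(epochs, model)
    artefacts["sequence"] = out / "sequence.csv"
    _write_with_header(pd.DataFrame({"epoch_start": epochs.epoch_start,
                                     "label": sequence.labels}),
                       artefacts["sequence"], config)

    profile = wear.impute(epochs, mask, behaviours=sequence.labels,
                          quality=quality)
    prof_table = pd.DataFrame({
        "minute_of_day": np.arange(1440), "enmo_mg": profile.enmo,
        "f_sleep": profile.fractions[:, 0], "f_sed": profile.fractions[:, 1],
        "f_lipa": profile.fractions[:, 2], "f_mvpa": profile.fractions[:, 3],
        "n_days": profile.n_days_observed})
    artefacts["profile"] = out / "profile.csv"
    _write_with_header(prof_table, artefacts["profile"], config)

    summary = summarize_participant(profile, epochs, mask, sequence.labels)
    shares = waking_shares(summary.sleep_h, summary.sedentary_h,
                           summary.lipa_h, summary.mvpa_min)
    summary_kv = {
        "overall_accel_mg": round(summary.overall_accel, 4),
        "sleep_h": round(summary.sleep_h, 4),
        "sedentary_h": round(summary.sedentary_h, 4),
        "lipa_h": round(summary.lipa_h, 4),
        "mvpa_min": round(summary.mvpa_min, 4),
        "waking_share_sedentary_pct": shares["sedentary"],
        "waking_share_lipa_pct": shares["LIPA"],
        "waking_share_mvpa_pct": shares["MVPA"],
    }
    artefacts["summary"] = out / "summary.txt"
    with open(artefacts["summary"], "w") as fh:
        fh.write(f"# config_hash = {config.config_hash}\n")
        for k, v in summary_kv.items():
            fh.write(f"{k} = {v}\n")

    manifest = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 2),
        "eligible": quality.eligible,
        "summary": summary_kv,
        "files": {k: {"path": str(p), "sha256": _sha256(p)}
                  for k, p in artefacts.items()},
    }
    if truth is not None:
        n = min(epochs.n_epochs, len(truth.epoch_label))
        manifest["accuracy_vs_truth"] = classify.accuracy(
            classify.BehaviourSequence(labels=sequence.labels[:n]),
            truth.epoch_label[:n])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("summarise: done in %.1f s", manifest["elapsed_s"])
    return manifest


def _write_with_header(df: pd.DataFrame, path: Path,
                       config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash = {config.config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
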