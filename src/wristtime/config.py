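"""Pipeline configuration.

All thresholds used across the processing chain live in one flat object so
their provenance is auditable: the sampling rate, epoch length, the 13.0 mg /
60 min non-wear rule, the 72 h wear minimum, the 1.5-100 mg plausibility
bounds, the 1% clip limit and the 100 mg LIPA/MVPA intensity threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # signal processing
    sample_rate_hz: float = 100.0
    epoch_s: float = 30.0
    lowpass_hz: float = 20.0
    max_gap_s: float = 1.0
    # calibration
    stationary_window_s: float = 10.0
    stationary_sd_mg: float = 13.0
    calib_min_windows: int = 10
    calib_coverage_g: float = 0.3
    calib_max_residual_mg: float = 10.0
    # non-wear and eligibility
    nonwear_sd_mg: float = 13.0
    nonwear_min_minutes: int = 60
    min_wear_h: float = 72.0
    min_mean_mg: float = 1.5
    max_mean_mg: float = 100.0
    clip_limit: float = 0.01
    clip_margin_g: float = 0.1
    # classification
    intensity_threshold_mg: float = 100.0
    n_trees: int = 100
    hmm_smoothing: float = 1.0
    # orchestration
    seed: int = 42
    synth_preset: str = "ckb_like"
    synth_days: int = 7
    log_level: str = "INFO"

    _POSITIVE = (
        "sample_rate_hz", "epoch_s", "lowpass_hz", "max_gap_s",
        "stationary_window_s", "stationary_sd_mg", "calib_min_windows",
        "calib_coverage_g", "calib_max_residual_mg", "nonwear_sd_mg",
        "nonwear_min_minutes", "min_wear_h", "min_mean_mg", "max_mean_mg",
        "clip_limit", "clip_margin_g", "intensity_threshold_mg", "n_trees",
        "hmm_smoothing",
    )

    def validate(self) -> "PipelineConfig":
        errors = []
        for key in self._POSITIVE:
            value = getattr(self, key)
            if not value > 0:
                errors.append(f"{key} must be > 0, got {value!r}")
        if self.max_mean_mg <= self.min_mean_mg:
            errors.append("max_mean_mg must exceed min_mean_mg")
        if self.synth_days < 1:
            errors.append("synth_days must be >= 1")
        if errors:
            raise ConfigError("; ".join(errors))
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("_POSITIVE", None)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        """Stable short hash identifying the effective configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range thresholds."""


def validate_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file, apply defaults for absent keys, range-check.

    An empty or absent file yields the default configuration. Unknown keys
    and out-of-range values raise :class:`ConfigError` naming the key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    valid_keys = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - valid_keys
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data).validate()
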