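"""Configuration objects for the PPG analysis pipeline.

All tunables live in small dataclasses so that a run is fully described by
plain keyword values, and can be loaded from a YAML file (flat keys or a
nested mapping with ``filter:``, ``detector:`` and ``pipeline:`` sections).
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class FilterConfig:
    """Preprocessing filter bank settings.

    Parameters
    ----------
    bp_low, bp_high : float
        Band-pass stop-band edges in Hz. The default 0.5–12 Hz band keeps
        pulse-wave content at heart rates of 30–200 bpm while suppressing
        baseline wander and high-frequency noise.
    bp_order : int
        Order of the one-way Chebyshev type-II prototype; the filter is
        applied forward–backward, so the effective attenuation is doubled.
    bp_rs_db : float
        Stop-band attenuation of the one-way prototype in dB.
    maf_signal_ms : float
        Width of the flat moving-average filter applied to the band-passed
        PPG (50 ms ~ 9 Hz cut-off).
    maf_deriv_ms : float
        Width of the flat moving-average filter applied after each
        differentiation stage (10 ms ~ 45 Hz cut-off).
    resample_fs : float
        Rate (Hz) of the Fourier-resampled copy used only by the beat
        detector.
    """

    bp_low: float = 0.5
    bp_high: float = 12.0
    bp_order: int = 4
    bp_rs_db: float = 20.0
    maf_signal_ms: float = 50.0
    maf_deriv_ms: float = 10.0
    resample_fs: float = 75.0

    def validate(self, fs: float | None = None) -> None:
        if not (0 < self.bp_low < self.bp_high):
            raise ConfigError("require 0 < bp_low < bp_high")
        if fs is not None and self.bp_high >= fs / 2:
            from .errors import FilterDesignError

            raise FilterDesignError(
                f"bp_high={self.bp_high} Hz needs fs > {2 * self.bp_high} Hz")
        if self.maf_signal_ms <= 0 or self.maf_deriv_ms <= 0:
            raise ConfigError("MAF widths must be > 0")
        if self.resample_fs <= 0:
            raise ConfigError("resample_fs must be > 0")
        if self.bp_order < 1:
            raise ConfigError("bp_order must be >= 1")


@dataclass
class DetectorConfig:
    """Adaptive systolic-peak detector settings.

    The detector works on 10 s windows of the 75 Hz signal: a heart-rate
    band (``hr_band``) filter supports a per-window HR estimate, then a
    peak band whose upper edge scales with the estimated HR isolates the
    beat-rate oscillation on which local maxima are picked.
    """

    window_s: float = 10.0
    hr_min: float = 30.0
    hr_max: float = 200.0
    iir_order: int = 5
    iir_rs_db: float = 20.0
    hr_band: tuple[float, float] = (0.5, 3.3)
    peak_band_low: float = 0.5
    # upper peak-band edge = peak_band_harmonics * HR(Hz); keeps enough
    # harmonics for the crest to track the true systolic peak
    peak_band_harmonics: float = 6.0
    refine_ms: float = 100.0
    refractory_factor: float = 0.6
    amp_percentile: float = 75.0
    amp_fraction: float = 0.3
    merge_ms: float = 100.0

    def validate(self) -> None:
        if not (0 < self.hr_min < self.hr_max):
            raise ConfigError("require 0 < hr_min < hr_max")
        if self.window_s <= 0:
            raise ConfigError("window_s must be > 0")
        if not (0 < self.refractory_factor < 1):
            raise ConfigError("refractory_factor must be in (0, 1)")


@dataclass
class PipelineConfig:
    """End-to-end run options on top of the filter and detector settings."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    correction: bool = True
    #: substitute a clear PPG local minimum for the dicrotic notch when the
    #: derivative-based estimate is > 100 ms away (disable for single-pulse
    #: PPG-BP-style analysis)
    notch_min_substitution: bool = True
    width_percents: tuple[float, ...] = (50.0,)
    warmup_s: float = 1.0
    sqi: bool = False
    #: systolic (onset->notch) and diastolic (notch->offset) minimum durations
    min_systolic_ms: float = 120.0
    min_diastolic_ms: float = 300.0
    #: fractional pulse-duration search bounds for the e/f points and the
    #: diastolic peak
    e_bound_frac: float = 0.6
    f_bound_frac: float = 0.8
    dp_bound_frac: float = 0.8

    def validate(self, fs: float | None = None) -> None:
        self.filter.validate(fs)
        self.detector.validate()
        for x in self.width_percents:
            if not (0 < x < 100):
                raise ConfigError("width percentages must be in (0, 100)")


def _apply_flat(cfg: PipelineConfig, data: dict) -> None:
    known = {}
    for obj in (cfg.filter, cfg.detector, cfg):
        for f in fields(obj):
            if f.name in ("filter", "detector"):
                continue
            known.setdefault(f.name, obj)
    for key, value in data.items():
        if isinstance(value, dict):
            target = {"filter": cfg.filter, "detector": cfg.detector, "pipeline": cfg}.get(key)
            if target is None:
                raise ConfigError(f"unknown config section {key!r}")
            for k, v in value.items():
                if not hasattr(target, k):
                    raise ConfigError(f"unknown config key {key}.{k}")
                setattr(target, k, _coerce(target, k, v))
        else:
            if key not in known:
                raise ConfigError(f"unknown config key {key!r}")
            setattr(known[key], key, _coerce(known[key], key, value))


def _coerce(obj, name, value):
    current = getattr(obj, name)
    if isinstance(current, tuple) and not isinstance(value, (list, tuple)):
        raise ConfigError(f"{name} must be a list")
    if isinstance(current, tuple):
        return tuple(value)
    if isinstance(current, bool):
        return bool(value)
    if isinstance(current, float):
        return float(value)
    if isinstance(current, int):
        return int(value)
    return value


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file.

    Accepts either flat keys (``bp_high: 8``) or nested sections
    (``filter: {bp_high: 8}``). Unknown keys raise :class:`ConfigError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    cfg = PipelineConfig()
    _apply_flat(cfg, data)
    cfg.validate()
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    return asdict(cfg)
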