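"""Zero-phase filtering of the PPG and computation of its derivatives.

The working object of the pipeline is :class:`ProcessedSignal`: the
band-passed and smoothed PPG, its first three derivatives (each smoothed
with a short moving average after every differentiation stage), and a
Fourier-resampled 75 Hz copy used only by the beat detector.

All filters are zero-phase (forward-backward IIR, centered FIR kernels),
so extremum locations — which every downstream fiducial definition relies
on — are preserved.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import FilterConfig
from .errors import FilterDesignError, ShortSignalError
from .io import RawSignal

log = logging.getLogger(__name__)

__all__ = [
    "ProcessedSignal",
    "bandpass_filter",
    "moving_average",
    "compute_derivatives",
    "resample_for_beats",
    "preprocess",
]


@dataclass
class ProcessedSignal:
    """Filtered PPG, its three derivatives and the 75 Hz detector copy.

    ``ppg``, ``d1``, ``d2``, ``d3`` share one length and the sampling rate
    ``fs``; derivative units are amplitude·s⁻¹, s⁻², s⁻³.
    """

    ppg: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    d3: np.ndarray
    fs: float
    ppg_75: np.ndarray = field(default_factory=lambda: np.empty(0))
    resample_fs: float = 75.0

    def __post_init__(self) -> None:
        n = len(self.ppg)
        if not (len(self.d1) == len(self.d2) == len(self.d3) == n):
            raise ValueError("ppg and derivatives must have equal length")
        for name in ("ppg", "d1", "d2", "d3"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")


def design_bandpass(cfg: FilterConfig, fs: float) -> np.ndarray:
    """Chebyshev type-II band-pass in second-order sections."""
    if fs <= 2 * cfg.bp_high:
        raise FilterDesignError(
            f"sampling rate {fs} Hz too low for a {cfg.bp_high} Hz upper band edge"
        )
    return signal.cheby2(
        cfg.bp_order, cfg.bp_rs_db, [cfg.bp_low, cfg.bp_high],
        btype="bandpass", fs=fs, output="sos",
    )


def _sosfiltfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # scipy's default padlen for sosfiltfilt
    ntaps = 2 * sos.shape[0] + 1
    padlen = 3 * (ntaps - 1)
    if len(x) <= padlen:
        raise ShortSignalError(
            f"signal of {len(x)} samples is shorter than the filter warm-up ({padlen + 1})"
        )
    return signal.sosfiltfilt(sos, x)


def bandpass_filter(raw: RawSignal, cfg: FilterConfig | None = None) -> np.ndarray:
    """Zero-phase Chebyshev-II band-pass of a raw PPG.

    The quoted order refers to the one-way prototype; forward-backward
    application squares its magnitude response and cancels its phase.
    """
    cfg = cfg or FilterConfig()
    cfg.validate(raw.fs)
    sos = design_bandpass(cfg, raw.fs)
    return _sosfiltfilt(sos, np.asarray(raw.samples, dtype=float))


def moving_average(x: np.ndarray, width_ms: float, fs: float) -> np.ndarray:
    """Flat (boxcar) moving average with an odd, centered window.

    The window length is ``round(width_ms * fs / 1000)`` forced odd so the
    kernel is symmetric (zero phase). Edges use a shrinking window, which
    keeps the output the same length and exact on constants. A width below
    one sample returns the input unchanged.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(width_ms * fs / 1000.0))
    if w <= 1:
        log.info("moving_average window < 2 samples (width_ms=%s, fs=%s); no-op", width_ms, fs)
        return x.copy()
    if w % 2 == 0:
        w += 1
    # shrinking-window edges == normalized convolution with an all-ones mask
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def compute_derivatives(
    ppg: np.ndarray, fs: float, cfg: FilterConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First three derivatives by iterated central differences.

    Each stage is a central difference scaled to per-second units followed
    by the short moving average, mirroring the smoothing applied to the
    PPG itself. Central differences preserve extremum locations, which the
    fiducial definitions depend on.
    """
    cfg = cfg or FilterConfig()
    dt = 1.0 / fs
    d1 = moving_average(np.gradient(np.asarray(ppg, dtype=float), dt), cfg.maf_deriv_ms, fs)
    d2 = moving_average(np.gradient(d1, dt), cfg.maf_deriv_ms, fs)
    d3 = moving_average(np.gradient(d2, dt), cfg.maf_deriv_ms, fs)
    return d1, d2, d3


def resample_for_beats(ppg: np.ndarray, fs: float, target_fs: float = 75.0) -> np.ndarray:
    """Fourier-method resampling used for the beat detector.

    Identity when the rates already match; output length is
    ``round(n * target_fs / fs)``.
    """
    ppg = np.asarray(ppg, dtype=float)
    if target_fs == fs:
        return ppg.copy()
    n_out = int(round(len(ppg) * target_fs / fs))
    return signal.resample(ppg, n_out)


def preprocess(raw: RawSignal, cfg: FilterConfig | None = None) -> ProcessedSignal:
    """Full preprocessing chain: band-pass, smooth, differentiate, resample."""
    cfg = cfg or FilterConfig()
    bp = bandpass_filter(raw, cfg)
    ppg = moving_average(bp, cfg.maf_signal_ms, raw.fs)
    d1, d2, d3 = compute_derivatives(ppg, raw.fs, cfg)
    ppg_75 = resample_for_beats(ppg, raw.fs, cfg.resample_fs)
    return ProcessedSignal(
        ppg=ppg, d1=d1, d2=d2, d3=d3, fs=raw.fs,
        ppg_75=ppg_75, resample_fs=cfg.resample_fs,
    )
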