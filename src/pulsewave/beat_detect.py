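"""Adaptive systolic-peak detection on the 75 Hz signal.

The detector processes the resampled PPG in 10 s windows. For each
window it (i) estimates the heart rate from the peak intervals of an
HR-band (0.5-3.3 Hz) filtered copy, retaining the previous window's
estimate when the implied rate falls outside the plausible 30-200 bpm
range; (ii) band-pass filters the window with an upper edge tied to the
estimated HR and picks local maxima above a rank-based amplitude
threshold, separated by a refractory interval of 0.6 of the HR-implied
period; and (iii) maps the peak indices to the analysis rate and snaps
each to the local maximum of the filtered PPG nearby. Duplicates at
window joins are merged keeping the higher-amplitude peak.

All filters are zero-phase Chebyshev type-II IIRs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import DetectorConfig
from .preprocess import ProcessedSignal

log = logging.getLogger(__name__)

__all__ = ["BeatSequence", "estimate_segment_hr", "detect_beats"]


@dataclass
class BeatSequence:
    """Detected systolic peaks at the analysis and 75 Hz rates."""

    sp_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    sp_idx_75: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    segment_hr: np.ndarray = field(default_factory=lambda: np.empty(0))
    segment_valid: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    fs: float = 0.0

    def __len__(self) -> int:
        return len(self.sp_idx)

    def times_ms(self) -> np.ndarray:
        return self.sp_idx * 1000.0 / self.fs


def _zero_phase_band(x: np.ndarray, low: float, high: float, fs: float,
                     order: int, rs_db: float) -> np.ndarray:
    high = min(high, 0.45 * fs)
    if high <= low:
        high = min(1.5 * low, 0.45 * fs)
    sos = signal.cheby2(order, rs_db, [low, high], btype="bandpass", fs=fs, output="sos")
    ntaps = 2 * sos.shape[0] + 1
    padlen = min(3 * (ntaps - 1), max(len(x) - 2, 0))
    if len(x) < 4:
        return x - np.mean(x) if len(x) else x
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def estimate_segment_hr(
    segment: np.ndarray, prev_hr: float | None, cfg: DetectorConfig | None = None,
    fs: float = 75.0,
) -> tuple[float, bool]:
    """Estimate the heart rate of one window from HR-band peak intervals.

    Returns ``(hr_bpm, valid)``. When the implied rate falls outside
    ``[hr_min, hr_max]`` (or the segment is degenerate), the previous
    window's estimate — or the band midpoint if there is none — is
    returned with ``valid=False``.
    """
    cfg = cfg or DetectorConfig()
    fallback = prev_hr if prev_hr is not None else 0.5 * (cfg.hr_min + cfg.hr_max)
    segment = np.asarray(segment, dtype=float)
    if len(segment) < fs or np.ptp(segment) == 0:
        return fallback, False
    xf = _zero_phase_band(segment, cfg.hr_band[0], cfg.hr_band[1], fs,
                          cfg.iir_order, cfg.iir_rs_db)
    # a segment whose power lies almost entirely outside the plausible
    # heart-rate band carries no usable rhythm (e.g. an over-fast
    # oscillation): keep the previous estimate
    freqs, psd = signal.periodogram(segment - np.mean(segment), fs=fs,
                                    window="hann")
    total = float(np.sum(psd[freqs > 0]))
    in_band = float(np.sum(psd[(freqs >= cfg.hr_band[0]) & (freqs <= cfg.hr_band[1])]))
    if total <= 0 or in_band < 0.2 * total:
        return fallback, False
    # period from the autocorrelation: robust against a prominent
    # diastolic wave that doubles simple peak counting. The biased
    # estimate (no 1/(n-lag) correction) discounts long lags, and the
    # fundamental is taken as the shortest lag whose peak comes close to
    # the global maximum — avoiding subharmonic (multiple-period) picks.
    n = len(xf)
    ac = signal.correlate(xf, xf, mode="full")[n - 1:]
    if ac[0] <= 0:
        return fallback, False
    ac = ac / ac[0]
    # search down to periods 1.5x faster than hr_max so an over-fast
    # rhythm is recognized as implausible instead of clipped into range
    lag_lo = max(2, int(round(fs * 60.0 / (1.5 * cfg.hr_max))))
    lag_hi = min(n - 1, int(round(fs * 60.0 / cfg.hr_min)))
    if lag_hi <= lag_lo:
        return fallback, False
    window = ac[lag_lo:lag_hi + 1]
    peaks, _ = signal.find_peaks(window)
    if len(peaks) == 0:
        peaks = np.asarray([int(np.argmax(window))])
    m = float(window[peaks].max())
    fundamental = peaks[window[peaks] >= 0.75 * m][0]
    hr = 60.0 * fs / float(lag_lo + fundamental)
    if cfg.hr_min <= hr <= cfg.hr_max:
        return hr, True
    return fallback, False


def _window_peaks(seg: np.ndarray, hr: float, cfg: DetectorConfig, fs: float,
                  core: tuple[int, int] | None = None) -> np.ndarray:
    """Candidate peaks in one (padded) window; ``core`` bounds, when given,
    restrict the returned peaks to the window proper so that overlap
    padding only serves to suppress filter edge transients."""
    high = cfg.peak_band_harmonics * hr / 60.0
    xf = _zero_phase_band(seg, cfg.peak_band_low, high, fs, cfg.iir_order, cfg.iir_rs_db)
    refractory = max(1, int(round(fs * cfg.refractory_factor * 60.0 / hr)))
    cand, _ = signal.find_peaks(xf, distance=refractory)
    if len(cand) == 0:
        return cand
    amps = xf[cand]
    thr = cfg.amp_fraction * np.percentile(amps, cfg.amp_percentile)
    keep = cand[amps >= thr]
    if core is not None:
        keep = keep[(keep >= core[0]) & (keep < core[1])]
    return keep


def detect_beats(proc: ProcessedSignal, cfg: DetectorConfig | None = None) -> BeatSequence:
    """Detect systolic peaks on ``proc.ppg_75`` and refine on ``proc.ppg``.

    Deterministic: identical input and config give identical output. An
    all-zero (or empty) signal yields an empty :class:`BeatSequence`.
    """
    cfg = cfg or DetectorConfig()
    cfg.validate()
    x75 = np.asarray(proc.ppg_75, dtype=float)
    fs75 = proc.resample_fs
    if len(x75) == 0 or np.ptp(x75) == 0:
        return BeatSequence(fs=proc.fs)

    win = int(round(cfg.window_s * fs75))
    pad = int(round(2.0 * fs75))  # overlap absorbing filter edge transients
    n_win = max(1, int(np.ceil(len(x75) / win)))
    peaks75: list[int] = []
    seg_hr: list[float] = []
    seg_valid: list[bool] = []
    prev_hr: float | None = None
    for w in range(n_win):
        lo, hi = w * win, min((w + 1) * win, len(x75))
        seg = x75[lo:hi]
        if np.ptp(seg) == 0:
            seg_hr.append(prev_hr if prev_hr is not None else 0.5 * (cfg.hr_min + cfg.hr_max))
            seg_valid.append(False)
            continue
        hr, valid = estimate_segment_hr(seg, prev_hr, cfg, fs75)
        seg_hr.append(hr)
        seg_valid.append(valid)
        prev_hr = hr
        plo, phi = max(0, lo - pad), min(len(x75), hi + pad)
        for p in _window_peaks(x75[plo:phi], hr, cfg, fs75,
                               core=(lo - plo, hi - plo)):
            peaks75.append(plo + int(p))

    if not peaks75:
        return BeatSequence(segment_hr=np.asarray(seg_hr),
                            segment_valid=np.asarray(seg_valid), fs=proc.fs)
    peaks75 = np.asarray(sorted(peaks75), dtype=int)

    # map to the analysis rate and snap to the local PPG maximum
    ratio = proc.fs / fs75
    half = int(round(cfg.refine_ms / 1000.0 * proc.fs))
    ppg = proc.ppg
    refined: list[int] = []
    for p75 in peaks75:
        center = int(round(p75 * ratio))
        lo = max(0, center - half)
        hi = min(len(ppg), center + half + 1)
        if hi <= lo:
            continue
        refined.append(lo + int(np.argmax(ppg[lo:hi])))
    refined_arr = np.asarray(sorted(set(refined)), dtype=int)

    # merge near-duplicates from window joins, keep the higher peak
    merge = int(round(cfg.merge_ms / 1000.0 * proc.fs))
    min_gap = int(round(proc.fs * 60.0 / cfg.hr_max))
    kept: list[int] = []
    for idx in refined_arr:
        if kept and idx - kept[-1] < max(merge, min_gap):
            if ppg[idx] > ppg[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)
    sp_idx = np.asarray(kept, dtype=int)
    sp75 = np.asarray(np.round(sp_idx / ratio), dtype=int)
    return BeatSequence(sp_idx=sp_idx, sp_idx_75=sp75,
                        segment_hr=np.asarray(seg_hr),
                        segment_valid=np.asarray(seg_valid), fs=proc.fs)
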