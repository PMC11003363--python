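"""Pulse-wave segmentation: onsets and offsets around each systolic peak.

The onset is the beginning of the systolic upslope. It is first taken as
the minimum of the PPG between the previous systolic peak and the current
one, then refined to the last local maximum of the third derivative
preceding the pulse's early-systolic p1 landmark (which is itself found
from a provisional a/b pass on the second derivative). The offset of a
pulse is the onset of the next one, so retained pulses tile the record.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._extrema import argmax_in, argmin_in, local_maxima, local_minima
from .beat_detect import BeatSequence
from .config import PipelineConfig
from .preprocess import ProcessedSignal

log = logging.getLogger(__name__)

__all__ = ["PulseWave", "detect_onsets_offsets"]


@dataclass
class PulseWave:
    """One segmented pulse: onset, systolic peak and offset sample indices."""

    on_idx: int
    sp_idx: int
    off_idx: int
    valid: bool = True

    def duration_ms(self, fs: float) -> float:
        return (self.off_idx - self.on_idx) * 1000.0 / fs


def _upslope_argmax_d2(proc: ProcessedSignal, lo: int, hi: int) -> int | None:
    """Highest second derivative on the systolic upslope (d1 > 0): the
    a-wave sits on the rising edge, unlike the inter-beat trough whose
    curvature can rival it."""
    lo, hi = max(lo, 0), min(hi, len(proc.d2) - 1)
    if hi < lo:
        return None
    seg = proc.d2[lo:hi + 1].copy()
    seg[proc.d1[lo:hi + 1] <= 0] = -np.inf
    if not np.isfinite(seg).any():
        return lo + int(np.argmax(proc.d2[lo:hi + 1]))
    return lo + int(np.argmax(seg))


def _refine_onset(proc: ProcessedSignal, lo: int, sp: int, hi: int,
                  margin: int = 0) -> int | None:
    """Provisional min-before-sp onset refined via the PPG''' landmark chain.

    The provisional a-wave is the last curvature maximum before the
    steepest upslope point, and the backward search for the onset (the
    last PPG''' maximum preceding p1) starts just before the inter-beat
    minimum — both guards keep the previous beat's diastolic tail out of
    the chain.
    """
    cand = argmin_in(proc.ppg, lo, sp - 1)
    if cand is None:
        return None
    u = argmax_in(proc.d1, cand, sp)
    a_list = local_maxima(proc.d2, cand, u) if u is not None else []
    a = a_list[-1] if a_list else _upslope_argmax_d2(proc, cand, sp)
    if a is None:
        return cand
    b_list = local_minima(proc.d2, a + 1, min(hi, len(proc.ppg) - 2))
    if not b_list:
        return cand
    b = b_list[0]
    p1_list = local_maxima(proc.d3, b + 1, min(hi, len(proc.ppg) - 2))
    if not p1_list:
        return cand
    p1 = p1_list[0]
    on_list = local_maxima(proc.d3, max(lo, cand - margin), p1 - 1)
    if not on_list:
        return cand
    return on_list[-1]


def detect_onsets_offsets(
    proc: ProcessedSignal, beats: BeatSequence, cfg: PipelineConfig | None = None
) -> list[PulseWave]:
    """Locate pulse onsets/offsets for every detected systolic peak.

    The first and last ``warmup_s`` seconds are treated as filter warm-up
    and pulses overlapping them are dropped. Beats for which no admissible
    onset exists are excluded with a logged reason.
    """
    cfg = cfg or PipelineConfig()
    fs = proc.fs
    sps = np.asarray(beats.sp_idx, dtype=int)
    if len(sps) == 0:
        return []
    warm = int(round(cfg.warmup_s * fs))
    period = float(np.median(np.diff(sps))) if len(sps) > 1 else 1.0 * fs

    onsets: list[int | None] = []
    for k, sp in enumerate(sps):
        lo = int(sps[k - 1]) if k > 0 else max(0, sp - int(round(1.5 * period)))
        hi = int(sps[k + 1]) if k + 1 < len(sps) else min(len(proc.ppg) - 1,
                                                          sp + int(round(0.75 * period)))
        if sp - lo < 3:
            onsets.append(None)
            continue
        onsets.append(_refine_onset(proc, lo, int(sp), int(sp + 0.6 * (hi - sp)),
                                    margin=int(round(0.05 * period))))

    pulses: list[PulseWave] = []
    for k, sp in enumerate(sps):
        on = onsets[k]
        if on is None:
            log.info("pulse %d: no admissible onset; skipped", k)
            continue
        if k + 1 < len(sps) and onsets[k + 1] is not None:
            off = onsets[k + 1]
        else:
            # last beat: offset surrogate = first local minimum after sp
            hi = min(len(proc.ppg) - 2, int(sp + 1.5 * period))
            mins = local_minima(proc.ppg, int(sp) + 1, hi)
            mins = [m for m in mins if m - sp > 0.2 * period]
            if not mins:
                log.info("pulse %d: no offset surrogate after last peak; dropped", k)
                continue
            off = mins[0]
        if not (on < sp < off):
            log.info("pulse %d: inconsistent on/sp/off ordering; skipped", k)
            continue
        if on < warm or off > len(proc.ppg) - 1 - warm:
            continue
        pulses.append(PulseWave(on_idx=int(on), sp_idx=int(sp), off_idx=int(off)))
    return pulses
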