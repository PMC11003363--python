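"""Template-matching signal-quality index for segmented pulses.

Each pulse is linearly resampled to a fixed length, a template is formed
as the pointwise mean across pulses, and the per-pulse SQI is the Pearson
correlation of the pulse with the template, clipped to [0, 1]. The index
is invariant to a pulse's amplitude scale and baseline offset (Pearson
correlation property). It is informational only: no other stage is gated
on it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ProcessedSignal
from .segmentation import PulseWave

__all__ = ["QualitySeries", "compute_sqi"]

TEMPLATE_LEN = 100


@dataclass
class QualitySeries:
    """Per-pulse SQI in [0, 1] (NaN when undefined) and the mean template."""

    sqi: np.ndarray = field(default_factory=lambda: np.empty(0))
    template: np.ndarray = field(default_factory=lambda: np.empty(0))


def _resample_pulse(ppg: np.ndarray, pulse: PulseWave, length: int) -> np.ndarray:
    seg = ppg[pulse.on_idx:pulse.off_idx + 1]
    grid = np.linspace(0, len(seg) - 1, length)
    return np.interp(grid, np.arange(len(seg)), seg)


def compute_sqi(
    proc: ProcessedSignal, pulses: list[PulseWave], length: int = TEMPLATE_LEN
) -> QualitySeries:
    """Per-pulse template-matching SQI; needs at least two pulses."""
    if len(pulses) < 2:
        return QualitySeries(sqi=np.full(len(pulses), np.nan))
    beats = np.vstack([_resample_pulse(proc.ppg, p, length) for p in pulses])
    template = beats.mean(axis=0)
    t_center = template - template.mean()
    t_norm = np.linalg.norm(t_center)
    sqi = np.empty(len(pulses))
    for i, beat in enumerate(beats):
        b_center = beat - beat.mean()
        denom = np.linalg.norm(b_center) * t_norm
        r = float(b_center @ t_center / denom) if denom > 0 else np.nan
        sqi[i] = np.nan if np.isnan(r) else min(max(r, 0.0), 1.0)
    return QualitySeries(sqi=sqi, template=template)
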