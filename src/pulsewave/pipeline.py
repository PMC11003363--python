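"""End-to-end orchestration: raw signal in, tables out."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beat_detect import BeatSequence, detect_beats
from .biomarkers import compute_biomarkers
from .config import PipelineConfig
from .fiducials import FiducialSet, detect_fiducials
from .io import RawSignal, write_beats, write_biomarkers, write_fiducials
from .preprocess import ProcessedSignal, preprocess
from .segmentation import PulseWave, detect_onsets_offsets
from .sqi import QualitySeries, compute_sqi

__all__ = ["PipelineResult", "analyze"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one recording."""

    proc: ProcessedSignal
    beats: BeatSequence
    pulses: list[PulseWave]
    fiducials: list[FiducialSet]
    per_beat: pd.DataFrame
    summary: pd.DataFrame
    sqi: QualitySeries | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write beat, fiducial and biomarker tables into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"beats": write_beats(self.beats.sp_idx, self.proc.fs, out / "beats.csv")}
        sqi_vals = self.sqi.sqi if self.sqi is not None else None
        paths["fiducials"] = write_fiducials(
            self.fiducials, out / "fiducials.csv", self.proc.fs, sqi=sqi_vals)
        b, s = write_biomarkers(self.per_beat, self.summary, out / "biomarkers")
        paths["biomarkers_beats"], paths["biomarkers_summary"] = b, s
        return paths


def analyze(raw: RawSignal, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run preprocessing, beat detection, segmentation, fiducial detection,
    biomarker engineering and (optionally) the SQI on one recording."""
    cfg = cfg or PipelineConfig()
    cfg.validate(raw.fs)
    proc = preprocess(raw, cfg.filter)
    beats = detect_beats(proc, cfg.detector)
    pulses = detect_onsets_offsets(proc, beats, cfg)
    fiducials = detect_fiducials(proc, pulses, cfg)
    per_beat, summary = compute_biomarkers(proc, fiducials, cfg)
    quality = compute_sqi(proc, pulses) if cfg.sqi else None
    return PipelineResult(proc=proc, beats=beats, pulses=pulses,
                          fiducials=fiducials, per_beat=per_beat,
                          summary=summary, sqi=quality, config=cfg)
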