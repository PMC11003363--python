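import numpy as np
import pytest

from pulsewave import PipelineConfig, SynthConfig, analyze, generate_synthetic_ppg


@pytest.fixture(scope="session")
def default_record():
    """A clean 60 bpm synthetic recording with full ground truth."""
    cfg = SynthConfig(hr=60.0, duration=20.0, fs=250.0, seed=1)
    raw, gt = generate_synthetic_ppg(cfg)
    return raw, gt


@pytest.fixture(scope="session")
def default_result(default_record):
    raw, _ = default_record
    return analyze(raw, PipelineConfig())


def pair_fiducials(fiducials, gt, fs, tolerance_ms=150.0):
    """Match detected fiducial sets to ground-truth beats by peak time."""
    pairs = []
    if not fiducials:
        return pairs
    sp_det = np.array([f.sp for f in fiducials]) * 1000.0 / fs
    for beat in gt.beats:
        i = int(np.argmin(np.abs(sp_det - beat["sp"])))
        if abs(sp_det[i] - beat["sp"]) <= tolerance_ms:
            pairs.append((fiducials[i], beat))
    return pairs
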