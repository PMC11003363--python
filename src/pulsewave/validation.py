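"""Evaluation machinery: beat matching with F1, fiducial error statistics
and Bland-Altman agreement.

Beat trains are aligned by a single global lag (chosen by
cross-correlating binarized event trains at 10 ms resolution), then
matched one-to-one greedily within a tolerance. Sensitivity, positive
predictive value and their harmonic mean (F1) are reported in percent.

Fiducial errors are summarized per point as the mean absolute error, the
standard deviation of the absolute errors, the signed bias, and the
Bland-Altman limits of agreement (bias +/- 1.96 SD of the signed
differences, covering ~95% of errors).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fiducials import POINT_NAMES, FiducialSet

log = logging.getLogger(__name__)

__all__ = ["MatchResult", "ErrorStats", "align_and_match", "match_events",
           "fiducial_errors", "bland_altman_stats", "error_table"]

_BIN_MS = 10.0


@dataclass
class MatchResult:
    """One-to-one beat-matching counts and scores (percent)."""

    TP: int
    FP: int
    FN: int
    Se: float
    PPV: float
    F1: float
    lag_ms: float = 0.0


@dataclass
class ErrorStats:
    """Per-fiducial timing-error summary in ms."""

    mae: float
    sd_abs: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


def _best_lag(detected: np.ndarray, reference: np.ndarray, max_lag_ms: float) -> float:
    """Global lag (ms) maximizing coincidence of 10 ms binned event trains."""
    if len(detected) == 0 or len(reference) == 0 or max_lag_ms <= 0:
        return 0.0
    lo = min(detected.min(), reference.min()) - max_lag_ms
    hi = max(detected.max(), reference.max()) + max_lag_ms
    n_bins = int(np.ceil((hi - lo) / _BIN_MS)) + 1
    det = np.zeros(n_bins)
    ref = np.zeros(n_bins)
    det[np.floor((detected - lo) / _BIN_MS).astype(int)] = 1.0
    ref[np.floor((reference - lo) / _BIN_MS).astype(int)] = 1.0
    max_shift = int(round(max_lag_ms / _BIN_MS))
    best_score, best_shift = -1.0, 0
    for shift in range(-max_shift, max_shift + 1):
        score = float(np.dot(np.roll(det, shift), ref))
        if score > best_score:
            best_score, best_shift = score, shift
    # positive lag = detections run late relative to the reference
    return -best_shift * _BIN_MS


def match_events(
    detected: np.ndarray, reference: np.ndarray, tolerance_ms: float
) -> tuple[list[tuple[int, int]], MatchResult]:
    """Greedy one-to-one nearest matching within tolerance.

    References are visited in time order (earlier reference wins a
    contested detection), each taking its nearest unmatched detection.
    """
    detected = np.asarray(detected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    used = np.zeros(len(detected), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for j, r in enumerate(reference):
        if len(detected) == 0:
            break
        order = np.argsort(np.abs(detected - r), kind="stable")
        for i in order:
            if np.abs(detected[i] - r) > tolerance_ms:
                break
            if not used[i]:
                used[i] = True
                pairs.append((int(i), j))
                break
    tp = len(pairs)
    fp = len(detected) - tp
    fn = len(reference) - tp
    se = 100.0 * tp / len(reference) if len(reference) else float("nan")
    ppv = 100.0 * tp / len(detected) if len(detected) else float("nan")
    if len(reference) == 0 or np.isnan(se) or np.isnan(ppv) or se + ppv == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * se * ppv / (se + ppv)
    return pairs, MatchResult(TP=tp, FP=fp, FN=fn, Se=se, PPV=ppv, F1=f1)


def align_and_match(
    detected, reference, tolerance_ms: float = 150.0, max_lag_ms: float = 0.0
) -> MatchResult:
    """Align two event trains (times in ms, sorted) and score the match.

    A constant offset up to ``max_lag_ms`` between the trains is removed
    before matching, so F1 is invariant to such a shift. An empty
    reference yields F1 = 0 with a warning (sensitivity undefined).
    """
    detected = np.asarray(detected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(reference) == 0:
        log.warning("empty reference train: sensitivity undefined, F1 set to 0")
        return MatchResult(TP=0, FP=len(detected), FN=0,
                           Se=float("nan"), PPV=float("nan"), F1=0.0)
    lag = _best_lag(detected, reference, max_lag_ms)
    _, result = match_events(detected - lag, reference, tolerance_ms)
    result.lag_ms = lag
    return result


def segment_f1(
    detected, reference, tolerance_ms: float = 150.0, max_lag_ms: float = 0.0,
    segment_s: float = 600.0, min_ref_beats: int = 300,
) -> list[MatchResult]:
    """Per-segment beat scoring for long recordings.

    The record is split into fixed-length segments; segments with fewer
    than ``min_ref_beats`` reference beats are excluded. Summarize the
    returned per-segment F1 values with median and quartiles for a
    recording-level figure.
    """
    detected = np.asarray(detected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(reference) == 0:
        return []
    seg_ms = segment_s * 1000.0
    out: list[MatchResult] = []
    n_seg = int(np.ceil((reference.max() + 1) / seg_ms))
    for k in range(n_seg):
        lo, hi = k * seg_ms, (k + 1) * seg_ms
        ref_k = reference[(reference >= lo) & (reference < hi)]
        if len(ref_k) < min_ref_beats:
            continue
        det_k = detected[(detected >= lo) & (detected < hi)]
        out.append(align_and_match(det_k, ref_k, tolerance_ms, max_lag_ms))
    return out


def bland_altman_stats(differences) -> tuple[float, float, float, float]:
    """Bias, SD (n-1) and the +/-1.96 SD limits of agreement of signed
    differences; requires n >= 2."""
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) < 2:
        return (float("nan"),) * 4
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def fiducial_errors(
    detected: list[FiducialSet], annotated: list[FiducialSet], fs: float
) -> dict[str, ErrorStats]:
    """Per-point timing-error statistics between paired pulse sequences.

    ``detected`` and ``annotated`` must refer to the same pulses, in
    order. Pulses where either side lacks the point are excluded for that
    point; points with no usable pulses are omitted from the result.
    """
    if len(detected) != len(annotated):
        raise ValueError("detected and annotated must have equal length")
    out: dict[str, ErrorStats] = {}
    for point in POINT_NAMES:
        diffs = []
        for det, ann in zip(detected, annotated):
            di, ai = getattr(det, point), getattr(ann, point)
            if di is None or ai is None:
                continue
            diffs.append((di - ai) * 1000.0 / fs)
        if not diffs:
            continue
        d = np.asarray(diffs)
        bias, _, lo, hi = bland_altman_stats(d) if len(d) >= 2 else (
            float(d[0]), 0.0, float(d[0]), float(d[0]))
        out[point] = ErrorStats(
            mae=float(np.mean(np.abs(d))),
            sd_abs=float(np.std(np.abs(d), ddof=1)) if len(d) > 1 else 0.0,
            bias=float(np.mean(d)) if len(d) < 2 else bias,
            loa_low=lo, loa_high=hi, n=len(d),
        )
    return out


def error_table(stats: dict[str, ErrorStats]):
    """Error statistics as a DataFrame: one row per fiducial point."""
    import pandas as pd

    return pd.DataFrame(
        {p: {"MAE": s.mae, "SD": s.sd_abs, "bias": s.bias,
             "loa_low": s.loa_low, "loa_high": s.loa_high, "n": s.n}
         for p, s in stats.items()}
    ).T
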