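"""Fiducial-point detection on the PPG and its three derivatives.

Per pulse, the detected set is: on, sp, dn (dicrotic notch, with a
morphology class), dp (diastolic peak) and off on the PPG itself; u, v, w
on the first derivative; the alternating a-f waves on the second
derivative; and the early/late systolic landmarks p1, p2 on the third
derivative. Undetectable points are left absent rather than fabricated.

Detection follows standardized morphological definitions; an optional
correction pass enforces the expected relative ordering of the points,
recomputing the diastolic peak where possible and discarding points that
remain inconsistent.

Notch morphology classes: 1 incisura (a true local minimum), 2 a
near-horizontal plateau on the downslope, 3 a gradient change only, and
4 no discernible notch.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from ._extrema import argmax_in, argmin_in, local_maxima, local_minima, zero_crossings
from .config import PipelineConfig
from .preprocess import ProcessedSignal
from .segmentation import PulseWave, _upslope_argmax_d2

log = logging.getLogger(__name__)

__all__ = ["FiducialSet", "detect_derivative_points", "detect_dicrotic_notch",
           "detect_diastolic_peak", "correct_fiducials", "detect_fiducials"]

POINT_NAMES = ("on", "sp", "dn", "dp", "off", "u", "v", "w",
               "a", "b", "c", "d", "e", "f", "p1", "p2")


@dataclass
class FiducialSet:
    """Per-pulse fiducial sample indices (analysis rate); absent = None."""

    on: int | None = None
    sp: int | None = None
    dn: int | None = None
    dp: int | None = None
    off: int | None = None
    u: int | None = None
    v: int | None = None
    w: int | None = None
    a: int | None = None
    b: int | None = None
    c: int | None = None
    d: int | None = None
    e: int | None = None
    f: int | None = None
    p1: int | None = None
    p2: int | None = None
    dn_class: int | None = None
    valid: bool = True

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in POINT_NAMES}

    def time_ms(self, point: str, fs: float, from_onset: bool = False) -> float | None:
        idx = getattr(self, point)
        if idx is None:
            return None
        ref = self.on if from_onset else 0
        if from_onset and ref is None:
            return None
        return (idx - ref) * 1000.0 / fs


def _bound(pulse: PulseWave, frac: float) -> int:
    return pulse.on_idx + int(round(frac * (pulse.off_idx - pulse.on_idx)))


def detect_derivative_points(
    proc: ProcessedSignal, pulse: PulseWave, cfg: PipelineConfig | None = None
) -> FiducialSet:
    """Detect u, v, w (PPG'), a-f (PPG'') and p1, p2 (PPG''') for one pulse.

    Searches are confined to [on, off]; the e and f points additionally
    respect upper bounds of 60% and 80% of the pulse duration. Points with
    no admissible candidate are left absent.
    """
    cfg = cfg or PipelineConfig()
    on, sp, off = pulse.on_idx, pulse.sp_idx, pulse.off_idx
    fid = FiducialSet(on=on, sp=sp, off=off)
    d1, d2, d3 = proc.d1, proc.d2, proc.d3

    if np.ptp(proc.ppg[on:off + 1]) == 0:
        return fid  # flat segment: no extrema to detect

    fid.u = argmax_in(d1, on, sp)
    if fid.u is not None and np.ptp(d1[on:sp + 1]) == 0:
        fid.u = None
    fid.a = _upslope_argmax_d2(proc, on, sp)
    if fid.a is None:
        return fid
    b_list = local_minima(d2, fid.a + 1, off)
    if not b_list:
        return fid
    fid.b = b_list[0]

    e_hi = _bound(pulse, cfg.e_bound_frac)
    e_cands = local_maxima(d2, max(fid.b, sp) + 1, e_hi)
    if not e_cands:
        e_cands = local_maxima(d2, fid.b + 1, e_hi)
    if e_cands:
        fid.e = max(e_cands, key=lambda i: d2[i])

    if fid.e is not None:
        c_cands = local_maxima(d2, fid.b + 1, fid.e - 1)
        if c_cands:
            fid.c = max(c_cands, key=lambda i: d2[i])
        else:
            zc = zero_crossings(d3, fid.b + 1, fid.e - 1)
            fid.c = zc[0] if zc else None
        if fid.c is not None:
            d_cands = local_minima(d2, fid.c + 1, fid.e - 1)
            if d_cands:
                fid.d = min(d_cands, key=lambda i: d2[i])
            else:
                zc = zero_crossings(d3, fid.c + 1, fid.e - 1)
                fid.d = zc[0] if zc else None
        f_hi = _bound(pulse, cfg.f_bound_frac)
        # the f-wave is a genuine negative-curvature trough, not a ripple
        # in the near-flat diastolic tail
        f_cands = [i for i in local_minima(d2, fid.e + 1, f_hi) if d2[i] < 0]
        if f_cands:
            fid.f = f_cands[0]

    p1_cands = local_maxima(d3, fid.b + 1, off)
    if p1_cands:
        fid.p1 = p1_cands[0]
    if fid.d is not None:
        p2_cands = local_minima(d3, fid.b + 1, fid.d)
        # no admissible PPG''' minimum: fall back to the d-point location
        fid.p2 = p2_cands[-1] if p2_cands else fid.d

    v_hi = fid.e if fid.e is not None else _bound(pulse, cfg.f_bound_frac)
    if fid.u is not None and v_hi > fid.u:
        fid.v = argmin_in(d1, fid.u, v_hi)
    if fid.v is not None and fid.e is not None:
        w_hi = fid.f if fid.f is not None else _bound(pulse, cfg.f_bound_frac)
        w_cands = local_maxima(d1, max(fid.e, fid.v) + 1, w_hi)
        if w_cands:
            fid.w = w_cands[0]
    return fid


def detect_dicrotic_notch(
    proc: ProcessedSignal, pulse: PulseWave, partial: FiducialSet,
    cfg: PipelineConfig | None = None,
) -> FiducialSet:
    """Locate the dicrotic notch and assign its morphology class.

    A clear local minimum of the PPG between the systolic peak and the
    diastolic-peak search bound is the class-1 notch. Otherwise the
    alternative estimate — the rising zero-crossing of PPG'' between the
    d and e points — is used (class 2 when the local slope is nearly
    flat, class 3 for a plain gradient change). When the minimum and the
    derivative estimate disagree by more than 100 ms, the minimum is
    substituted (disable via ``notch_min_substitution`` for single-pulse
    analysis). With neither available, the notch is absent (class 4).
    """
    cfg = cfg or PipelineConfig()
    fid = replace(partial)
    sp, hi = pulse.sp_idx, _bound(pulse, cfg.dp_bound_frac)
    # a class-1 notch is a minimum followed by a diastolic rebound; a bare
    # trough running into the next upslope is not an incisura
    asp = proc.ppg[sp] - proc.ppg[pulse.on_idx]
    m = None
    for cand in local_minima(proc.ppg, sp + 1, hi):
        rebounds = local_maxima(proc.ppg, cand + 1, hi)
        if rebounds and proc.ppg[rebounds[0]] - proc.ppg[cand] >= 0.005 * asp:
            m = cand
            break
    primary = None
    if fid.e is not None and fid.f is not None:
        # inflection on the downslope: PPG'' zero-crossing between the
        # d-wave (or the systolic region when d is absent) and the e-wave.
        # Requiring the f-wave distinguishes a genuine notch inflection
        # from the generic inflection of a bare monotone decay.
        z_lo = fid.d if fid.d is not None else max(fid.b or sp, sp)
        if fid.e > z_lo:
            zc = zero_crossings(proc.d2, z_lo, fid.e, direction="rising")
            primary = zc[0] if zc else None

    subst_ms = 100.0
    if m is not None and primary is not None:
        far = abs(m - primary) * 1000.0 / proc.fs > subst_ms
        if far and cfg.notch_min_substitution:
            fid.dn, fid.dn_class = m, 1
        elif not far:
            # both estimates agree on an incisura morphology
            fid.dn, fid.dn_class = m, 1
        else:
            fid.dn, fid.dn_class = primary, _slope_class(proc, pulse, primary)
    elif m is not None:
        fid.dn, fid.dn_class = m, 1
    elif primary is not None:
        fid.dn, fid.dn_class = primary, _slope_class(proc, pulse, primary)
    else:
        fid.dn, fid.dn_class = None, 4
    return fid


def _slope_class(proc: ProcessedSignal, pulse: PulseWave, dn: int) -> int:
    scale = max(abs(proc.d1[pulse.on_idx:pulse.off_idx + 1].max()),
                abs(proc.d1[pulse.on_idx:pulse.off_idx + 1].min()))
    return 2 if abs(proc.d1[dn]) < 0.02 * scale else 3


def detect_diastolic_peak(
    proc: ProcessedSignal, pulse: PulseWave, partial: FiducialSet,
    cfg: PipelineConfig | None = None,
) -> FiducialSet:
    """First local PPG maximum after the notch (fallback: after the e-point)
    and before 0.8 of the pulse interval; absent when no maximum exists."""
    cfg = cfg or PipelineConfig()
    fid = replace(partial)
    hi = _bound(pulse, cfg.dp_bound_frac)
    start = fid.dn if fid.dn is not None else fid.e
    fid.dp = None
    asp = proc.ppg[pulse.sp_idx] - proc.ppg[pulse.on_idx]

    def first_prominent(lo: int) -> int | None:
        # demand a meaningful rise over the preceding trough so diastolic
        # tail ripple is not mistaken for a reflection peak
        for cand in local_maxima(proc.ppg, lo + 1, hi):
            base = float(np.min(proc.ppg[lo:cand + 1]))
            if proc.ppg[cand] - base >= 0.005 * asp:
                return cand
        return None

    if start is not None:
        fid.dp = first_prominent(start)
        if fid.dp is None and fid.e is not None and fid.e != start:
            fid.dp = first_prominent(fid.e)
    return fid


def _drop(fid: FiducialSet, name: str, why: str) -> None:
    log.info("correction: dropping %s (%s)", name, why)
    setattr(fid, name, None)


def correct_fiducials(
    fiducials: list[FiducialSet], enabled: bool = True,
    proc: ProcessedSignal | None = None, pulses: list[PulseWave] | None = None,
    cfg: PipelineConfig | None = None,
) -> list[FiducialSet]:
    """Enforce the expected relative ordering of the fiducial points.

    Each point appears at most once per pulse by construction; here,
    points violating the ordering invariants (on <= u <= sp, a < b <= e <
    f, sp <= dn <= dp <= off) are discarded, except the diastolic peak
    which is first recomputed from the corrected notch/e/off when the
    signal is available. With ``enabled=False`` detections pass through
    untouched. Idempotent on consistent sets.
    """
    if not enabled:
        return fiducials
    cfg = cfg or PipelineConfig()
    out: list[FiducialSet] = []
    for i, fid in enumerate(fiducials):
        fid = replace(fid)
        on, sp, off = fid.on, fid.sp, fid.off
        if fid.u is not None and not (on <= fid.u <= sp):
            _drop(fid, "u", "outside [on, sp]")
        if fid.a is not None and not (on <= fid.a <= sp):
            _drop(fid, "a", "outside [on, sp]")
        if fid.b is not None and (fid.a is None or not fid.a < fid.b):
            _drop(fid, "b", "not after a")
        if fid.e is not None and (fid.b is None or not fid.b <= fid.e):
            _drop(fid, "e", "not after b")
        if fid.f is not None and (fid.e is None or not fid.e < fid.f):
            _drop(fid, "f", "not after e")
        for name in ("c", "d"):
            val = getattr(fid, name)
            if val is not None and (fid.b is None or fid.e is None
                                    or not (fid.b <= val <= fid.e)):
                _drop(fid, name, "outside [b, e]")
        if fid.dn is not None and not (sp <= fid.dn <= off):
            _drop(fid, "dn", "outside [sp, off]")
            fid.dn_class = 4
        if fid.dp is not None and (fid.dn is not None and not fid.dn <= fid.dp <= off):
            if proc is not None and pulses is not None:
                fid = detect_diastolic_peak(proc, pulses[i], fid, cfg)
            if fid.dp is not None and fid.dn is not None and not fid.dn <= fid.dp <= off:
                _drop(fid, "dp", "still before dn after recomputation")
        for name in ("v", "w", "p1", "p2"):
            val = getattr(fid, name)
            if val is not None and not (on <= val <= off):
                _drop(fid, name, "outside pulse")
        out.append(fid)
    return out


def detect_fiducials(
    proc: ProcessedSignal, pulses: list[PulseWave], cfg: PipelineConfig | None = None
) -> list[FiducialSet]:
    """Full fiducial detection for a sequence of segmented pulses.

    Runs the derivative-point, notch and diastolic-peak detectors per
    pulse, applies the optional correction pass, and flags pulses whose
    systolic (onset to notch) or diastolic (notch to offset) durations
    fall below the physiological minima (120 / 300 ms by default).
    """
    cfg = cfg or PipelineConfig()
    sets: list[FiducialSet] = []
    for pulse in pulses:
        fid = detect_derivative_points(proc, pulse, cfg)
        fid = detect_dicrotic_notch(proc, pulse, fid, cfg)
        fid = detect_diastolic_peak(proc, pulse, fid, cfg)
        sets.append(fid)
    sets = correct_fiducials(sets, cfg.correction, proc, pulses, cfg)
    for pulse, fid in zip(pulses, sets):
        if fid.dn is not None:
            t_sys = (fid.dn - pulse.on_idx) * 1000.0 / proc.fs
            t_dia = (pulse.off_idx - fid.dn) * 1000.0 / proc.fs
            if t_sys < cfg.min_systolic_ms or t_dia < cfg.min_diastolic_ms:
                pulse.valid = False
                fid.valid = False
    return sets
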