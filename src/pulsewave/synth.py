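"""Synthetic PPG generation with analytic ground-truth fiducial points.

Each beat is modelled as the sum of a systolic and a diastolic Gaussian
wave on the beat's period grid. Because every derivative of a Gaussian has
a closed form (Hermite polynomials), all fiducial landmarks of the
continuous, noise-free model — extrema and zero-crossings of the signal
and its first three derivatives — can be located to arbitrary precision
by bracketed root-finding. This gives exact ground truth for testing the
discrete pipeline without any recorded data.

The generator emulates a clean fingertip pulse morphology (sharp systolic
upstroke, dicrotic notch, diastolic wave), optionally with baseline
wander, inter-beat-interval jitter and additive white noise. It is not a
physiological simulator: there are no motion artifacts, arrhythmias or
waveform non-stationarities beyond those knobs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .config import ConfigError
from .io import RawSignal

__all__ = ["SynthConfig", "SynthGroundTruth", "generate_synthetic_ppg"]

# probabilists' Hermite polynomials He_n for Gaussian derivatives:
# d^n/dt^n exp(-x^2/2) = (-1)^n He_n(x) exp(-x^2/2) / sigma^n, x=(t-mu)/sigma
_HERMITE = (
    lambda x: np.ones_like(x),
    lambda x: x,
    lambda x: x * x - 1.0,
    lambda x: x ** 3 - 3.0 * x,
    lambda x: x ** 4 - 6.0 * x * x + 3.0,
)


@dataclass
class SynthConfig:
    """Parameters of the two-Gaussian beat model.

    ``sys_mu``/``dia_mu`` and the sigmas are fractions of the beat period;
    amplitudes are arbitrary units. Defaults describe a clean adult
    fingertip pulse at rest: systolic peak ~30% into the cycle, a
    diastolic wave of ~35% relative amplitude at ~62%.
    """

    hr: float = 60.0
    duration: float = 30.0
    fs: float = 250.0
    sys_amp: float = 1.0
    sys_mu: float = 0.30
    sys_sigma: float = 0.10
    dia_amp: float = 0.40
    dia_mu: float = 0.70
    dia_sigma: float = 0.07
    #: late-systolic reflection wave; produces the c/d waves of the second
    #: derivative and the late-systolic p2 landmark seen in fingertip PPG
    ref_amp: float = 0.20
    ref_mu: float = 0.46
    ref_sigma: float = 0.055
    baseline_amp: float = 0.0
    baseline_freq: float = 0.25
    noise_snr_db: float | None = None
    hr_jitter_pct: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (30.0 <= self.hr <= 200.0):
            raise ConfigError("hr must be within [30, 200] bpm")
        if self.dia_mu <= self.sys_mu:
            raise ConfigError("dia_mu must exceed sys_mu")
        if self.sys_amp < 0 or self.dia_amp < 0:
            raise ConfigError("amplitudes must be >= 0")
        if self.duration <= 0 or self.fs <= 0:
            raise ConfigError("duration and fs must be > 0")


@dataclass
class SynthGroundTruth:
    """Per-beat ground-truth landmark times (ms from signal start).

    ``beats`` holds one dict per beat mapping point name (on, sp, dn, dp,
    off, u, v, w, a..f, p1, p2) to a time in ms, plus ``dn_class``. Points
    the continuous model does not exhibit are missing from the dict.
    """

    beats: list[dict] = field(default_factory=list)
    periods_ms: list[float] = field(default_factory=list)

    def times_ms(self, point: str) -> np.ndarray:
        return np.asarray(
            [b[point] for b in self.beats if point in b], dtype=float
        )

    @property
    def n_beats(self) -> int:
        return len(self.beats)


class _BeatTrain:
    """Continuous model: sum of Gaussian pairs over all beats."""

    def __init__(self, starts: np.ndarray, periods: np.ndarray, cfg: SynthConfig):
        self.cfg = cfg
        # (amp, mu, sigma) per Gaussian, absolute seconds
        params = []
        for t0, T in zip(starts, periods):
            params.append((cfg.sys_amp, t0 + cfg.sys_mu * T, cfg.sys_sigma * T))
            if cfg.ref_amp > 0:
                params.append((cfg.ref_amp, t0 + cfg.ref_mu * T, cfg.ref_sigma * T))
            if cfg.dia_amp > 0:
                params.append((cfg.dia_amp, t0 + cfg.dia_mu * T, cfg.dia_sigma * T))
        self.params = params

    def deriv(self, order: int) -> Callable[[np.ndarray], np.ndarray]:
        hermite = _HERMITE[order]
        sign = (-1.0) ** order
        params = self.params

        def f_vec(t: np.ndarray) -> np.ndarray:
            out = np.zeros_like(t)
            if len(t) == 0:
                return out
            t_lo, t_hi = t.min(), t.max()
            for amp, mu, sig in params:
                if mu + 9.0 * sig < t_lo or mu - 9.0 * sig > t_hi:
                    continue  # contributes < 1e-17 everywhere in the window
                x = (t - mu) / sig
                mask = np.abs(x) < 9.0
                xm = x[mask]
                out[mask] += amp * sign * hermite(xm) * np.exp(-xm * xm / 2) / sig ** order
            return out

        def f(t):
            if np.ndim(t) == 0:
                return float(f_vec(np.asarray([t], dtype=float))[0])
            return f_vec(np.asarray(t, dtype=float))

        return f


# --- continuous-model landmark search -------------------------------------

_GRID_HZ = 10_000.0


def _refine(f: Callable, lo: float, hi: float) -> float:
    try:
        return brentq(f, lo, hi, xtol=1e-7)
    except ValueError:
        return 0.5 * (lo + hi)


def _extrema(train: _BeatTrain, order: int, lo: float, hi: float,
             kind: str) -> list[float]:
    """Local maxima ('max') or minima ('min') of derivative ``order`` in
    (lo, hi), via sign changes of the next derivative."""
    if hi - lo <= 2.0 / _GRID_HZ:
        return []
    nxt = train.deriv(order + 1)
    t = np.arange(lo, hi, 1.0 / _GRID_HZ)
    if len(t) < 3:
        return []
    y = nxt(t)
    out = []
    sign = np.sign(y)
    for i in np.nonzero(np.diff(sign) != 0)[0]:
        if sign[i] == 0:
            continue
        falling = sign[i] > 0
        if (kind == "max") == falling:
            out.append(_refine(nxt, t[i], t[i + 1]))
    return out


def _zero_crossings(train: _BeatTrain, order: int, lo: float, hi: float) -> list[float]:
    f = train.deriv(order)
    t = np.arange(lo, hi, 1.0 / _GRID_HZ)
    if len(t) < 3:
        return []
    y = f(t)
    sign = np.sign(y)
    return [_refine(f, t[i], t[i + 1]) for i in np.nonzero(np.diff(sign) != 0)[0] if sign[i] != 0]


def _argext(train: _BeatTrain, order: int, lo: float, hi: float, kind: str) -> float | None:
    cands = _extrema(train, order, lo, hi, kind)
    if not cands:
        return None
    f = train.deriv(order)
    vals = [f(c) for c in cands]
    i = int(np.argmax(vals)) if kind == "max" else int(np.argmin(vals))
    return cands[i]


def _beat_landmarks(train: _BeatTrain, sp: float, prev_sp: float | None,
                    next_on_hint: float | None, T: float, cfg: SynthConfig) -> dict:
    """Apply the morphological landmark definitions to the continuous model
    for the beat whose systolic peak is at ``sp`` (seconds)."""
    s0, s1, s2, s3 = (train.deriv(k) for k in range(4))
    lm: dict = {"sp": sp}
    lo = prev_sp if prev_sp is not None else sp - 0.75 * T
    # provisional systolic-phase window anchored at the inter-beat PPG
    # minimum: keeps the previous beat's diastolic wave (whose curvature
    # can rival the systolic a-wave) out of the a/b search
    grid = np.arange(max(lo, sp - 0.75 * T), sp, 1.0 / _GRID_HZ)
    w_lo = float(grid[np.argmin(s0(grid))]) if len(grid) else sp - 0.5 * T

    def upslope_a(a_lo: float, a_hi: float) -> float | None:
        # the a-wave lies on the rising systolic edge (PPG' > 0)
        cands = [x for x in _extrema(train, 2, a_lo, a_hi, "max") if s1(x) > 0]
        if not cands:
            return None
        return max(cands, key=s2)

    a = upslope_a(w_lo, sp)
    if a is None:
        return lm
    b_cands = _extrema(train, 2, a, sp + 0.5 * T, "min")
    if not b_cands:
        return lm
    b = b_cands[0]
    p1_cands = _extrema(train, 3, b, sp + 0.5 * T, "max")
    p1 = p1_cands[0] if p1_cands else None
    # onset: nearest local max of PPG''' at or before p1, starting just
    # before the inter-beat minimum
    if p1 is not None:
        on_cands = _extrema(train, 3, w_lo - 0.05 * T, p1 + 1e-6, "max")
        on = on_cands[-1] if on_cands else None
    else:
        on = None
    if on is None:
        mins = _extrema(train, 0, w_lo, sp, "min")
        on = mins[-1] if mins else w_lo
    lm["on"] = on
    # refine systolic points inside [on, sp]
    u = _argext(train, 1, on, sp, "max")
    a2 = upslope_a(on, sp)
    if a2 is not None:
        a = a2
    lm.update({k: v for k, v in (("u", u), ("a", a), ("b", b), ("p1", p1)) if v is not None})

    off = next_on_hint if next_on_hint is not None else on + T
    dur = off - on
    lm["off"] = off
    # e: highest local max of PPG'' in [sp, on + 0.6 dur]
    e = _argext(train, 2, max(b, sp), on + 0.6 * dur, "max")
    if e is not None:
        lm["e"] = e
        c = _argext(train, 2, b + 1e-6, e - 1e-6, "max")
        if c is None:
            zc = _zero_crossings(train, 3, b + 1e-6, e - 1e-6)
            c = zc[0] if zc else None
        if c is not None:
            lm["c"] = c
            d = _argext(train, 2, c + 1e-6, e - 1e-6, "min")
            if d is None:
                zc = _zero_crossings(train, 3, c + 1e-6, e - 1e-6)
                d = zc[0] if zc else None
            if d is not None:
                lm["d"] = d
        f_cands = [x for x in _extrema(train, 2, e, on + 0.8 * dur, "min")
                   if s2(x) < 0]
        if f_cands:
            lm["f"] = f_cands[0]
    # p2: last local min of PPG''' in (b, d); fallback: d
    if "d" in lm:
        p2_cands = _extrema(train, 3, b, lm["d"], "min")
        lm["p2"] = p2_cands[-1] if p2_cands else lm["d"]
    # dicrotic notch and diastolic peak; a class-1 notch is a minimum
    # followed by a diastolic rebound, not a bare inter-beat trough
    dn = None
    dn_class = 4
    asp = s0(sp) - s0(on)
    for cand in _extrema(train, 0, sp, on + 0.8 * dur, "min"):
        rebounds = _extrema(train, 0, cand, on + 0.8 * dur, "max")
        if rebounds and s0(rebounds[0]) - s0(cand) >= 0.005 * asp:
            dn = cand
            dn_class = 1
            break
    if dn is None and "e" in lm and "f" in lm:
        z_lo = lm.get("d", max(b, sp))
        zc = [x for x in _zero_crossings(train, 2, z_lo, lm["e"])
              if s3(x) > 0]
        if zc:
            dn = zc[0]
            slope_scale = abs(s1(u)) if u is not None else 1.0
            dn_class = 2 if abs(s1(dn)) < 0.02 * slope_scale else 3
    if dn is not None:
        lm["dn"] = dn
    lm["dn_class"] = dn_class
    # dp: first local max of PPG after dn (else after e) with a meaningful
    # rise over the preceding trough, before on + 0.8 dur
    start = dn if dn is not None else lm.get("e")
    if start is not None:
        for cand in _extrema(train, 0, start, on + 0.8 * dur, "max"):
            mins = _extrema(train, 0, start, cand, "min")
            base = min((s0(x) for x in mins), default=s0(start))
            if s0(cand) - base >= 0.005 * asp:
                lm["dp"] = cand
                break
    # v: minimum of PPG' between u and e; w: first local max of PPG' after
    # max(e, v) and before f
    if u is not None and "e" in lm:
        v = _argext(train, 1, u, lm["e"], "min")
        if v is not None:
            lm["v"] = v
            w_hi = lm.get("f", on + 0.8 * dur)
            w_cands = _extrema(train, 1, max(lm["e"], v), w_hi, "max")
            if w_cands:
                lm["w"] = w_cands[0]
    return lm


def generate_synthetic_ppg(
    cfg: SynthConfig, points: str = "all"
) -> tuple[RawSignal, SynthGroundTruth]:
    """Generate a synthetic PPG record and its continuous-model ground truth.

    Returns the sampled raw signal (with baseline wander and noise, if
    configured) and the noise-free ground-truth landmark times. Identical
    configs (including seed) produce bitwise-identical output.

    ``points="sp"`` computes only the systolic-peak ground truth (exact
    maxima of the continuous model), which is much faster for long
    beat-detection studies; ``"all"`` runs the full landmark search.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    T0 = 60.0 / cfg.hr
    # beat periods with optional jitter, filling the duration
    periods = []
    total = 0.0
    while total < cfg.duration + T0:
        T = T0
        if cfg.hr_jitter_pct > 0:
            T = T0 * (1.0 + cfg.hr_jitter_pct / 100.0 * rng.standard_normal())
            T = float(np.clip(T, 0.5 * T0, 1.5 * T0))
        periods.append(T)
        total += T
    starts = np.concatenate([[0.0], np.cumsum(periods)[:-1]])
    periods = np.asarray(periods)

    train = _BeatTrain(starts, periods, cfg)
    t = np.arange(int(round(cfg.duration * cfg.fs))) / cfg.fs
    clean = train.deriv(0)(t)
    samples = clean.copy()
    if cfg.baseline_amp > 0:
        samples = samples + cfg.baseline_amp * np.sin(2 * np.pi * cfg.baseline_freq * t)
    if cfg.noise_snr_db is not None:
        p_sig = float(np.var(clean))
        sigma = np.sqrt(p_sig / 10 ** (cfg.noise_snr_db / 10.0))
        samples = samples + sigma * rng.standard_normal(len(t))

    gt = SynthGroundTruth()
    # ground truth only for beats fully inside the record
    sps = starts + cfg.sys_mu * periods
    raw = RawSignal(samples=samples, fs=cfg.fs,
                    source=f"synthetic(hr={cfg.hr},seed={cfg.seed})")
    if points == "sp":
        s1 = train.deriv(1)
        for k, sp0 in enumerate(sps):
            if sp0 >= cfg.duration - 0.25 * periods[k]:
                break
            # the true peak of the summed model sits within a fraction of
            # sigma of the systolic Gaussian center
            half = 0.5 * cfg.sys_sigma * periods[k]
            try:
                sp = brentq(s1, sp0 - half, sp0 + half, xtol=1e-7)
            except ValueError:
                sp = sp0
            gt.beats.append({"sp": sp * 1000.0, "dn_class": 0})
        gt.periods_ms = [p * 1000.0 for p in periods[: len(gt.beats)]]
        return raw, gt
    landmarks: list[dict] = []
    for k, sp in enumerate(sps):
        if sp >= cfg.duration - 0.25 * periods[k]:
            break
        prev_sp = sps[k - 1] if k > 0 else None
        lm = _beat_landmarks(train, sp, prev_sp, None, periods[k], cfg)
        landmarks.append(lm)
    # offsets: the next beat's onset (recompute dependent points with it)
    final: list[dict] = []
    for k, lm in enumerate(landmarks):
        if k + 1 < len(landmarks) and "on" in landmarks[k + 1] and "on" in lm:
            lm = _beat_landmarks(
                train, lm["sp"], sps[k - 1] if k > 0 else None,
                landmarks[k + 1]["on"], periods[k], cfg,
            )
            if lm.get("off") is not None and lm.get("off", 0) * cfg.fs < len(t):
                final.append(lm)
    for lm in final:
        beat = {"dn_class": lm.pop("dn_class", 4)}
        beat.update({k: v * 1000.0 for k, v in lm.items()})
        gt.beats.append(beat)
    gt.periods_ms = [p * 1000.0 for p in periods[: len(final)]]
    return raw, gt


def morphology_grid(
    sys_sigmas=(0.05, 0.10, 0.15), dia_amps=(0.0, 0.3, 0.6), **overrides
) -> list[SynthConfig]:
    """The morphology grid used for fiducial-recovery testing."""
    base = SynthConfig(**overrides)
    grid = []
    for ss in sys_sigmas:
        for da in dia_amps:
            grid.append(replace(base, sys_sigma=ss, dia_amp=da))
    return grid
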