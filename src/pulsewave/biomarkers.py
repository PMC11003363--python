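"""Morphological biomarker engineering from detected fiducial points.

74 per-beat biomarkers in four categories — PPG Signal (17), Signal
Ratios (12), PPG Derivatives (15) and Derivatives Ratios (30) — plus nine
summary statistics per biomarker over a window of beats.

Conventions: all PPG amplitudes (Asp, Adn, Adp, Aoff, and the PPG values
entering AI/RI ratios) are measured relative to the amplitude at the
pulse onset; derivative amplitudes (Au..Af, Ap1, Ap2) are read off the
respective derivative series at the point's sample, in derivative units.
Times are milliseconds; areas are trapezoidal integrals of the
onset-relative pulse in amplitude*ms. A biomarker whose required fiducial
points are absent — or whose denominator is zero — is absent (NaN), never
zero.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .fiducials import FiducialSet
from .preprocess import ProcessedSignal

log = logging.getLogger(__name__)

__all__ = ["biomarker_names", "pulse_width_at_x", "compute_beat_biomarkers",
           "compute_biomarkers", "summarize_biomarkers", "SUMMARY_STATS"]

SUMMARY_STATS = ("AVG", "MED", "SD", "Q1", "Q3", "IQR", "SKW", "KUR", "MAD")


def biomarker_names(x: float = 50.0) -> list[str]:
    """The 74 biomarker column names (17 + 12 + 15 + 30) at width level x%."""
    xs = f"{x:g}"
    sig = ["Tpi", "Tpp", "Tsys", "Tdia", "Tsp", "Tdp", "dT",
           f"Tsw{xs}", f"Tdw{xs}", f"Tpw{xs}",
           "Asp", "Adn", "Adp", "Aoff", "AUCpi", "AUCsys", "AUCdia"]
    ratios = ["IPR", "Tsys/Tdia", f"Tpw{xs}/Tpi", f"Tpw{xs}/Tsp", f"Tdw{xs}/Tsw{xs}",
              "Tsp/Tpi", "Asp/Aoff", "Adp/Asp", "IPA", "Tsp/Asp", "Asp/dT",
              "Asp/(Tpi-Tsp)"]
    deriv = ["Tu", "Tv", "Tw", "Ta", "Tb", "Tc", "Td", "Te", "Tf",
             "Tb-c", "Tb-d", "Tp1", "Tp2", "Tp1-dp", "Tp2-dp"]
    dratios = ["Tu/Tpi", "Tv/Tpi", "Tw/Tpi", "Ta/Tpi", "Tb/Tpi", "Tc/Tpi",
               "Td/Tpi", "Te/Tpi", "Tf/Tpi", "(Tu-Ta)/Tpi", "(Tv-Tb)/Tpi",
               "Au/Asp", "Av/Au", "Aw/Au", "Ab/Aa", "Ac/Aa", "Ad/Aa", "Ae/Aa",
               "Af/Aa", "Ap2/Ap1", "(Ac-Ab)/Aa", "(Ad-Ab)/Aa",
               "AGI", "AGImod", "AGIinf", "AI", "RIp1", "RIp2", "SC", "IPAD"]
    return sig + ratios + deriv + dratios


BIOMARKER_CATEGORIES = {
    "PPG Signal": slice(0, 17),
    "Signal Ratios": slice(17, 29),
    "PPG Derivatives": slice(29, 44),
    "Derivatives Ratios": slice(44, 74),
}


def _cross_time(ppg: np.ndarray, i: int, level: float) -> float:
    """Sub-sample crossing position between samples i and i+1."""
    lo, hi = ppg[i], ppg[i + 1]
    if hi == lo:
        return float(i)
    return i + (level - lo) / (hi - lo)


def pulse_width_at_x(
    ppg: np.ndarray, fid: FiducialSet, x: float, fs: float
) -> tuple[float, float, float]:
    """Systolic, diastolic and total pulse width (ms) at x% of Asp.

    The threshold level is the onset amplitude plus x% of the systolic
    peak amplitude; crossing times on the upslope (onset to peak) and
    downslope (peak to offset) are found by linear interpolation. A side
    whose level is never crossed yields NaN for that width.
    """
    on, sp, off = fid.on, fid.sp, fid.off
    if None in (on, sp, off) or not (0 <= x <= 100):
        return math.nan, math.nan, math.nan
    base = ppg[on]
    level = base + x / 100.0 * (ppg[sp] - base)
    tsw = math.nan
    for i in range(sp - 1, on - 1, -1):
        if (ppg[i] - level) * (ppg[i + 1] - level) <= 0 and ppg[i] <= level:
            tsw = (sp - _cross_time(ppg, i, level)) * 1000.0 / fs
            break
    tdw = math.nan
    for i in range(sp, off):
        if (ppg[i] - level) * (ppg[i + 1] - level) <= 0 and ppg[i + 1] <= level:
            tdw = (_cross_time(ppg, i, level) - sp) * 1000.0 / fs
            break
    tpw = tsw + tdw if not (math.isnan(tsw) or math.isnan(tdw)) else math.nan
    return tsw, tdw, tpw


def _ratio(num: float, den: float) -> float:
    if math.isnan(num) or math.isnan(den) or den == 0:
        return math.nan
    return num / den


def compute_beat_biomarkers(
    proc: ProcessedSignal, fid: FiducialSet, next_fid: FiducialSet | None = None,
    cfg: PipelineConfig | None = None, x: float = 50.0,
) -> dict[str, float]:
    """All 74 biomarkers for one pulse; absent values are NaN.

    ``next_fid`` supplies the next pulse's systolic peak for the
    peak-to-peak interval Tpp.
    """
    cfg = cfg or PipelineConfig()
    fs = proc.fs
    ppg = proc.ppg
    ms = 1000.0 / fs
    nan = math.nan

    def t(point: str) -> float:
        idx = getattr(fid, point)
        return nan if idx is None or fid.on is None else (idx - fid.on) * ms

    def amp(point: str, series: np.ndarray, relative: bool = False) -> float:
        idx = getattr(fid, point)
        if idx is None:
            return nan
        val = float(series[idx])
        return val - float(series[fid.on]) if relative else val

    out: dict[str, float] = {}
    tpi, tsp, tdp = t("off"), t("sp"), t("dp")
    out["Tpi"] = tpi
    out["Tpp"] = (
        (next_fid.sp - fid.sp) * ms
        if next_fid is not None and next_fid.sp is not None and fid.sp is not None
        else nan
    )
    out["Tsys"], out["Tdia"] = t("dn"), tpi - t("dn") if not math.isnan(t("dn")) else nan
    out["Tsp"], out["Tdp"] = tsp, tdp
    out["dT"] = tdp - tsp if not (math.isnan(tdp) or math.isnan(tsp)) else nan
    xs = f"{x:g}"
    tsw, tdw, tpw = pulse_width_at_x(ppg, fid, x, fs)
    out[f"Tsw{xs}"], out[f"Tdw{xs}"], out[f"Tpw{xs}"] = tsw, tdw, tpw

    asp = amp("sp", ppg, relative=True)
    adn = amp("dn", ppg, relative=True)
    adp = amp("dp", ppg, relative=True)
    aoff = amp("off", ppg, relative=True)
    out["Asp"], out["Adn"], out["Adp"], out["Aoff"] = asp, adn, adp, aoff

    rel = None
    if fid.on is not None and fid.off is not None:
        rel = ppg[fid.on:fid.off + 1] - ppg[fid.on]
    auc_pi = auc_sys = auc_dia = nan
    if rel is not None:
        auc_pi = float(np.trapezoid(rel, dx=ms))
        if fid.dn is not None:
            k = fid.dn - fid.on
            auc_sys = float(np.trapezoid(rel[:k + 1], dx=ms))
            auc_dia = float(np.trapezoid(rel[k:], dx=ms))
    out["AUCpi"], out["AUCsys"], out["AUCdia"] = auc_pi, auc_sys, auc_dia

    out["IPR"] = _ratio(60000.0, tpi)  # bpm from a ms interval
    out["Tsys/Tdia"] = _ratio(out["Tsys"], out["Tdia"])
    out[f"Tpw{xs}/Tpi"] = _ratio(tpw, tpi)
    out[f"Tpw{xs}/Tsp"] = _ratio(tpw, tsp)
    out[f"Tdw{xs}/Tsw{xs}"] = _ratio(tdw, tsw)
    out["Tsp/Tpi"] = _ratio(tsp, tpi)
    out["Asp/Aoff"] = _ratio(asp, aoff)
    out["Adp/Asp"] = _ratio(adp, asp)
    out["IPA"] = _ratio(auc_dia, auc_sys)
    out["Tsp/Asp"] = _ratio(tsp, asp)
    out["Asp/dT"] = _ratio(asp, out["dT"])
    out["Asp/(Tpi-Tsp)"] = _ratio(asp, tpi - tsp)

    for name, point in (("Tu", "u"), ("Tv", "v"), ("Tw", "w"), ("Ta", "a"),
                        ("Tb", "b"), ("Tc", "c"), ("Td", "d"), ("Te", "e"),
                        ("Tf", "f"), ("Tp1", "p1"), ("Tp2", "p2")):
        out[name] = t(point)
    out["Tb-c"] = out["Tc"] - out["Tb"]
    out["Tb-d"] = out["Td"] - out["Tb"]
    out["Tp1-dp"] = tdp - out["Tp1"]
    out["Tp2-dp"] = tdp - out["Tp2"]

    for name in ("Tu", "Tv", "Tw", "Ta", "Tb", "Tc", "Td", "Te", "Tf"):
        out[f"{name}/Tpi"] = _ratio(out[name], tpi)
    out["(Tu-Ta)/Tpi"] = _ratio(out["Tu"] - out["Ta"], tpi)
    out["(Tv-Tb)/Tpi"] = _ratio(out["Tv"] - out["Tb"], tpi)

    au, av, aw = amp("u", proc.d1), amp("v", proc.d1), amp("w", proc.d1)
    aa, ab = amp("a", proc.d2), amp("b", proc.d2)
    ac, ad = amp("c", proc.d2), amp("d", proc.d2)
    ae, af = amp("e", proc.d2), amp("f", proc.d2)
    ap1, ap2 = amp("p1", proc.d3), amp("p2", proc.d3)
    out["Au/Asp"] = _ratio(au, asp)
    out["Av/Au"] = _ratio(av, au)
    out["Aw/Au"] = _ratio(aw, au)
    out["Ab/Aa"] = _ratio(ab, aa)
    out["Ac/Aa"] = _ratio(ac, aa)
    out["Ad/Aa"] = _ratio(ad, aa)
    out["Ae/Aa"] = _ratio(ae, aa)
    out["Af/Aa"] = _ratio(af, aa)
    out["Ap2/Ap1"] = _ratio(ap2, ap1)
    out["(Ac-Ab)/Aa"] = _ratio(ac - ab, aa)
    out["(Ad-Ab)/Aa"] = _ratio(ad - ab, aa)
    out["AGI"] = _ratio(ab - ac - ad - ae, aa)
    out["AGImod"] = _ratio(ab - ac - ad, aa)
    out["AGIinf"] = _ratio(ab - ae, aa)
    out["AI"] = _ratio(amp("p2", ppg, relative=True) - amp("p1", ppg, relative=True), asp)
    out["RIp1"] = _ratio(adp, amp("p1", ppg, relative=True))
    out["RIp2"] = _ratio(adp, amp("p2", ppg, relative=True))
    sc_den = _ratio(asp - au, asp)
    out["SC"] = _ratio(amp("sp", proc.d2), sc_den)
    out["IPAD"] = (out["IPA"] + out["Ad/Aa"]
                   if not (math.isnan(out["IPA"]) or math.isnan(out["Ad/Aa"]))
                   else math.nan)
    return out


def compute_biomarkers(
    proc: ProcessedSignal, fiducials: list[FiducialSet],
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-beat biomarker matrix and its summary table for a pulse sequence.

    Pulses flagged invalid (duration-constraint violations) are excluded.
    One triple of width biomarkers is produced per configured width
    percentage; the canonical 74-biomarker set corresponds to a single
    width level (the default 50%).
    """
    cfg = cfg or PipelineConfig()
    xs = cfg.width_percents or (50.0,)
    rows = []
    for i, fid in enumerate(fiducials):
        if not fid.valid:
            continue
        nxt = fiducials[i + 1] if i + 1 < len(fiducials) else None
        row = compute_beat_biomarkers(proc, fid, nxt, cfg, x=xs[0])
        for extra_x in xs[1:]:
            tsw, tdw, tpw = pulse_width_at_x(proc.ppg, fid, extra_x, proc.fs)
            g = f"{extra_x:g}"
            row[f"Tsw{g}"], row[f"Tdw{g}"], row[f"Tpw{g}"] = tsw, tdw, tpw
        rows.append(row)
    columns = biomarker_names(xs[0])
    for extra_x in xs[1:]:
        g = f"{extra_x:g}"
        columns += [f"Tsw{g}", f"Tdw{g}", f"Tpw{g}"]
    per_beat = pd.DataFrame(rows, columns=columns)
    return per_beat, summarize_biomarkers(per_beat)


def summarize_biomarkers(per_beat: pd.DataFrame) -> pd.DataFrame:
    """Nine summary statistics per biomarker over the window of beats.

    AVG/MED/SD (n-1 denominator), Q1/Q3 (linear-interpolation quartiles),
    IQR, adjusted Fisher-Pearson skewness, excess kurtosis, and MAD (mean
    absolute deviation from the mean). Statistics are computed over the
    non-absent values of each biomarker; all-absent biomarkers are
    omitted from the table. Degenerate (zero-variance) columns report
    SKW = KUR = 0.
    """
    records = {}
    for name in per_beat.columns:
        vals = per_beat[name].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        q1, med, q3 = (float(np.percentile(vals, q)) for q in (25, 50, 75))
        degenerate = sd <= 1e-9 * max(1.0, abs(float(np.mean(vals))))
        if degenerate or len(vals) < 3:
            skw = kur = 0.0
        else:
            skw = float(stats.skew(vals, bias=False))
            kur = float(stats.kurtosis(vals, bias=False))
        records[name] = {
            "AVG": float(np.mean(vals)), "MED": med, "SD": sd,
            "Q1": q1, "Q3": q3, "IQR": q3 - q1,
            "SKW": skw, "KUR": kur,
            "MAD": float(np.mean(np.abs(vals - np.mean(vals)))),
        }
    return pd.DataFrame.from_dict(records, orient="index", columns=list(SUMMARY_STATS))
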