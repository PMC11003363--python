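"""Deterministic discrete extremum and zero-crossing primitives.

Conventions: a local maximum is a sample strictly greater than its left
neighbor and not smaller than its right neighbor; plateaus are reported
at their first sample. Zero-crossings are located with linear sub-sample
interpolation and reported at the nearest sample. Search intervals are
half-open-ish index ranges [lo, hi] inclusive of interior samples only.
"""
from __future__ import annotations

import numpy as np

__all__ = ["local_maxima", "local_minima", "argmax_in", "argmin_in", "zero_crossings"]


def _local_extrema(x: np.ndarray, lo: int, hi: int, sign: float) -> list[int]:
    lo = max(lo, 1)
    hi = min(hi, len(x) - 2)
    out: list[int] = []
    i = lo
    while i <= hi:
        if sign * (x[i] - x[i - 1]) > 0:
            j = i
            while j + 1 <= hi + 1 and x[j + 1] == x[i]:
                j += 1
            if j + 1 < len(x) and sign * (x[i] - x[j + 1]) > 0:
                out.append(i)  # plateau start
            i = j + 1
        else:
            i += 1
    return out


def local_maxima(x: np.ndarray, lo: int, hi: int) -> list[int]:
    """Indices of local maxima of ``x`` with lo <= i <= hi."""
    return _local_extrema(np.asarray(x, dtype=float), lo, hi, +1.0)


def local_minima(x: np.ndarray, lo: int, hi: int) -> list[int]:
    return _local_extrema(np.asarray(x, dtype=float), lo, hi, -1.0)


def argmax_in(x: np.ndarray, lo: int, hi: int) -> int | None:
    lo = max(lo, 0)
    hi = min(hi, len(x) - 1)
    if hi < lo:
        return None
    return lo + int(np.argmax(x[lo:hi + 1]))


def argmin_in(x: np.ndarray, lo: int, hi: int) -> int | None:
    lo = max(lo, 0)
    hi = min(hi, len(x) - 1)
    if hi < lo:
        return None
    return lo + int(np.argmin(x[lo:hi + 1]))


def zero_crossings(x: np.ndarray, lo: int, hi: int, direction: str = "any") -> list[int]:
    """Nearest-sample indices of zero-crossings of ``x`` in [lo, hi].

    ``direction``: 'rising' (- to +), 'falling' (+ to -) or 'any'. The
    crossing between samples i and i+1 is placed at i when the linearly
    interpolated root lies in the first half of the interval, else i+1.
    """
    x = np.asarray(x, dtype=float)
    lo = max(lo, 0)
    hi = min(hi, len(x) - 2)
    out: list[int] = []
    for i in range(lo, hi + 1):
        a, b = x[i], x[i + 1]
        if a == 0.0 and b != 0.0:
            out.append(i)
            continue
        if a * b < 0:
            if direction == "rising" and not (a < 0 < b):
                continue
            if direction == "falling" and not (a > 0 > b):
                continue
            frac = a / (a - b)
            out.append(i if frac < 0.5 else i + 1)
    return out
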