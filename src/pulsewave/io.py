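"""Reading raw PPG signals and writing fiducial/biomarker tables.

Supported inputs: one-sample-per-line CSV/TXT, MAT containers holding a
single named numeric vector plus a scalar sampling rate, and standard EDF
(European Data Format) files with named channels. Outputs are plain CSV
(comma separator, ``.`` decimal, UTF-8, header row).

Sample indexing is 0-based throughout; reported times are milliseconds
from the start of the signal (fiducial tables additionally give
milliseconds from the pulse onset).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ChannelNotFoundError, ConfigError, ParseError

if TYPE_CHECKING:  # pragma: no cover
    from .fiducials import FiducialSet

__all__ = ["RawSignal", "load_signal", "write_fiducials", "read_fiducials",
           "write_biomarkers", "write_beats", "read_event_times_ms"]

FIDUCIAL_POINTS = ("on", "sp", "dn", "dp", "off", "u", "v", "w",
                   "a", "b", "c", "d", "e", "f", "p1", "p2")


@dataclass
class RawSignal:
    """A single-channel raw PPG series with its sampling rate."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ConfigError("sampling rate must be > 0")
        if self.samples.size == 0:
            raise ParseError(f"no samples in {self.source or 'signal'}")
        if not np.all(np.isfinite(self.samples)):
            raise ParseError(f"non-finite samples in {self.source or 'signal'}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def _load_text(path: Path) -> np.ndarray:
    values = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            token = line.strip().rstrip(",")
            if not token:
                continue
            # tolerate a single header line of non-numeric text
            try:
                values.append(float(token))
            except ValueError:
                if lineno == 1 and re.search(r"[A-Za-z]", token):
                    continue
                raise ParseError(f"{path}:{lineno}: not a number: {token!r}") from None
    if not values:
        raise ParseError(f"{path}: no numeric samples found")
    return np.asarray(values, dtype=float)


def _load_mat(path: Path, channel: str | None, fs: float | None):
    from scipy.io import loadmat

    data = loadmat(path, squeeze_me=True)
    names = [k for k in data if not k.startswith("__")]
    arrays = {k: np.atleast_1d(np.asarray(data[k]).squeeze()) for k in names}
    file_fs = None
    for key in ("fs", "Fs", "sampling_rate"):
        if key in arrays and arrays[key].size == 1:
            file_fs = float(arrays[key][0])
    vectors = {k: v for k, v in arrays.items()
               if v.ndim == 1 and v.size > 1 and np.issubdtype(v.dtype, np.number)}
    if channel is not None:
        if channel not in vectors:
            raise ChannelNotFoundError(f"{path}: no vector named {channel!r} (have {sorted(vectors)})")
        samples = vectors[channel]
    elif len(vectors) == 1:
        samples = next(iter(vectors.values()))
    else:
        raise ConfigError(f"{path}: multiple vectors {sorted(vectors)}; pass channel=")
    return samples.astype(float), file_fs if file_fs is not None else fs


def _read_edf_header(fh) -> dict:
    def fixed(n: int) -> str:
        return fh.read(n).decode("ascii", errors="replace").strip()

    hdr = {}
    hdr["version"] = fixed(8)
    hdr["patient"] = fixed(80)
    hdr["recording"] = fixed(80)
    hdr["startdate"] = fixed(8)
    hdr["starttime"] = fixed(8)
    hdr["header_bytes"] = int(fixed(8))
    fixed(44)  # reserved
    hdr["n_records"] = int(fixed(8))
    hdr["record_duration"] = float(fixed(8))
    ns = int(fixed(4))
    hdr["ns"] = ns

    def per_signal(n: int, cast=str):
        return [cast(fixed(n)) for _ in range(ns)]

    hdr["labels"] = per_signal(16)
    per_signal(80)  # transducer
    hdr["dims"] = per_signal(8)
    hdr["phys_min"] = per_signal(8, float)
    hdr["phys_max"] = per_signal(8, float)
    hdr["dig_min"] = per_signal(8, int)
    hdr["dig_max"] = per_signal(8, int)
    per_signal(80)  # prefilter
    hdr["nsamp"] = per_signal(8, int)
    per_signal(32)  # reserved
    return hdr


def _load_edf(path: Path, channel: str | None):
    """Minimal EDF reader: fixed-width ASCII header + int16 LE records."""
    with open(path, "rb") as fh:
        try:
            hdr = _read_edf_header(fh)
        except (ValueError, UnicodeDecodeError) as exc:
            raise ParseError(f"{path}: malformed EDF header: {exc}") from exc
        labels = hdr["labels"]
        if channel is None:
            if len(labels) != 1:
                raise ConfigError(f"{path}: channels {labels}; pass channel=")
            idx = 0
        else:
            matches = [i for i, lab in enumerate(labels) if lab == channel]
            if not matches:
                raise ChannelNotFoundError(f"{path}: no channel {channel!r} (have {labels})")
            idx = matches[0]
        nsamp = hdr["nsamp"]
        fs = nsamp[idx] / hdr["record_duration"]
        gain = (hdr["phys_max"][idx] - hdr["phys_min"][idx]) / (
            hdr["dig_max"][idx] - hdr["dig_min"][idx])
        offset = hdr["phys_min"][idx] - gain * hdr["dig_min"][idx]

        fh.seek(hdr["header_bytes"])
        rec_len = sum(nsamp)
        raw = np.fromfile(fh, dtype="<i2", count=hdr["n_records"] * rec_len)
    n_records = len(raw) // rec_len
    raw = raw[: n_records * rec_len].reshape(n_records, rec_len)
    start = sum(nsamp[:idx])
    digital = raw[:, start:start + nsamp[idx]].ravel()
    return digital * gain + offset, fs


def load_signal(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    channel: str | None = None,
) -> RawSignal:
    """Load a raw PPG series from CSV/TXT, MAT or EDF.

    ``fs`` is taken from file metadata when the format carries it (EDF
    always; MAT when an ``fs`` scalar is present) and must be supplied
    for plain-text input. ``channel`` selects the EDF signal label or the
    MAT variable name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("csv", "txt"):
        samples, file_fs = _load_text(path), None
    elif fmt == "mat":
        samples, file_fs = _load_mat(path, channel, fs)
    elif fmt == "edf":
        samples, file_fs = _load_edf(path, channel)
    else:
        raise ConfigError(f"unsupported format {fmt!r}")
    final_fs = file_fs if file_fs is not None else fs
    if final_fs is None:
        raise ConfigError(f"{path}: sampling rate not in file; pass fs=")
    return RawSignal(samples=samples, fs=float(final_fs), source=str(path))


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

def fiducials_to_frame(fiducials: Sequence["FiducialSet"], fs: float) -> pd.DataFrame:
    """One row per pulse; ``<pt>_idx``, ``<pt>_ms`` (from signal start) and
    ``<pt>_ms_on`` (from pulse onset) columns per fiducial point."""
    rows = []
    for i, fid in enumerate(fiducials):
        row: dict = {"pulse": i, "dn_class": fid.dn_class}
        on = fid.on
        for pt in FIDUCIAL_POINTS:
            idx = getattr(fid, pt)
            row[f"{pt}_idx"] = idx
            row[f"{pt}_ms"] = None if idx is None else idx * 1000.0 / fs
            row[f"{pt}_ms_on"] = (
                None if idx is None or on is None else (idx - on) * 1000.0 / fs
            )
        rows.append(row)
    cols = ["pulse", "dn_class"]
    for pt in FIDUCIAL_POINTS:
        cols += [f"{pt}_idx", f"{pt}_ms", f"{pt}_ms_on"]
    return pd.DataFrame(rows, columns=cols)


def write_fiducials(
    fiducials: Sequence["FiducialSet"], path: str | Path, fs: float,
    sqi: Sequence[float] | None = None,
) -> Path:
    """Write the per-pulse fiducial table as CSV (missing points = empty cells)."""
    frame = fiducials_to_frame(fiducials, fs)
    if sqi is not None:
        frame["sqi"] = list(sqi)
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.6f", encoding="utf-8")
    return path


def read_fiducials(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, encoding="utf-8")
    idx_cols = [c for c in frame.columns if c.endswith("_idx")]
    frame[idx_cols] = frame[idx_cols].astype("Int64")
    if "dn_class" in frame:
        frame["dn_class"] = frame["dn_class"].astype("Int64")
    return frame


def write_biomarkers(
    per_beat: pd.DataFrame, summary: pd.DataFrame, path: str | Path
) -> tuple[Path, Path]:
    """Write the per-beat biomarker matrix and its summary-statistics table.

    ``path`` is a base path: ``<base>_beats.csv`` holds one row per beat
    and one column per biomarker; ``<base>_summary.csv`` holds one row per
    biomarker and the nine statistic columns.
    """
    base = Path(path)
    if base.suffix == ".csv":
        base = base.with_suffix("")
    beats_path = base.parent / (base.name + "_beats.csv")
    summary_path = base.parent / (base.name + "_summary.csv")
    per_beat.to_csv(beats_path, index_label="pulse", float_format="%.6f", encoding="utf-8")
    summary.to_csv(summary_path, index_label="biomarker", float_format="%.6f", encoding="utf-8")
    return beats_path, summary_path


def write_beats(sp_idx: Iterable[int], fs: float, path: str | Path) -> Path:
    """Write detected systolic peaks as a CSV with index and time-ms columns."""
    sp_idx = np.asarray(list(sp_idx), dtype=int)
    frame = pd.DataFrame({"sp_idx": sp_idx, "sp_ms": sp_idx * 1000.0 / fs})
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.3f", encoding="utf-8")
    return path


def read_event_times_ms(path: str | Path, fs: float | None = None) -> np.ndarray:
    """Read event times in ms from a CSV (``*_ms`` column preferred, else an
    index column interpreted with ``fs``) or a headerless single column."""
    frame = pd.read_csv(path, encoding="utf-8")
    ms_cols = [c for c in frame.columns if str(c).endswith("_ms") or str(c) == "ms"]
    if ms_cols:
        return frame[ms_cols[0]].to_numpy(dtype=float)
    idx_cols = [c for c in frame.columns if str(c).endswith("_idx") or str(c) == "idx"]
    if idx_cols:
        if fs is None:
            raise ConfigError(f"{path}: index column needs fs to convert to ms")
        return frame[idx_cols[0]].to_numpy(dtype=float) * 1000.0 / fs
    # headerless single column of times
    col = frame.columns[0]
    try:
        first = [float(col)]
    except ValueError:
        first = []
    return np.asarray(first + frame[col].tolist(), dtype=float)
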