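"""File I/O: EDF recordings, annotation files, feature tables.

EDF files are written with a minimal built-in 16-bit writer (1-second data
records, physical dimension uV) and read back through :mod:`mne`.  Expert
annotations travel as delimited text with columns
``subject  epoch_index  rater  score`` where score is ``0..6`` or ``REJECT``.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .core import REJECT, Recording

__all__ = ["write_edf", "read_edf", "write_annotations", "read_annotations",
           "write_feature_table", "read_feature_table"]


def _pad(value: str, width: int) -> bytes:
    b = str(value).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, recording: Recording) -> Path:
    """Write a recording as 16-bit EDF with 1-second data records.

    The trailing partial second, if any, is dropped.  Physical dimension is
    uV; each channel gets its own symmetric physical range.
    """
    path = Path(path)
    fs = recording.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = recording.n_samples // spr
    data = recording.data[:, : n_rec * spr]
    nch = recording.n_channels

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6) * 1.0001
    dig_max, dig_min = 32767, -32768

    with open(path, "wb") as f:
        start = _dt.datetime(2000, 1, 1)
        f.write(_pad("0", 8))
        f.write(_pad(recording.subject_id, 80))
        f.write(_pad("Startdate 01-JAN-2000", 80))
        f.write(_pad(start.strftime("%d.%m.%y"), 8))
        f.write(_pad(start.strftime("%H.%M.%S"), 8))
        f.write(_pad(str(256 * (nch + 1)), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(nch), 4))
        for lab in recording.channel_labels:
            f.write(_pad(f"EEG {lab}", 16))
        for _ in range(nch):
            f.write(_pad("", 80))
        for _ in range(nch):
            f.write(_pad("uV", 8))
        for pm in phys_max:
            f.write(_pad(f"{-pm:.6g}"[:8], 8))
        for pm in phys_max:
            f.write(_pad(f"{pm:.6g}"[:8], 8))
        for _ in range(nch):
            f.write(_pad(str(dig_min), 8))
        for _ in range(nch):
            f.write(_pad(str(dig_max), 8))
        for _ in range(nch):
            f.write(_pad("", 80))
        for _ in range(nch):
            f.write(_pad(str(spr), 8))
        for _ in range(nch):
            f.write(_pad("", 32))

        scale = dig_max / phys_max  # digital per uV, per channel
        for r in range(n_rec):
            block = data[:, r * spr: (r + 1) * spr]
            dig = np.round(block * scale[:, None]).astype("<i2")
            f.write(dig.tobytes())
    return path


def read_edf(path: str | Path, subject_id: str | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (uV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    labels = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    return Recording(data=data_uv, fs=float(raw.info["sfreq"]),
                     channel_labels=labels,
                     subject_id=subject_id or Path(path).stem)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def write_annotations(path: str | Path, table: pd.DataFrame) -> Path:
    """Write an annotation table (subject, epoch_index, rater, score).

    ``score`` may contain the integer REJECT sentinel; it is serialized as the
    literal string ``REJECT``.
    """
    path = Path(path)
    out = table.copy()
    out["score"] = [
        "REJECT" if s == REJECT else str(int(s)) for s in out["score"]]
    out.to_csv(path, sep="\t", index=False)
    return path


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation table; REJECT becomes the integer sentinel."""
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "rater": str})
    df["score"] = [REJECT if str(s).strip().upper() == "REJECT" else int(s)
                   for s in df["score"]]
    return df


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(path: str | Path, values: np.ndarray,
                        feature_ids: list[str],
                        subject_id: str | None = None) -> Path:
    """Write an epochs x features matrix as TSV with feature-id header."""
    df = pd.DataFrame(values, columns=feature_ids)
    df.insert(0, "epoch_index", np.arange(len(df)))
    if subject_id is not None:
        df.insert(0, "subject", subject_id)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
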