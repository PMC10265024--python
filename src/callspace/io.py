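"""Shared file I/O: WAV audio, Raven-style selection tables, event and snapshot CSVs.

Selection tables follow the Raven tab-separated dialect: a single header row,
``Begin Time (s)`` / ``End Time (s)`` columns, optional frequency bounds and
label columns.  Unknown columns round-trip opaquely.  Times are written with
6-decimal precision and round-trip exactly at that precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

REQUIRED_SELECTION_COLUMNS = ("Begin Time (s)", "End Time (s)")

#: canonical column order for tables this package writes
_CANONICAL = [
    "Selection",
    "Begin Time (s)",
    "End Time (s)",
    "Low Freq (Hz)",
    "High Freq (Hz)",
    "label",
]


@dataclass
class CallSelection:
    """One detected or annotated call in a recording.

    Times are seconds on the half-open interval ``[begin, end)``.
    """

    recording: str
    begin: float
    end: float
    low_freq: float = 500.0
    high_freq: float = 8000.0
    label: str = "call"
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.end - self.begin


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono WAV file, returning (float waveform in [-1, 1], sample rate)."""
    sample_rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    return data, int(sample_rate)


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write a float waveform as 16-bit PCM mono WAV."""
    peak = np.max(np.abs(waveform)) if waveform.size else 0.0
    scaled = waveform if peak <= 1.0 else waveform / peak
    pcm = np.round(scaled * 32767.0).astype(np.int16)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(str(path), int(sample_rate), pcm)


def selections_to_frame(selections: list[CallSelection]) -> pd.DataFrame:
    """Convert CallSelection objects to a Raven-dialect DataFrame."""
    rows = []
    for i, s in enumerate(selections, start=1):
        row = {
            "Selection": i,
            "Begin Time (s)": s.begin,
            "End Time (s)": s.end,
            "Low Freq (Hz)": s.low_freq,
            "High Freq (Hz)": s.high_freq,
            "label": s.label,
        }
        row.update(s.meta)
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=_CANONICAL)
    return pd.DataFrame(rows)


def frame_to_selections(table: pd.DataFrame, recording: str = "") -> list[CallSelection]:
    out = []
    for _, row in table.iterrows():
        meta = {
            k: row[k]
            for k in table.columns
            if k not in _CANONICAL
        }
        out.append(
            CallSelection(
                recording=recording,
                begin=float(row["Begin Time (s)"]),
                end=float(row["End Time (s)"]),
                low_freq=float(row.get("Low Freq (Hz)", 500.0)),
                high_freq=float(row.get("High Freq (Hz)", 8000.0)),
                label=str(row.get("label", "call")),
                meta=meta,
            )
        )
    return out


def read_selection_table(path: str | Path) -> pd.DataFrame:
    """Read a Raven-style tab-separated selection table.

    Raises ``ValueError`` naming the first missing required column.
    """
    table = pd.read_csv(path, sep="\t")
    for col in REQUIRED_SELECTION_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"selection table {path} is missing required column {col!r}")
    return table


def write_selection_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a selection table; float times at 6-decimal precision."""
    for col in REQUIRED_SELECTION_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"selection table is missing required column {col!r}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a dyadic interaction event log (CSV with header)."""
    events = pd.read_csv(path)
    missing = {"session", "actor", "receiver", "type"} - set(events.columns)
    if missing:
        raise ValueError(f"event log {path} missing columns: {sorted(missing)}")
    return events


def read_snapshots(path: str | Path) -> pd.DataFrame:
    """Read a proximity snapshot table (CSV; distance_cm may be empty = missing)."""
    snaps = pd.read_csv(path)
    missing = {"snapshot_id", "bird_a", "bird_b", "distance_cm"} - set(snaps.columns)
    if missing:
        raise ValueError(f"snapshot table {path} missing columns: {sorted(missing)}")
    return snaps
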