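"""Reading and writing fluorescence trace tables, event tables and ROI stacks.

Trace tables are plain CSV: a header row, a leading time column named
``time_s`` (seconds) or ``frame`` (frame index), and one column per ROI.
Event tables are CSV with one row per detected event.  Image stacks are
multi-page grayscale TIFF, from which mean-intensity traces can be extracted
over square ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTrace",
    "TraceParseError",
    "read_traces",
    "write_traces",
    "read_events",
    "write_events",
    "extract_rois",
]

TIME_COLUMNS = ("time_s", "frame")


class TraceParseError(ValueError):
    """Raised when a trace table cannot be parsed."""


@dataclass
class FluorescenceTrace:
    """One ROI's sampled fluorescence versus time.

    Parameters
    ----------
    roi_id : str
        Identifier of the region of interest (bouton).
    frame_interval : float
        Sampling interval in seconds (~0.12 s single channel, 0.18 s dual).
    values : ndarray
        Fluorescence in arbitrary units, one value per frame.
    channel : str
        ``"green"`` (pHluorin / GCaMP) or ``"red"`` (pHTomato).
    t0 : float
        Time of the first frame, seconds.
    """

    roi_id: str
    frame_interval: float
    values: np.ndarray
    channel: str = "green"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trace {self.roi_id!r} contains non-finite values")
        if self.channel not in ("green", "red"):
            raise ValueError("channel must be 'green' or 'red'")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total recorded time in seconds."""
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return self.t0 + np.arange(self.n_frames) * self.frame_interval

    def copy(self, **changes) -> "FluorescenceTrace":
        if "values" not in changes:
            changes["values"] = self.values.copy()
        return replace(self, **changes)


def read_traces(path, frame_interval: float, channel: str = "green") -> list[FluorescenceTrace]:
    """Read a CSV trace table into one :class:`FluorescenceTrace` per ROI column.

    The first column must be named ``time_s`` or ``frame``; every remaining
    column is one ROI.  Raises :class:`TraceParseError` on an empty file,
    ragged rows, non-numeric cells or a nonpositive frame interval, naming the
    offending row/column where possible.
    """
    path = Path(path)
    if frame_interval <= 0:
        raise TraceParseError("frame_interval must be positive")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TraceParseError(f"{path}: file is empty") from None
    except pd.errors.ParserError as exc:
        raise TraceParseError(f"{path}: {exc}") from None
    if df.shape[1] < 2:
        raise TraceParseError(f"{path}: need a time column plus at least one ROI column")
    if df.columns[0] not in TIME_COLUMNS:
        raise TraceParseError(
            f"{path}: first column must be named one of {TIME_COLUMNS}, got {df.columns[0]!r}"
        )
    if df.shape[0] == 0:
        raise TraceParseError(f"{path}: no data rows")

    t0 = 0.0
    if df.columns[0] == "time_s":
        tcol = pd.to_numeric(df.iloc[:, 0], errors="coerce")
        if tcol.isna().any():
            row = int(tcol.isna().idxmax())
            raise TraceParseError(f"{path}: non-numeric time value at row {row}")
        t0 = float(tcol.iloc[0])

    traces = []
    for col in df.columns[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise TraceParseError(f"{path}: non-numeric cell at row {row}, column {col!r}")
        traces.append(
            FluorescenceTrace(
                roi_id=str(col),
                frame_interval=frame_interval,
                values=vals.to_numpy(dtype=float),
                channel=channel,
                t0=t0,
            )
        )
    return traces


def write_traces(path, traces: Sequence[FluorescenceTrace], time_column: str = "time_s") -> None:
    """Write traces (all the same length) as a CSV table, one column per ROI."""
    if not traces:
        raise ValueError("no traces to write")
    n = traces[0].n_frames
    if any(t.n_frames != n for t in traces):
        raise ValueError("all traces must have the same length")
    if time_column == "time_s":
        lead = traces[0].times
    elif time_column == "frame":
        lead = np.arange(n)
    else:
        raise ValueError(f"unknown time column {time_column!r}")
    df = pd.DataFrame({time_column: lead})
    for t in traces:
        df[t.roi_id] = t.values
    df.to_csv(path, index=False)


EVENT_COLUMNS = [
    "roi_id",
    "onset_frame",
    "onset_time",
    "amplitude",
    "dff",
    "baseline_mean",
    "baseline_sd",
    "polarity",
]


def write_events(path, events) -> None:
    """Write a list of detected events (or a DataFrame) to CSV."""
    if isinstance(events, pd.DataFrame):
        df = events
    else:
        df = pd.DataFrame([e.as_dict() for e in events], columns=EVENT_COLUMNS)
    df.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Read an event table written by :func:`write_events`."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TraceParseError(f"{path}: file is empty") from None
    missing = [c for c in ("roi_id", "onset_time", "amplitude") if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing event columns {missing}")
    return df


def extract_rois(
    stack: np.ndarray,
    centers: Sequence[tuple[int, int]],
    side: int,
    frame_interval: float,
    channel: str = "green",
) -> list[FluorescenceTrace]:
    """Mean-intensity traces over square ROIs of a (frames, rows, cols) stack.

    Coordinates are 0-based ``(row, col)``.  The square ROI covers ``side``
    pixels per axis starting at ``center - side // 2`` (odd sides are centered
    on the pixel; even sides are biased toward lower indices).  ROIs partially
    outside the image are clipped to the image; an ROI fully outside raises a
    ``ValueError`` naming the offending center.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be a 3-D (frames, rows, cols) array")
    if side < 1:
        raise ValueError("side must be >= 1")
    _, n_rows, n_cols = stack.shape
    traces = []
    for i, (r, c) in enumerate(centers):
        r0, c0 = int(r) - side // 2, int(c) - side // 2
        r1, c1 = r0 + side, c0 + side
        r0c, r1c = max(r0, 0), min(r1, n_rows)
        c0c, c1c = max(c0, 0), min(c1, n_cols)
        if r0c >= r1c or c0c >= c1c:
            raise ValueError(f"ROI centered at {(r, c)} lies fully outside the image")
        block = stack[:, r0c:r1c, c0c:c1c]
        traces.append(
            FluorescenceTrace(
                roi_id=f"roi{i}",
                frame_interval=frame_interval,
                values=block.reshape(stack.shape[0], -1).mean(axis=1),
                channel=channel,
            )
        )
    return traces


def read_tiff_stack(path) -> np.ndarray:
    """Load a multi-page grayscale TIFF as a (frames, rows, cols) array."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return np.asarray(arr, dtype=float)
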