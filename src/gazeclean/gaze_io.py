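"""Gaze data model and CSV I/O.

A gaze log is a minimal CSV with header ``t,x,y,valid`` (seconds, pixels, pixels,
0/1); a click log has header ``t,x,y,target_id``. Coordinates are 0-based with
the origin at the top-left of the screen. Invalid samples are carried through the
containers but excluded from all downstream mathematics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, InvalidArgumentError

logger = logging.getLogger(__name__)

GAZE_COLUMNS = ("t", "x", "y", "valid")
CLICK_COLUMNS = ("t", "x", "y", "target_id")


@dataclass(frozen=True)
class GazeSample:
    """One timestamped gaze coordinate; ``valid`` is the tracker's validity flag."""

    t: float
    x: float
    y: float
    valid: bool = True


@dataclass
class GazeTrace:
    """A timestamped 2-D gaze stream at a fixed sampling rate.

    Attributes
    ----------
    t : (n,) seconds since session start, non-decreasing.
    xy : (n, 2) screen-pixel coordinates.
    valid : (n,) tracker validity flags.
    fs : sampling frequency in Hz (default 30).
    """

    t: np.ndarray
    xy: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    fs: float = 30.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise FormatError("xy must be an (n, 2) array")
        if self.t.shape[0] != self.xy.shape[0]:
            raise FormatError("t and xy lengths differ")
        if self.valid is None:
            self.valid = np.ones(len(self.t), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape[0] != self.t.shape[0]:
            raise FormatError("valid and t lengths differ")
        if len(self.t) and np.any(np.diff(self.t) < 0):
            raise FormatError("timestamps must be non-decreasing")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def from_samples(cls, samples: Iterable[GazeSample], fs: float = 30.0) -> "GazeTrace":
        samples = list(samples)
        if not samples:
            return cls(np.empty(0), np.empty((0, 2)), np.empty(0, dtype=bool), fs)
        return cls(
            np.array([s.t for s in samples]),
            np.array([[s.x, s.y] for s in samples]),
            np.array([s.valid for s in samples]),
            fs,
        )

    def samples(self) -> list[GazeSample]:
        return [
            GazeSample(float(t), float(x), float(y), bool(v))
            for t, (x, y), v in zip(self.t, self.xy, self.valid)
        ]

    def valid_only(self) -> "GazeTrace":
        """Trace restricted to tracker-valid samples."""
        m = self.valid
        return GazeTrace(self.t[m], self.xy[m], np.ones(int(m.sum()), bool), self.fs)

    def slice(self, start: int, stop: int) -> "GazeTrace":
        return GazeTrace(self.t[start:stop], self.xy[start:stop], self.valid[start:stop], self.fs)


@dataclass
class FixationChunk:
    """A contiguous run of fixation-classified samples from one trace.

    ``start_index``/``end_index`` are inclusive indices into the source trace.
    The centroid is always the arithmetic mean of the member coordinates.
    """

    xy: np.ndarray
    start_index: int
    end_index: int
    t: np.ndarray | None = None
    target_id: int | str | None = None

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.end_index < self.start_index:
            raise InvalidArgumentError("end_index must be >= start_index")
        if self.t is not None:
            self.t = np.asarray(self.t, dtype=float)

    def __len__(self) -> int:
        return self.xy.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.xy.mean(axis=0)

    def with_xy(self, xy: np.ndarray) -> "FixationChunk":
        """Copy of this chunk with replaced coordinates (same sample count)."""
        xy = np.asarray(xy, dtype=float)
        if xy.shape != self.xy.shape:
            raise InvalidArgumentError("replacement coordinates must keep the shape")
        return FixationChunk(xy, self.start_index, self.end_index, self.t, self.target_id)


@dataclass(frozen=True)
class ClickEvent:
    """A logged mouse click: time, screen position and (optional) stimulus id."""

    t: float
    x: float
    y: float
    target_id: int | str | None = None


def read_gaze_csv(path: str | Path, fs: float | None = None) -> GazeTrace:
    """Read a ``t,x,y,valid`` CSV into a GazeTrace.

    Malformed (non-numeric) rows are dropped with a logged count. ``fs`` is taken
    from the argument or inferred from the median inter-sample interval.
    """
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gaze CSV {path} missing columns: {missing}")
    n_raw = len(df)
    if n_raw == 0:
        raise EmptyInputError(f"gaze CSV {path} contains no rows")
    for c in GAZE_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = df.dropna(subset=list(GAZE_COLUMNS))
    dropped = n_raw - len(df)
    if dropped:
        logger.warning("read_gaze_csv: dropped %d malformed row(s) from %s", dropped, path)
    if len(df) == 0:
        raise EmptyInputError(f"gaze CSV {path} contains no parseable rows")
    t = df["t"].to_numpy(float)
    if fs is None:
        dt = np.median(np.diff(t)) if len(t) > 1 else None
        fs = 1.0 / dt if dt and dt > 0 else 30.0
    return GazeTrace(t, df[["x", "y"]].to_numpy(float), df["valid"].to_numpy() != 0, fs)


def write_gaze_csv(trace: GazeTrace, path: str | Path) -> None:
    """Write a GazeTrace as a ``t,x,y,valid`` CSV (round-trips to 1e-6)."""
    pd.DataFrame(
        {
            "t": trace.t,
            "x": trace.xy[:, 0],
            "y": trace.xy[:, 1],
            "valid": trace.valid.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.9g")


def read_clicks_csv(path: str | Path) -> list[ClickEvent]:
    """Read a ``t,x,y,target_id`` CSV into ClickEvents."""
    df = pd.read_csv(path)
    missing = [c for c in CLICK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"click CSV {path} missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        tid = row.target_id
        if pd.isna(tid):
            tid = None
        elif isinstance(tid, float) and tid.is_integer():
            tid = int(tid)
        out.append(ClickEvent(float(row.t), float(row.x), float(row.y), tid))
    return out


def write_clicks_csv(clicks: Sequence[ClickEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "t": [c.t for c in clicks],
            "x": [c.x for c in clicks],
            "y": [c.y for c in clicks],
            "target_id": [c.target_id for c in clicks],
        }
    ).to_csv(path, index=False, float_format="%.9g")


def segment_by_clicks(
    trace: GazeTrace, clicks: Sequence[ClickEvent], window_s: float = 2.0
) -> list[tuple[ClickEvent, GazeTrace]]:
    """Cut the sub-trace covering ``[t_click - window_s, t_click]`` for every click.

    Sub-traces may overlap; a click earlier than ``window_s`` from the start yields
    the truncated prefix. No returned sample lies after its click timestamp.
    """
    if window_s <= 0:
        raise InvalidArgumentError("window_s must be positive")
    out: list[tuple[ClickEvent, GazeTrace]] = []
    for click in clicks:
        lo = np.searchsorted(trace.t, click.t - window_s, side="left")
        hi = np.searchsorted(trace.t, click.t, side="right")
        out.append((click, trace.slice(int(lo), int(hi))))
    return out
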