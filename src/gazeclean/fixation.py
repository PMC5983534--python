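"""Velocity-threshold (I-VT) fixation extraction.

Samples whose point-to-point velocity exceeds a threshold are saccades; maximal
sub-threshold runs become :class:`~gazeclean.gaze_io.FixationChunk` objects. The
threshold defaults to 20 in pixels-per-sample; with a :class:`ScreenGeometry` it
can instead be interpreted in degrees per second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, InvalidArgumentError
from .gaze_io import FixationChunk, GazeTrace
from .geometry import ScreenGeometry, px_to_deg

DEFAULT_VELOCITY_THRESHOLD = 20.0
DEFAULT_MIN_FIXATION_SAMPLES = 4
#: adjacent-fixation merging, as in standard I-VT post-processing: runs
#: separated by at most this many supra-threshold samples ...
DEFAULT_MERGE_MAX_GAP = 2
#: ... and with centroids at most this far apart (px; ~1 degree at 60 cm)
#: are fused, gap samples included. Set merge_max_gap=0 to disable.
DEFAULT_MERGE_MAX_DIST = 30.0


@dataclass
class VelocitySeries:
    """Per-sample speeds aligned to samples 2..n of the source trace."""

    values: np.ndarray
    units: str  # "px_per_sample" or "deg_per_s"

    def __len__(self) -> int:
        return len(self.values)


def sample_velocities(
    trace: GazeTrace,
    units: str = "px_per_sample",
    geom: ScreenGeometry | None = None,
) -> VelocitySeries:
    """Point-to-point speeds of the valid samples of ``trace``.

    ``v_i`` is the Euclidean distance between consecutive valid samples divided
    by their gap in samples (default) or, with a geometry, converted to degrees
    of visual angle per second.
    """
    valid = trace.valid_only()
    if len(valid) < 2:
        raise EmptyInputError("need at least 2 valid samples to compute velocities")
    d = np.linalg.norm(np.diff(valid.xy, axis=0), axis=1)
    gap = np.maximum(np.rint(np.diff(valid.t) * valid.fs), 1.0)  # gaps in samples
    v = d / gap
    if units == "px_per_sample":
        return VelocitySeries(v, units)
    if units == "deg_per_s":
        if geom is None:
            raise InvalidArgumentError("deg_per_s units require a ScreenGeometry")
        deg = np.array([px_to_deg(di, geom) for di in d])
        return VelocitySeries(deg / (gap / valid.fs), units)
    raise InvalidArgumentError(f"unknown velocity units {units!r}")


def extract_fixations(
    trace: GazeTrace,
    v_threshold: float = DEFAULT_VELOCITY_THRESHOLD,
    min_len: int = DEFAULT_MIN_FIXATION_SAMPLES,
    units: str = "px_per_sample",
    geom: ScreenGeometry | None = None,
    merge_max_gap: int = DEFAULT_MERGE_MAX_GAP,
    merge_max_dist: float = DEFAULT_MERGE_MAX_DIST,
) -> list[FixationChunk]:
    """Classify samples by I-VT and return maximal fixation runs as chunks.

    A sample is a fixation sample when its incoming velocity is below
    ``v_threshold``; the first sample inherits the classification of the second.
    Adjacent runs separated by at most ``merge_max_gap`` saccade-classified
    samples and with centroids at most ``merge_max_dist`` px apart are merged
    (gap samples included) — single noise-displaced samples inside one true
    fixation otherwise split it into spurious fragments. Runs shorter than
    ``min_len`` after merging are discarded. Chunks are disjoint, ordered, and
    restricted to tracker-valid samples.
    """
    if v_threshold <= 0:
        raise InvalidArgumentError("v_threshold must be positive")
    if min_len < 1:
        raise InvalidArgumentError("min_len must be >= 1")
    valid = trace.valid_only()
    n = len(valid)
    if n == 0:
        return []
    if n == 1:
        is_fix = np.ones(1, dtype=bool)
    else:
        v = sample_velocities(trace, units=units, geom=geom).values
        is_fix = np.empty(n, dtype=bool)
        is_fix[1:] = v < v_threshold
        is_fix[0] = is_fix[1]  # first sample has no incoming velocity

    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not is_fix[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and is_fix[j + 1]:
            j += 1
        runs.append((i, j))
        i = j + 1

    if merge_max_gap > 0:
        merged: list[tuple[int, int]] = []
        for i, j in runs:
            if merged:
                pi, pj = merged[-1]
                gap = i - pj - 1
                if gap <= merge_max_gap:
                    c_prev = valid.xy[pi : pj + 1].mean(axis=0)
                    c_cur = valid.xy[i : j + 1].mean(axis=0)
                    if np.linalg.norm(c_cur - c_prev) <= merge_max_dist:
                        merged[-1] = (pi, j)
                        continue
            merged.append((i, j))
        runs = merged

    return [
        FixationChunk(valid.xy[i : j + 1], i, j, t=valid.t[i : j + 1])
        for i, j in runs
        if j - i + 1 >= min_len
    ]
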