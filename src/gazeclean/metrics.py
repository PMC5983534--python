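"""Evaluation metrics: smoothness ratio, closeness, and AOI hit accuracy.

The smoothness ratio SR = D_r / D_f compares the radius of a raw chunk with the
radius of its filtered counterpart (larger is better); closeness CL is the mean
squared distance of a chunk's points from their centroid in px^2 (smaller is
better). Gaze-target accuracy is the percentage of fixation chunks whose
centroid falls inside the area of interest (AOI) of its true target — a chunk
in no AOI or in a wrong AOI counts as incorrect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyInputError, InvalidArgumentError
from .gaze_io import FixationChunk

logger = logging.getLogger(__name__)

AOI_SHAPES = ("circle", "ellipse", "rectangle")


def chunk_radius(chunk: FixationChunk, method: str = "max") -> float:
    """Radius of a chunk: distance from its centroid to its farthest point.

    ``method="p95"`` uses the 95th-percentile distance instead, for robustness
    to a single stray sample. A single-point chunk has radius 0.
    """
    if len(chunk) == 0:
        raise EmptyInputError("chunk must be non-empty")
    d = np.linalg.norm(chunk.xy - chunk.centroid, axis=1)
    if method == "max":
        return float(d.max())
    if method == "p95":
        return float(np.percentile(d, 95))
    raise InvalidArgumentError("method must be 'max' or 'p95'")


def smoothness_ratio(raw: FixationChunk, filtered: FixationChunk, method: str = "max") -> float:
    """SR = radius(raw) / radius(filtered); +inf when the filtered chunk collapses.

    A radius below 1e-9 px (far under any physical resolution; the float mean
    of identical rows can be off by one ulp) counts as fully collapsed.
    """
    dr = chunk_radius(raw, method)
    df = chunk_radius(filtered, method)
    if df < 1e-9:
        logger.warning("smoothness_ratio: filtered chunk fully collapsed (D_f = 0)")
        return float("inf")
    return dr / df


def closeness(chunk: FixationChunk) -> float:
    """CL = mean squared Euclidean distance of chunk points from their centroid."""
    if len(chunk) == 0:
        raise EmptyInputError("chunk must be non-empty")
    d2 = np.sum((chunk.xy - chunk.centroid) ** 2, axis=1)
    return float(d2.mean())


@dataclass(frozen=True)
class AOI:
    """An area of interest around one stimulus entity.

    ``half_extents`` are (half-width, half-height) for the rectangle and the
    semi-axes for the ellipse; the circle uses their minimum as radius, so the
    three shapes nest: circle within ellipse within rectangle.
    """

    shape: str
    center: tuple[float, float]
    half_extents: tuple[float, float]
    stimulus_id: int | str | None = None

    def __post_init__(self) -> None:
        if self.shape not in AOI_SHAPES:
            raise InvalidArgumentError(f"shape must be one of {AOI_SHAPES}")
        if min(self.half_extents) <= 0:
            raise InvalidArgumentError("AOI extents must be positive")


def aoi_contains(aoi: AOI, point: Sequence[float]) -> bool:
    """Boundary-inclusive point-in-AOI test for all three shapes."""
    dx = float(point[0]) - aoi.center[0]
    dy = float(point[1]) - aoi.center[1]
    w, h = aoi.half_extents
    if aoi.shape == "rectangle":
        return abs(dx) <= w and abs(dy) <= h
    if aoi.shape == "ellipse":
        return (dx / w) ** 2 + (dy / h) ** 2 <= 1.0
    r = min(w, h)
    return dx * dx + dy * dy <= r * r


def gaze_accuracy(chunks: Sequence[FixationChunk], layout, shape: str = "rectangle") -> float:
    """Percent of labelled chunks whose centroid hits its true target's AOI.

    ``layout`` must provide ``aoi(target_id, shape)`` (see
    :class:`gazeclean.synth.StimulusLayout`). Every chunk must carry a true
    ``target_id``; unlabeled chunks are invalid input.
    """
    if len(chunks) == 0:
        raise EmptyInputError("no chunks to score")
    hits = 0
    for c in chunks:
        if c.target_id is None:
            raise InvalidArgumentError("gaze_accuracy requires labelled chunks")
        aoi = layout.aoi(c.target_id, shape)
        hits += aoi_contains(aoi, c.centroid)
    return 100.0 * hits / len(chunks)
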