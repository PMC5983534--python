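"""Systematic-error removal via 2x2 linear transforms.

A correction transform ``T`` maps filtered gaze points (row vectors) onto a
ground-truth position: ``corrected = points @ T``. ``T`` is fitted by a
derivative-free Nelder-Mead simplex search on the summed squared residuals,
started at the identity; its determinant is the correctness measure ``M``
(identity fit <=> M = 1). Translation is deliberately not modelled: the
correction class is purely linear about the screen origin.

Supervised paths use transforms learned at the nine calibration targets
(path A: single nearest; path B: four nearest combined by inverse-distance
weighting). Unsupervised paths fit fresh transforms against the nearest
stimulus positions treated as presumptive ground truth (path C: four nearest;
path D: two nearest), again combined by inverse-distance weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import (
    DegenerateFitError,
    EmptyInputError,
    InvalidArgumentError,
    RecalibrationRequired,
)
from .gaze_io import FixationChunk

M_THRESHOLD = 0.8
IWF_EXPONENT = 2
SIMPLEX_MAX_ITER = 2000
SIMPLEX_FTOL = 1e-8


@dataclass
class TransformMatrix:
    """A 2x2 correction matrix; ``M`` (det) is recomputed on access, never stored."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 2):
            raise InvalidArgumentError("transform must be 2x2")

    @property
    def M(self) -> float:
        return float(np.linalg.det(self.matrix))

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(xy, dtype=float)) @ self.matrix


def correctness_measure(T: TransformMatrix | np.ndarray) -> float:
    """The determinant-based correctness measure M = det(T)."""
    m = T.matrix if isinstance(T, TransformMatrix) else np.asarray(T, dtype=float)
    return float(np.linalg.det(m))


def _objective(params: np.ndarray, src: np.ndarray, dst: np.ndarray) -> float:
    T = params.reshape(2, 2)
    r = src @ T - dst
    return float(np.sum(r * r))


def _fit_pairs(chunk, target):
    """Resolve a (chunk, target) pair into (source, desired) row arrays.

    A single target position pairs with the chunk *centroid* — the correction
    learns the separation between where the fixation landed and where it should
    have landed, as in linear-transformation drift correction. (Pairing every
    sample with the same constant target would make the global optimum a
    rank-one map that collapses the fixation dispersion onto the target, so its
    determinant could never act as a correctness measure.) An (n, 2) array of
    per-sample desired coordinates pairs samplewise and fully determines T.
    """
    pts = chunk.xy if isinstance(chunk, FixationChunk) else np.atleast_2d(np.asarray(chunk, float))
    if pts.shape[0] < 1:
        raise EmptyInputError("chunk must contain at least one sample")
    target = np.asarray(target, dtype=float)
    if not np.all(np.isfinite(target)):
        raise InvalidArgumentError("target must be finite")
    if np.allclose(pts, 0.0):
        raise DegenerateFitError("all-zero chunk coordinates: transform unidentifiable")
    if target.ndim == 1:
        return pts.mean(axis=0, keepdims=True), target[None, :]
    if target.shape != pts.shape:
        raise InvalidArgumentError("per-sample targets must match the chunk shape")
    return pts, target


def estimate_transform(
    chunk: FixationChunk | np.ndarray,
    target,
    *,
    max_iter: int = SIMPLEX_MAX_ITER,
    ftol: float = SIMPLEX_FTOL,
) -> TransformMatrix:
    """Fit T minimizing the summed squared correction residuals by simplex search.

    ``target`` is either a single ground-truth position (the fixation centroid
    is mapped onto it; the simplex starts at the identity, so an already-exact
    chunk yields the identity with M = 1 and a drifted chunk yields a
    near-identity solution whose determinant is diagnostic) or an (n, 2) array
    of per-sample desired coordinates (a fully determined least-squares
    problem). The search is restarted once from its own optimum — a standard
    Nelder-Mead polishing step — so the four entries are resolved to ~1e-5 even
    on elongated quadratic bowls.
    """
    src, dst = _fit_pairs(chunk, target)
    x0 = np.eye(2).ravel()
    opts = {"maxiter": max_iter, "fatol": ftol, "xatol": ftol}
    res = minimize(_objective, x0, args=(src, dst), method="Nelder-Mead", options=opts)
    res = minimize(_objective, res.x, args=(src, dst), method="Nelder-Mead", options=opts)
    return TransformMatrix(res.x.reshape(2, 2))


def least_squares_transform(points: np.ndarray, target) -> TransformMatrix:
    """Closed-form (normal equations) solution of the same objective.

    Kept as an independent cross-check of the simplex fit; the pipeline itself
    uses :func:`estimate_transform`. Requires a fully determined problem
    (per-sample targets with a full-rank source Gram matrix).
    """
    src, dst = _fit_pairs(points, target)
    gram = src.T @ src
    if np.linalg.matrix_rank(gram) < 2:
        raise DegenerateFitError("rank-deficient source points: least-squares transform not unique")
    return TransformMatrix(np.linalg.solve(gram, src.T @ dst))


@dataclass
class CalibrationEntry:
    """One calibration target with its validated transform."""

    position: np.ndarray
    transform: TransformMatrix
    provenance: str = "fitted"  # or "replaced"

    @property
    def valid(self) -> bool:
        return self.provenance == "fitted"


@dataclass
class CalibrationModel:
    """The nine calibration targets S1..S9 paired with validated transforms."""

    entries: list[CalibrationEntry] = field(default_factory=list)

    @property
    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.entries])

    @property
    def transforms(self) -> list[TransformMatrix]:
        return [e.transform for e in self.entries]

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "position": e.position.tolist(),
                "matrix": e.transform.matrix.tolist(),
                "M": e.transform.M,
                "provenance": e.provenance,
            }
            for e in self.entries
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            [
                CalibrationEntry(
                    np.asarray(rec["position"], float),
                    TransformMatrix(np.asarray(rec["matrix"], float)),
                    rec.get("provenance", "fitted"),
                )
                for rec in payload
            ]
        )


def build_calibration_model(
    chunks: Sequence[FixationChunk],
    targets: Sequence[Sequence[float]],
    m_threshold: float = M_THRESHOLD,
) -> CalibrationModel:
    """Fit and validate one transform per calibration point.

    A transform with ``M < m_threshold`` is rejected and replaced by the
    elementwise mean of the transforms of the 2 nearest calibration points that
    passed validation. More than 3 rejections — or fewer than 2 valid
    neighbours for a replacement — raise :class:`RecalibrationRequired`.
    """
    if len(chunks) != len(targets):
        raise InvalidArgumentError("need one chunk per calibration target")
    positions = np.asarray(targets, dtype=float)
    fitted = [estimate_transform(c, p) for c, p in zip(chunks, positions)]
    failing = [i for i, T in enumerate(fitted) if T.M < m_threshold]
    if len(failing) > 3:
        raise RecalibrationRequired(
            f"{len(failing)} transforms failed M >= {m_threshold}; capture fresh data"
        )
    valid_idx = [i for i in range(len(fitted)) if i not in failing]
    entries = [CalibrationEntry(positions[i], fitted[i]) for i in range(len(fitted))]
    for i in failing:
        if len(valid_idx) < 2:
            raise RecalibrationRequired("fewer than 2 valid neighbours for replacement")
        d = np.linalg.norm(positions[valid_idx] - positions[i], axis=1)
        order = np.argsort(d, kind="stable")[:2]
        nbrs = [valid_idx[j] for j in order]
        mean_T = (fitted[nbrs[0]].matrix + fitted[nbrs[1]].matrix) / 2.0
        entries[i] = CalibrationEntry(positions[i], TransformMatrix(mean_T), "replaced")
    return CalibrationModel(entries)


def nearest_references(
    point: Sequence[float], refs: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the n nearest reference positions, ascending.

    Ties are broken toward the lower reference index (stable sort).
    """
    refs = np.atleast_2d(np.asarray(refs, dtype=float))
    if refs.shape[0] == 0:
        raise EmptyInputError("no reference points")
    if n > refs.shape[0]:
        raise InvalidArgumentError("n exceeds the number of reference points")
    d = np.linalg.norm(refs - np.asarray(point, dtype=float), axis=1)
    idx = np.argsort(d, kind="stable")[:n]
    return idx, d[idx]


def inverse_weighted_correction(
    chunk: FixationChunk,
    transforms: Sequence[TransformMatrix],
    distances: Sequence[float],
    p: float = IWF_EXPONENT,
) -> FixationChunk:
    """Combine per-neighbour corrections with weights ``1/d^p``.

    When some distance is exactly zero the combination degenerates to that
    neighbour's correction alone. Otherwise the normalized weights form a
    convex combination of the transformed chunks.
    """
    if len(transforms) < 1 or len(transforms) != len(distances):
        raise InvalidArgumentError("need one distance per transform")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise InvalidArgumentError("distances must be non-negative")
    zero = np.flatnonzero(d == 0)
    if zero.size:
        return chunk.with_xy(transforms[int(zero[0])].apply(chunk.xy))
    w = 1.0 / d**p
    w /= w.sum()
    out = np.zeros_like(chunk.xy)
    for wi, Ti in zip(w, transforms):
        out += wi * Ti.apply(chunk.xy)
    return chunk.with_xy(out)


PATH_NEIGHBOURS = {"A": 1, "B": 4, "C": 4, "D": 2}


def correct_path(
    chunk: FixationChunk,
    path: str,
    *,
    calibration: CalibrationModel | None = None,
    stimulus_positions: np.ndarray | None = None,
    p: float = IWF_EXPONENT,
    label_convention: str = "algorithm",
) -> FixationChunk:
    """Apply one of the four correction paths to a (variable-error-filtered) chunk.

    Paths A/B are supervised (need a :class:`CalibrationModel`); C/D are
    unsupervised (need stimulus positions, against which fresh transforms are
    fitted). ``label_convention="prose"`` swaps the A/B neighbour counts to
    match the running-text naming instead of the pseudocode naming.
    """
    path = path.upper()
    if path not in PATH_NEIGHBOURS:
        raise InvalidArgumentError(f"unknown path {path!r}")
    if label_convention not in ("algorithm", "prose"):
        raise InvalidArgumentError("label_convention must be 'algorithm' or 'prose'")
    if label_convention == "prose" and path in ("A", "B"):
        path = "B" if path == "A" else "A"
    n = PATH_NEIGHBOURS[path]
    centroid = chunk.centroid

    if path in ("A", "B"):
        if calibration is None:
            raise InvalidArgumentError(f"path {path} requires a CalibrationModel")
        refs = calibration.positions
        if refs.shape[0] < n:
            raise InvalidArgumentError("insufficient calibration points for this path")
        idx, dist = nearest_references(centroid, refs, n)
        transforms = [calibration.transforms[i] for i in idx]
    else:
        if stimulus_positions is None:
            raise InvalidArgumentError(f"path {path} requires stimulus positions")
        refs = np.atleast_2d(np.asarray(stimulus_positions, dtype=float))
        if refs.shape[0] < n:
            raise InvalidArgumentError("insufficient stimulus points for this path")
        idx, dist = nearest_references(centroid, refs, n)
        transforms = [estimate_transform(chunk, refs[i]) for i in idx]

    if n == 1:
        return chunk.with_xy(transforms[0].apply(chunk.xy))
    return inverse_weighted_correction(chunk, transforms, dist, p=p)
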