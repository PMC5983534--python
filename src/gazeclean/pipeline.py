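"""Pipeline orchestration: fixation extraction -> variable-error removal
(graph filter, then Kalman) -> systematic-error removal (path A/B/C/D) ->
evaluation, as one configured, deterministic run."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import correction, fixation, gsp, kalman, metrics
from .correction import CalibrationModel
from .errors import CalibrationIncomplete, EmptyInputError, InvalidArgumentError
from .gaze_io import ClickEvent, FixationChunk, GazeTrace, segment_by_clicks
from .geometry import ScreenGeometry
from .synth import StimulusLayout, SyntheticSession

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FixationConfig:
    velocity_threshold: float = 20.0
    velocity_units: str = "px_per_sample"
    min_fixation_samples: int = 4


@dataclass(frozen=True)
class KalmanConfig:
    phi1_scale: float = 4.0
    phi2_scale: float = 25.0
    default_ar: tuple[float, float, float] = kalman.DEFAULT_AR
    fit_min_samples: int = kalman.MIN_AR_SAMPLES


@dataclass(frozen=True)
class CorrectionConfig:
    m_threshold: float = correction.M_THRESHOLD
    p: float = correction.IWF_EXPONENT
    path_label_convention: str = "algorithm"


@dataclass(frozen=True)
class MetricsConfig:
    aoi_shape: str = "rectangle"
    radius_method: str = "max"


@dataclass
class PipelineConfig:
    """All stage configurations plus the correction path selection."""

    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    fixation: FixationConfig = field(default_factory=FixationConfig)
    gsp: gsp.GSPConfig = field(default_factory=gsp.GSPConfig)
    kalman: KalmanConfig = field(default_factory=KalmanConfig)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    path: str = "D"
    window_s: float = 2.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        return replace(
            cfg,
            geometry=ScreenGeometry(**raw.get("geometry", {})) if "geometry" in raw else cfg.geometry,
            fixation=FixationConfig(**raw.get("fixation", {})),
            gsp=gsp.GSPConfig(**raw.get("gsp", {})),
            kalman=KalmanConfig(**{**raw.get("kalman", {}),
                                   **({"default_ar": tuple(raw["kalman"]["default_ar"])}
                                      if "kalman" in raw and "default_ar" in raw["kalman"] else {})}),
            correction=CorrectionConfig(**raw.get("correction", {})),
            metrics=MetricsConfig(**raw.get("metrics", {})),
            path=raw.get("path", cfg.path),
            window_s=raw.get("window_s", cfg.window_s),
        )


@dataclass
class ChunkRecord:
    """Before/after stages of one fixation chunk through the pipeline."""

    target_id: int | str | None
    raw: FixationChunk
    gsp_filtered: FixationChunk
    kf_filtered: FixationChunk
    corrected: FixationChunk


@dataclass
class EvaluationReport:
    """Per-chunk metric rows plus the aggregate summary."""

    per_chunk: pd.DataFrame
    aggregate: dict

    def to_files(self, csv_path: str | Path, json_path: str | Path) -> None:
        import json

        self.per_chunk.to_csv(csv_path, index=False, float_format="%.9g")
        Path(json_path).write_text(json.dumps(self.aggregate, indent=1, default=float))


def _extract_fixation_chunks(trace: GazeTrace, cfg: PipelineConfig) -> list[FixationChunk]:
    fc = cfg.fixation
    return fixation.extract_fixations(
        trace,
        v_threshold=fc.velocity_threshold,
        min_len=fc.min_fixation_samples,
        units=fc.velocity_units,
        geom=cfg.geometry,
    )


def variable_error_filter(
    raw_chunks: Sequence[FixationChunk],
    cfg: PipelineConfig,
    fs: float,
    mode: str = "gsp+kf",
) -> list[FixationChunk]:
    """Apply the variable-error stage(s) to a batch of chunks.

    ``mode`` selects the chain: ``"gsp"``, ``"kf"`` or ``"gsp+kf"``. The AR(3)
    velocity model is fitted once per batch (per session) on the input to the
    Kalman stage, falling back to the configured default coefficients when the
    pooled velocity series is too short.
    """
    if mode not in ("gsp", "kf", "gsp+kf"):
        raise InvalidArgumentError("mode must be 'gsp', 'kf' or 'gsp+kf'")
    chunks = list(raw_chunks)
    if mode in ("gsp", "gsp+kf"):
        chunks = [gsp.gsp_filter_trace(c, cfg.gsp) for c in chunks]
    if mode in ("kf", "gsp+kf"):
        try:
            ar_x, ar_y = kalman.fit_session_ar(chunks, fs)
        except Exception:  # pragma: no cover - extremely degenerate sessions
            ar_x = ar_y = kalman.ARCoefficients(*cfg.kalman.default_ar)
        model = kalman.build_state_space(
            ar_x, ar_y, fs, cfg.kalman.phi1_scale, cfg.kalman.phi2_scale
        )
        chunks = [kalman.kalman_smooth(c, model) for c in chunks]
    return chunks


def run_pipeline(
    trace: GazeTrace,
    clicks: Sequence[ClickEvent],
    layout: StimulusLayout,
    config: PipelineConfig,
    calibration: CalibrationModel | None = None,
) -> tuple[list[ChunkRecord], EvaluationReport]:
    """Execute the full chain over the click-segmented fixations of a session.

    For every click, the 2-second window before it is segmented, the longest
    fixation chunk in the window is taken as the gaze event on the clicked
    target, filtered (graph filter then Kalman), and corrected along the
    configured path. The report carries per-chunk smoothness ratio, closeness
    before/after filtering, and raw/corrected AOI hits. Deterministic given
    inputs and configuration.
    """
    if config.path in ("A", "B") and calibration is None:
        raise InvalidArgumentError(f"path {config.path} requires a calibration model")

    raw_chunks: list[FixationChunk] = []
    for click, sub in segment_by_clicks(trace, clicks, config.window_s):
        found = _extract_fixation_chunks(sub, config)
        if not found:
            logger.warning("no fixation chunk in window before click at t=%.3f", click.t)
            continue
        best = max(found, key=len)
        best.target_id = click.target_id
        raw_chunks.append(best)
    if not raw_chunks:
        raise EmptyInputError("no fixation chunks found in any click window")

    gsp_chunks = [gsp.gsp_filter_trace(c, config.gsp) for c in raw_chunks]
    try:
        ar_x, ar_y = kalman.fit_session_ar(gsp_chunks, trace.fs)
    except Exception:  # pragma: no cover
        ar_x = ar_y = kalman.ARCoefficients(*config.kalman.default_ar)
    model = kalman.build_state_space(
        ar_x, ar_y, trace.fs, config.kalman.phi1_scale, config.kalman.phi2_scale
    )
    kf_chunks = [kalman.kalman_smooth(c, model) for c in gsp_chunks]

    corrected = [
        correction.correct_path(
            c,
            config.path,
            calibration=calibration,
            stimulus_positions=layout.positions,
            p=config.correction.p,
            label_convention=config.correction.path_label_convention,
        )
        for c in kf_chunks
    ]

    records = [
        ChunkRecord(r.target_id, r, g, k, c)
        for r, g, k, c in zip(raw_chunks, gsp_chunks, kf_chunks, corrected)
    ]
    report = evaluate_records(records, layout, config)
    return records, report


def evaluate_records(
    records: Sequence[ChunkRecord], layout: StimulusLayout, config: PipelineConfig
) -> EvaluationReport:
    """Build the evaluation report from staged chunk records."""
    shape = config.metrics.aoi_shape
    method = config.metrics.radius_method
    rows = []
    for rec in records:
        aoi = layout.aoi(rec.target_id, shape) if rec.target_id is not None else None
        rows.append(
            {
                "target_id": rec.target_id,
                "n_samples": len(rec.raw),
                "sr": metrics.smoothness_ratio(rec.raw, rec.kf_filtered, method),
                "cl_raw": metrics.closeness(rec.raw),
                "cl_filtered": metrics.closeness(rec.kf_filtered),
                "raw_hit": bool(aoi and metrics.aoi_contains(aoi, rec.raw.centroid)),
                "corrected_hit": bool(aoi and metrics.aoi_contains(aoi, rec.corrected.centroid)),
            }
        )
    df = pd.DataFrame(rows)
    finite_sr = df["sr"][np.isfinite(df["sr"])]
    aggregate = {
        "n_chunks": int(len(df)),
        "path": config.path,
        "aoi_shape": shape,
        "accuracy_raw_pct": 100.0 * df["raw_hit"].mean(),
        "accuracy_corrected_pct": 100.0 * df["corrected_hit"].mean(),
        "mean_sr": float(finite_sr.mean()) if len(finite_sr) else float("inf"),
        "mean_cl_raw": float(df["cl_raw"].mean()),
        "mean_cl_filtered": float(df["cl_filtered"].mean()),
    }
    return EvaluationReport(df, aggregate)


def calibrate(
    trace: GazeTrace,
    dwell_windows: Sequence[tuple[int | str, float, float]],
    layout: StimulusLayout,
    config: PipelineConfig,
) -> CalibrationModel:
    """Build a calibration model from the nine static dwells of one session.

    The central 60% of each dwell window is taken (trimming entry/exit
    transients), variable-error filtered, and fitted against the corresponding
    calibration target; the per-point transforms are then validated by the
    determinant rule.
    """
    if len(dwell_windows) != len(layout.entities):
        raise CalibrationIncomplete(
            f"need {len(layout.entities)} dwell windows, got {len(dwell_windows)}"
        )
    raw_chunks, targets = [], []
    for target_id, t0, t1 in dwell_windows:
        span = t1 - t0
        lo, hi = t0 + 0.2 * span, t1 - 0.2 * span
        mask = (trace.t >= lo) & (trace.t <= hi) & trace.valid
        if mask.sum() < 2:
            raise CalibrationIncomplete(f"dwell on {target_id!r} has too few samples")
        idx = np.flatnonzero(mask)
        raw_chunks.append(
            FixationChunk(trace.xy[mask], int(idx[0]), int(idx[-1]), t=trace.t[mask])
        )
        targets.append(layout.entity(target_id).position)

    filtered = variable_error_filter(raw_chunks, config, trace.fs, mode="gsp+kf")
    return correction.build_calibration_model(
        filtered, np.array(targets), config.correction.m_threshold
    )


def calibrate_session(session: SyntheticSession, config: PipelineConfig) -> CalibrationModel:
    """Convenience wrapper: calibrate from a synthetic calibration session."""
    return calibrate(session.trace, session.dwell_windows(), session.layout, config)


def per_minute_closeness(
    session: SyntheticSession, config: PipelineConfig
) -> pd.DataFrame:
    """Minute-by-minute raw vs filtered closeness over a (long) session.

    Raw closeness is computed on each dwell window's unprocessed samples (the
    2-second gaze events, artifacts included); filtered closeness on the
    fixation samples of the same window after the graph + Kalman chain, pooled
    around the window's filtered centroid (pooling per gaze event rather than
    per fixation fragment keeps the measure independent of how artifacts split
    a dwell into chunks). Windows are assigned to the minute containing their
    start; each minute's value is the sample-weighted mean over its windows.
    """
    windows = session.dwell_windows()
    if not windows:
        raise EmptyInputError("session has no dwell windows")
    trace = session.trace

    rows = []
    fix_chunks: list[FixationChunk] = []
    fix_rows: list[int] = []
    for target_id, t0, t1 in windows:
        mask = (trace.t >= t0) & (trace.t <= t1) & trace.valid
        if mask.sum() < 2:
            continue
        idx = np.flatnonzero(mask)
        sub = trace.slice(int(idx[0]), int(idx[-1]) + 1)
        raw = FixationChunk(sub.xy, int(idx[0]), int(idx[-1]), t=sub.t)
        row = {"minute": int(t0 // 60), "n_raw": len(raw),
               "cl_raw": metrics.closeness(raw)}
        for c in _extract_fixation_chunks(sub, config):
            fix_chunks.append(c)
            fix_rows.append(len(rows))
        rows.append(row)

    filtered = variable_error_filter(fix_chunks, config, trace.fs, mode="gsp+kf")
    window_pts: dict[int, list[np.ndarray]] = {}
    for row_i, c in zip(fix_rows, filtered):
        window_pts.setdefault(row_i, []).append(c.xy)
    ssq = np.zeros(len(rows))
    nfil = np.zeros(len(rows))
    for row_i, parts in window_pts.items():
        pts = np.vstack(parts)
        ssq[row_i] = float(np.sum((pts - pts.mean(axis=0)) ** 2))
        nfil[row_i] = len(pts)
    df = pd.DataFrame(rows)
    df["ssq_filtered"] = ssq
    df["n_filtered"] = nfil
    grouped = df.groupby("minute").apply(
        lambda g: pd.Series(
            {
                "cl_raw": np.average(g["cl_raw"], weights=g["n_raw"]),
                "cl_filtered": g["ssq_filtered"].sum() / max(g["n_filtered"].sum(), 1),
            }
        ),
        include_groups=False,
    )
    return grouped.reset_index()
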