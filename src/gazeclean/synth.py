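"""Ground-truthed synthetic gaze sessions.

Generates the three stimulus layouts used by the study design — a 9-point
calibration grid (corners, edge midpoints, centre), a single-row number-gazing
(NG) digit strip with 100/70/50 px spacing, and a 2-column recall-recognition
(RR) word grid — and simulates 30 Hz gaze traces over them:

* the clean trace dwells on each planned target and is joined by short linear
  saccadic ramps (or, for calibration, smooth-pursuit segments at the ball
  speed);
* variable error is isotropic Gaussian dispersion plus occasional short bursts
  of large abrupt displacement (head-jerk / blink-recovery artifacts);
* systematic error is a global 2x2 right-multiplication of the clean
  coordinates, so the linear correction class can in principle invert it
  exactly;
* a click event is emitted at the end of every test dwell.

Every random draw flows through one seeded generator, so equal seeds give
bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import EmptyInputError, InvalidArgumentError, LayoutOverflowError
from .gaze_io import ClickEvent, GazeTrace
from .geometry import ScreenGeometry, deg_to_px
from .metrics import AOI

NG_SPACINGS = (100, 70, 50)
RR_WORDS_PER_COLUMN = (3, 6, 12, 16)
NG_LEFT_MARGIN_PX = 100.0
NG_ROW_Y_PX = 150.0
#: digit glyph box width as a fraction of the font size
GLYPH_ASPECT = 0.6
CALIBRATION_MARGIN_FRAC = 0.08
CALIBRATION_DWELL_S = 5.0
PURSUIT_SPEED_DEG_S = 1.92


@dataclass(frozen=True)
class StimulusEntity:
    """One positioned stimulus: id, centre (px) and rendered extent (px)."""

    id: int | str
    x: float
    y: float
    width: float
    height: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class StimulusLayout:
    """Positioned stimulus entities with AOI definitions.

    AOIs are the rendered bounding box of each entity padded by a quarter of
    the free gap to the nearest neighbouring entity per side (never past the
    midline to a neighbour, so rectangle AOIs of one layout cannot overlap).
    Deliberately narrower than half the inter-stimulus spacing: the evaluation
    partition distinguishes correct region, wrong region and no-man's land, so
    AOIs must not tile the screen.
    """

    task: str
    entities: list[StimulusEntity]
    geom: ScreenGeometry = field(default_factory=ScreenGeometry)
    spacing: float | None = None

    @property
    def positions(self) -> np.ndarray:
        return np.array([[e.x, e.y] for e in self.entities])

    @property
    def ids(self) -> list:
        return [e.id for e in self.entities]

    def entity(self, target_id) -> StimulusEntity:
        for e in self.entities:
            if e.id == target_id:
                return e
        raise KeyError(f"no stimulus entity with id {target_id!r}")

    def _axis_limits(self, ent: StimulusEntity) -> tuple[float, float]:
        """Half of the smallest centre spacing to a mostly-horizontal /
        mostly-vertical neighbour (inf when there is none along that axis)."""
        lim_w = lim_h = float("inf")
        for other in self.entities:
            if other.id == ent.id:
                continue
            dx, dy = abs(other.x - ent.x), abs(other.y - ent.y)
            if dx > dy:
                lim_w = min(lim_w, dx / 2.0)
            else:
                lim_h = min(lim_h, dy / 2.0)
        return lim_w, lim_h

    def aoi(self, target_id, shape: str = "rectangle") -> AOI:
        ent = self.entity(target_id)
        lim_w, lim_h = self._axis_limits(ent)
        pad_x = (2 * lim_w - ent.width) / 4.0 if np.isfinite(lim_w) else ent.width / 2.0
        pad_y = (2 * lim_h - ent.height) / 4.0 if np.isfinite(lim_h) else ent.height / 2.0
        # a row/column layout pads its free axis like its constrained axis
        if not np.isfinite(lim_h):
            pad_y = pad_x if np.isfinite(lim_w) else pad_y
        if not np.isfinite(lim_w):
            pad_x = pad_y if np.isfinite(lim_h) else pad_x
        half_w = ent.width / 2.0 + max(pad_x, 0.5)
        half_h = ent.height / 2.0 + max(pad_y, 0.5)
        if np.isfinite(lim_w):
            half_w = min(half_w, lim_w - 0.1)
        if np.isfinite(lim_h):
            half_h = min(half_h, lim_h - 0.1)
        return AOI(shape, (ent.x, ent.y), (half_w, half_h), ent.id)


def gen_layout(
    task: str,
    *,
    spacing: float = 50,
    words_per_column: int = 6,
    geom: ScreenGeometry | None = None,
) -> StimulusLayout:
    """Deterministic stimulus positions for a calibration, NG or RR screen.

    NG digits sit in a single row anchored at a fixed left margin with the
    given centre-to-centre spacing and a 2:1 spacing-to-font-size ratio; RR
    words fill two columns; calibration points form the 3x3 grid of corners,
    edge midpoints and centre.
    """
    geom = geom or ScreenGeometry()
    import warnings

    if task == "calibration":
        xs = [CALIBRATION_MARGIN_FRAC * geom.width_px, geom.width_px / 2.0,
              (1 - CALIBRATION_MARGIN_FRAC) * geom.width_px]
        ys = [CALIBRATION_MARGIN_FRAC * geom.height_px, geom.height_px / 2.0,
              (1 - CALIBRATION_MARGIN_FRAC) * geom.height_px]
        entities = [
            StimulusEntity(f"S{3 * r + c + 1}", xs[c], ys[r], 20.0, 20.0)
            for r in range(3)
            for c in range(3)
        ]
        return StimulusLayout("calibration", entities, geom)

    if task == "ng":
        if spacing not in NG_SPACINGS:
            warnings.warn(f"NG spacing {spacing} px is outside the standard menu {NG_SPACINGS}")
        font = spacing / 2.0  # 2:1 spacing : font ratio
        width = GLYPH_ASPECT * font
        entities = [
            StimulusEntity(k, NG_LEFT_MARGIN_PX + (k - 1) * spacing, NG_ROW_Y_PX, width, font)
            for k in range(1, 10)
        ]
        if entities[-1].x + width / 2.0 > geom.width_px:
            raise LayoutOverflowError(f"NG spacing {spacing} px overflows a {geom.width_px}px screen")
        return StimulusLayout("ng", entities, geom, spacing=spacing)

    if task == "rr":
        if words_per_column not in RR_WORDS_PER_COLUMN:
            warnings.warn(
                f"{words_per_column} words/column is outside the standard menu {RR_WORDS_PER_COLUMN}"
            )
        n = words_per_column
        col_x = [0.35 * geom.width_px, 0.65 * geom.width_px]
        y_top, y_bot = 0.1 * geom.height_px, 0.9 * geom.height_px
        ys = np.linspace(y_top, y_bot, n)
        row_gap = (y_bot - y_top) / max(n - 1, 1)
        if row_gap < 10:
            raise LayoutOverflowError(f"{n} words/column overflow a {geom.height_px}px screen")
        entities = [
            StimulusEntity(col * n + r + 1, col_x[col], float(ys[r]), 120.0, 48.0)
            for col in range(2)
            for r in range(n)
        ]
        return StimulusLayout("rr", entities, geom)

    raise InvalidArgumentError(f"unknown task {task!r}")


@dataclass
class NoiseConfig:
    """Noise model for a synthetic session.

    ``sigma`` is the isotropic Gaussian dispersion of the variable error;
    abrupt-fluctuation artifacts are short bursts (``outlier_burst`` samples)
    of ``outlier_mag`` px displacement occurring with per-sample probability
    ``outlier_prob``; ``distortion`` is the 2x2 systematic-error map.
    """

    sigma: float = 8.0
    outlier_prob: float = 0.01
    outlier_mag: float = 200.0
    outlier_burst: int = 3
    distortion: np.ndarray = field(default_factory=lambda: np.eye(2))
    seed: int = 0

    def __post_init__(self) -> None:
        self.distortion = np.asarray(self.distortion, dtype=float)
        if self.sigma < 0 or not 0 <= self.outlier_prob <= 1:
            raise InvalidArgumentError("sigma must be >= 0 and outlier_prob in [0, 1]")
        if self.distortion.shape != (2, 2) or abs(np.linalg.det(self.distortion)) < 1e-12:
            raise InvalidArgumentError("distortion must be an invertible 2x2 matrix")


@dataclass
class SyntheticSession:
    """A simulated session with full per-sample ground truth."""

    trace: GazeTrace
    clicks: list[ClickEvent]
    truth_ids: np.ndarray  # per-sample intended target id (-1 during transitions)
    clean_xy: np.ndarray  # per-sample noise-free coordinates
    dwell_mask: np.ndarray  # True where the clean trace dwells on a target
    layout: StimulusLayout
    noise: NoiseConfig

    def dwell_windows(self) -> list[tuple[int | str, float, float]]:
        """(target_id, t_start, t_end) for every contiguous dwell segment."""
        out = []
        n = len(self.trace)
        i = 0
        while i < n:
            if not self.dwell_mask[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and self.dwell_mask[j + 1] and self.truth_ids[j + 1] == self.truth_ids[i]:
                j += 1
            out.append((self._id_of(i), float(self.trace.t[i]), float(self.trace.t[j])))
            i = j + 1
        return out

    def _id_of(self, i: int):
        raw = self.truth_ids[i]
        return self.layout.ids[int(raw)] if isinstance(raw, (int, np.integer)) else raw


def calibration_plan(layout: StimulusLayout, dwell_s: float = CALIBRATION_DWELL_S):
    """The nine 5-second static dwells of the calibration stimulus."""
    return [(e.id, dwell_s) for e in layout.entities]


def ng_plan(layout: StimulusLayout, pin: Sequence[int], dwell_s: float = 2.0):
    """Gaze-then-click plan over the digits of a pin."""
    return [(int(d), dwell_s) for d in pin]


def simulate_session(
    layout: StimulusLayout,
    plan: Sequence[tuple[int | str, float]],
    noise: NoiseConfig,
    fs: float = 30.0,
    *,
    seed: int | None = None,
    transition: str = "saccade",
    emit_clicks: bool | None = None,
) -> SyntheticSession:
    """Simulate one gaze session following ``plan`` (target id, dwell seconds).

    Transitions are 2-3 sample linear ramps (``"saccade"``) or constant-speed
    linear sweeps at the calibration ball speed (``"pursuit"``); transition
    samples carry truth id -1 and are excluded from the dwell mask. Clicks are
    emitted at the end of every dwell except for calibration layouts.
    """
    if len(plan) == 0:
        raise EmptyInputError("plan must contain at least one target")
    if transition not in ("saccade", "pursuit"):
        raise InvalidArgumentError("transition must be 'saccade' or 'pursuit'")
    if emit_clicks is None:
        emit_clicks = layout.task != "calibration"
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    pursuit_px_s = deg_to_px(PURSUIT_SPEED_DEG_S, layout.geom) * 1.0

    id_index = {e.id: i for i, e in enumerate(layout.entities)}
    clean_parts: list[np.ndarray] = []
    ids_parts: list[np.ndarray] = []
    dwell_parts: list[np.ndarray] = []
    click_sample_idx: list[tuple[int, int]] = []  # (sample index of dwell end, entity idx)

    pos = np.array(layout.geom.center)
    n_total = 0
    for target_id, dwell_s in plan:
        if target_id not in id_index:
            raise InvalidArgumentError(f"plan target {target_id!r} not in layout")
        if dwell_s <= 0:
            raise InvalidArgumentError("dwell durations must be positive")
        tgt = layout.entity(target_id).position
        dist = float(np.linalg.norm(tgt - pos))
        if dist > 0:
            if transition == "saccade":
                n_ramp = int(rng.integers(2, 4))  # 2-3 samples
            else:
                n_ramp = max(int(round(dist / pursuit_px_s * fs)), 2)
            frac = np.arange(1, n_ramp + 1)[:, None] / (n_ramp + 1)
            ramp = pos + frac * (tgt - pos)
            clean_parts.append(ramp)
            ids_parts.append(np.full(n_ramp, -1))
            dwell_parts.append(np.zeros(n_ramp, bool))
            n_total += n_ramp
        n_dwell = max(int(round(dwell_s * fs)), 1)
        clean_parts.append(np.tile(tgt, (n_dwell, 1)))
        ids_parts.append(np.full(n_dwell, id_index[target_id]))
        dwell_parts.append(np.ones(n_dwell, bool))
        n_total += n_dwell
        click_sample_idx.append((n_total - 1, id_index[target_id]))
        pos = tgt

    clean = np.vstack(clean_parts)
    truth_ids = np.concatenate(ids_parts)
    dwell_mask = np.concatenate(dwell_parts)
    t = np.arange(len(clean)) / fs

    observed = clean @ noise.distortion + rng.normal(0.0, noise.sigma, clean.shape)
    _inject_bursts_bernoulli(observed, noise, rng)

    clicks = []
    if emit_clicks:
        for si, ei in click_sample_idx:
            ent = layout.entities[ei]
            clicks.append(ClickEvent(float(t[si]), ent.x, ent.y, ent.id))
    trace = GazeTrace(t, observed, np.ones(len(t), bool), fs)
    return SyntheticSession(trace, clicks, truth_ids, clean, dwell_mask, layout, noise)


def _inject_bursts_bernoulli(observed: np.ndarray, noise: NoiseConfig, rng) -> None:
    """Add abrupt-fluctuation bursts at per-sample Bernoulli start points."""
    if noise.outlier_prob <= 0 or noise.outlier_mag <= 0:
        return
    n = observed.shape[0]
    starts = np.flatnonzero(rng.random(n) < noise.outlier_prob)
    for s in starts:
        theta = rng.uniform(0, 2 * np.pi)
        disp = noise.outlier_mag * np.array([np.cos(theta), np.sin(theta)])
        observed[s : s + noise.outlier_burst] += disp


def long_session(
    layout: StimulusLayout,
    duration_s: float,
    noise: NoiseConfig,
    fatigue_ramp: float = 0.0,
    fs: float = 30.0,
    *,
    seed: int | None = None,
    base_artifacts_per_min: float = 3.0,
    dwell_s: float = 2.0,
) -> SyntheticSession:
    """A long number-gazing session with a fatigue-driven artifact ramp.

    Random 4-digit pins are gazed (2 s dwell + click each) until ``duration_s``
    is reached. Fatigue is modelled as a growing rate of large transient
    artifacts — minute ``m`` of the session carries exactly
    ``round(base_artifacts_per_min * (1 + fatigue_ramp * m))`` bursts of
    ``noise.outlier_mag`` px at seeded random positions within that minute's
    dwells — reflecting that exhausted participants produce abrupt glitches
    (head jerks, blink recoveries) rather than a uniform inflation of
    fixational dispersion. The Gaussian dispersion stays at ``noise.sigma``
    throughout, which is what lets a velocity-gated smoothing chain hold its
    output quality while raw quality degrades.
    """
    if duration_s <= 0:
        raise InvalidArgumentError("duration_s must be positive")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    digit_ids = [e.id for e in layout.entities]
    plan = []
    t_acc = 0.0
    while t_acc < duration_s:
        pin = rng.choice(digit_ids, size=4, replace=False)
        for d in pin:
            plan.append((int(d), dwell_s))
            t_acc += dwell_s
            if t_acc >= duration_s:
                break

    base = replace(noise, outlier_prob=0.0)
    session = simulate_session(
        layout, plan, base, fs, seed=int(rng.integers(0, 2**31 - 1)), emit_clicks=True
    )

    observed = session.trace.xy
    n = len(observed)
    burst = noise.outlier_burst
    # burst may start where it stays inside one dwell (so every artifact lands
    # fully inside a single gaze event, never straddling a transition)
    ok = session.dwell_mask.copy()
    for k in range(1, burst):
        ok[:-k] &= session.dwell_mask[k:]
    ok[-burst:] = False
    n_minutes = int(np.ceil(n / (60.0 * fs)))
    for m in range(n_minutes):
        lo, hi = int(m * 60 * fs), min(int((m + 1) * 60 * fs), n)
        slots = lo + np.flatnonzero(ok[lo:hi])
        if slots.size == 0:
            continue
        count = int(round(base_artifacts_per_min * (1.0 + fatigue_ramp * m)))
        # artifacts are isolated events: keep starts at least one burst
        # length (plus recovery sample) apart so bursts never fuse
        order = rng.permutation(slots)
        starts: list[int] = []
        for s in order:
            if all(abs(s - a) > burst + 1 for a in starts):
                starts.append(int(s))
                if len(starts) >= count:
                    break
        for s in sorted(starts):
            theta = rng.uniform(0, 2 * np.pi)
            disp = noise.outlier_mag * np.array([np.cos(theta), np.sin(theta)])
            observed[s : s + burst] += disp
    return session
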