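"""Kalman smoothing of gaze chunks with AR(3) velocity dynamics.

The state is 8-dimensional: ``(x, y, vx, vy, vx_lag1, vy_lag1, vx_lag2,
vy_lag2)`` — position plus three lags of the per-axis velocity. A 4-component
state (one velocity per axis) cannot realize a third-order autoregression; carrying two extra
velocity lags per axis is the minimal linear realization of

    p_k = p_{k-1} + T * v_{k-1}
    v_k = a1 * v_{k-1} + a2 * v_{k-2} + a3 * v_{k-3} + noise

with ``T = 1/fs``. The AR coefficients are fitted per session by conditional
least squares on the graph-filtered velocities; the AR intercept is absorbed
into the zero-mean process noise. Positions are measured directly; the filter
runs the standard predict/update recursion and returns the posterior means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ARFitError, EmptyInputError, InvalidArgumentError, InvalidModelError
from .gaze_io import FixationChunk

#: Fallback AR weights when a session yields too few velocity samples to fit.
DEFAULT_AR = (0.4, 0.2, 0.1)
#: Fallback velocity innovation variance, (px/s)^2 — roughly the one-step
#: velocity variability of a 1-2 px fixational jitter sampled at 30 Hz.
DEFAULT_INNOVATION_VAR = 2500.0
MIN_AR_SAMPLES = 30


@dataclass(frozen=True)
class ARCoefficients:
    """AR(3) weights for one velocity axis, plus intercept and innovation variance."""

    a1: float
    a2: float
    a3: float
    intercept: float = 0.0
    innovation_var: float = 0.0

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3])


def fit_ar3(velocities: np.ndarray) -> ARCoefficients:
    """Fit an AR(3) with intercept to one axis's velocity series.

    Uses conditional least squares (statsmodels ``AutoReg``). A constant series
    has no autoregressive structure and returns all-zero weights; fewer than
    ``MIN_AR_SAMPLES`` finite samples raises :class:`ARFitError` so callers can
    fall back to :data:`DEFAULT_AR`.
    """
    v = np.asarray(velocities, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < MIN_AR_SAMPLES:
        raise ARFitError(
            f"need >= {MIN_AR_SAMPLES} finite velocity samples, got {len(v)}; "
            "fall back to DEFAULT_AR"
        )
    if np.ptp(v) == 0:  # constant series: degenerate variance
        return ARCoefficients(0.0, 0.0, 0.0, float(v[0]), 0.0)
    from statsmodels.tsa.ar_model import AutoReg

    res = AutoReg(v, lags=3, trend="c").fit()
    c, a1, a2, a3 = (float(p) for p in res.params)
    return ARCoefficients(a1, a2, a3, c, float(res.sigma2))


@dataclass
class StateSpaceModel:
    """Linear-Gaussian model over the 8-dim position/velocity-lag state."""

    F: np.ndarray  # 8x8 transition
    H: np.ndarray  # 2x8 measurement map (selects x, y)
    phi1: np.ndarray  # 8x8 process noise covariance
    phi2: np.ndarray  # 2x2 measurement noise covariance
    T: float  # sampling period, seconds
    init_pos_var: float = 25.0
    init_vel_var: float = 1e4

    def validate(self) -> None:
        for name, m in (("F", self.F), ("H", self.H), ("phi1", self.phi1), ("phi2", self.phi2)):
            if not np.all(np.isfinite(m)):
                raise InvalidModelError(f"{name} contains non-finite entries")
        for name, m in (("phi1", self.phi1), ("phi2", self.phi2)):
            if not np.allclose(m, m.T):
                raise InvalidModelError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(m)) < -1e-10:
                raise InvalidModelError(f"{name} must be positive semidefinite")


def build_state_space(
    ar_x: ARCoefficients,
    ar_y: ARCoefficients,
    fs: float,
    phi1_scale: float = 4.0,
    phi2_scale: float = 25.0,
) -> StateSpaceModel:
    """Assemble F, H and the noise covariances from per-axis AR(3) weights.

    The process noise excites only the current-velocity states (the lag copies
    are deterministic shifts) and is set per axis to ``phi1_scale`` times the
    AR fit's own innovation variance — the velocity model's estimate of its
    one-step unpredictability — falling back to
    :data:`DEFAULT_INNOVATION_VAR` when the fit reports none. ``phi2_scale``
    (px^2) is the isotropic measurement noise on x and y.
    """
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    T = 1.0 / fs
    F = np.zeros((8, 8))
    # positions: p_k = p_{k-1} + T * v_{k-1}
    F[0, 0] = F[1, 1] = 1.0
    F[0, 2] = F[1, 3] = T
    # velocities: AR(3) recursion per axis
    for axis, ar in ((0, ar_x), (1, ar_y)):
        F[2 + axis, 2 + axis] = ar.a1
        F[2 + axis, 4 + axis] = ar.a2
        F[2 + axis, 6 + axis] = ar.a3
    # lag shifting
    F[4, 2] = F[5, 3] = 1.0
    F[6, 4] = F[7, 5] = 1.0

    H = np.zeros((2, 8))
    H[0, 0] = H[1, 1] = 1.0

    phi1 = np.zeros((8, 8))
    for axis, ar in ((0, ar_x), (1, ar_y)):
        innov = ar.innovation_var if ar.innovation_var > 0 else DEFAULT_INNOVATION_VAR
        phi1[2 + axis, 2 + axis] = phi1_scale * innov
    phi2 = phi2_scale * np.eye(2)
    model = StateSpaceModel(F, H, phi1, phi2, T, init_pos_var=max(phi2_scale, 1e-12))
    model.validate()
    return model


def simulate_state_space(model: StateSpaceModel, x0: np.ndarray, n_steps: int) -> np.ndarray:
    """Noise-free rollout of the transition matrix; returns (n_steps+1, 8) states."""
    states = np.empty((n_steps + 1, 8))
    states[0] = np.asarray(x0, dtype=float)
    for k in range(n_steps):
        states[k + 1] = model.F @ states[k]
    return states


def kalman_smooth(chunk: FixationChunk, model: StateSpaceModel) -> FixationChunk:
    """Run the forward predict/update recursion over one chunk's coordinates.

    The first posterior mean is the first measurement with zero velocities; the
    initial covariance puts the measurement variance on the positions and a
    large variance on the velocity states. The posterior covariance is
    re-symmetrized after every update to keep it PSD. Output positions are the
    posterior means' (x, y) components; sample count is preserved.
    """
    if len(chunk) == 0:
        raise EmptyInputError("chunk must be non-empty")
    model.validate()
    F, H, Q, R = model.F, model.H, model.phi1, model.phi2
    n = len(chunk)
    out = np.empty((n, 2))

    mean = np.zeros(8)
    mean[:2] = chunk.xy[0]
    P = np.diag([model.init_pos_var] * 2 + [model.init_vel_var] * 6).astype(float)
    out[0] = mean[:2]

    eye = np.eye(8)
    for k in range(1, n):
        # predict
        mean = F @ mean
        P = F @ P @ F.T + Q
        # update
        z = chunk.xy[k]
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        mean = mean + K @ (z - H @ mean)
        P = (eye - K @ H) @ P
        P = 0.5 * (P + P.T)
        out[k] = mean[:2]
    return chunk.with_xy(out)


def fit_session_ar(
    chunks: list[FixationChunk], fs: float
) -> tuple[ARCoefficients, ARCoefficients]:
    """Per-session AR(3) fit on pooled within-chunk velocities (px/s per axis).

    Falls back to :data:`DEFAULT_AR` when the pooled series is too short.
    """
    vx_parts, vy_parts = [], []
    for c in chunks:
        if len(c) >= 2:
            d = np.diff(c.xy, axis=0) * fs
            vx_parts.append(d[:, 0])
            vy_parts.append(d[:, 1])
    vx = np.concatenate(vx_parts) if vx_parts else np.empty(0)
    vy = np.concatenate(vy_parts) if vy_parts else np.empty(0)
    try:
        return fit_ar3(vx), fit_ar3(vy)
    except ARFitError:
        fallback = ARCoefficients(*DEFAULT_AR)
        return fallback, fallback
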