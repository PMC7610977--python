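"""Simulated manipulandum: a damped point-mass plant under PID control.

The physical device is a planar robotic arm whose handle passively guides
the subject's non-controlling hand along the cursor trajectory, providing
artificial proprioceptive feedback.  Here the handle is modelled as a point
mass with viscous damping, driven by a PID controller toward a reference
(the cursor, or its mirror image about the vertical midline in the
incongruent-feedback protocol).  Only the fidelity of the delivered
feedback signal matters to the analysis, so arm kinematics, motor torque
models and encoder quantization are not modelled.

The controller applies, per axis,

    F = Kp * e + Ki * integral(e) - Kd * v ,

with ``e`` the position error and ``v`` the handle velocity (derivative on
the measurement, which avoids derivative kick on reference steps).  Force is
clipped to a limit, and the error integrator is frozen on any axis whose
force is saturated (anti-windup).  Integration is semi-implicit Euler at
the display rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlantParams",
    "PlantState",
    "step",
    "simulate_tracking",
    "mirror_reference",
    "TrackingAccuracy",
    "tracking_accuracy",
    "lag_of_max_cross_covariance",
]

DEFAULT_DT = 1.0 / 75.0


@dataclass(frozen=True)
class PlantParams:
    """Plant and controller parameters.

    Units: position cm, mass kg, damping N*s/cm, gains N/cm (Kp),
    N/(cm*s) (Ki), N*s/cm (Kd), force limit N.  Defaults give smooth,
    slightly sluggish low-frequency tracking: the real device was tuned to
    follow only the low-frequency content of the cursor to keep the motion
    feedback free of vibration.
    """

    mass: float = 1.0
    damping: float = 5.0
    kp: float = 200.0
    ki: float = 60.0
    kd: float = 25.0
    force_limit: float = 300.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.damping < 0:
            raise ValueError("damping must be non-negative")
        if self.force_limit <= 0:
            raise ValueError("force limit must be positive")


@dataclass
class PlantState:
    """Instantaneous handle state."""

    position: np.ndarray = field(default_factory=lambda: np.zeros(2))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    integrator: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).copy()
        self.velocity = np.asarray(self.velocity, dtype=float).copy()
        self.integrator = np.asarray(self.integrator, dtype=float).copy()


def step(
    state: PlantState,
    reference,
    params: PlantParams,
    dt: float = DEFAULT_DT,
) -> PlantState:
    """Advance the plant one control interval toward ``reference``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    reference = np.asarray(reference, dtype=float)
    if not (np.all(np.isfinite(reference)) and np.all(np.isfinite(state.position))):
        raise ValueError("non-finite reference or plant state")
    error = reference - state.position
    force = params.kp * error + params.ki * state.integrator - params.kd * state.velocity
    clipped = np.clip(force, -params.force_limit, params.force_limit)
    # anti-windup: only integrate on axes whose actuator is not saturated
    unsaturated = np.abs(force) <= params.force_limit
    integrator = state.integrator + np.where(unsaturated, error * dt, 0.0)
    # semi-implicit Euler; the viscous term is taken implicitly so the
    # update is unconditionally stable for any damping/mass ratio
    velocity = (state.velocity + clipped / params.mass * dt) / (
        1.0 + params.damping / params.mass * dt
    )
    position = state.position + velocity * dt
    return PlantState(position, velocity, integrator)


def simulate_tracking(
    reference_trajectory,
    params: PlantParams | None = None,
    dt: float = DEFAULT_DT,
    initial_state: PlantState | None = None,
) -> np.ndarray:
    """Run the plant along a reference trajectory; returns handle positions.

    The handle position recorded at frame ``k`` is the state reached after
    reacting to reference frame ``k`` (the handle therefore lags the cursor
    by at least one control interval, as a causal plant must).
    """
    params = params or PlantParams()
    ref = np.atleast_2d(np.asarray(reference_trajectory, dtype=float))
    state = initial_state or PlantState(position=ref[0].copy())
    out = np.empty_like(ref)
    for k, r in enumerate(ref):
        state = step(state, r, params, dt)
        out[k] = state.position
    return out


def mirror_reference(position) -> np.ndarray:
    """Mirror a position about the vertical midline through the start:
    (x, y) -> (-x, y)."""
    p = np.asarray(position, dtype=float)
    out = p.copy()
    out[..., 0] = -out[..., 0]
    return out


def lag_of_max_cross_covariance(
    cursor: np.ndarray,
    handle: np.ndarray,
    max_lag: int,
) -> int:
    """Lag (in frames, handle relative to cursor) maximizing cross-covariance.

    Positive lag means the handle trails the cursor.  The covariance is
    summed over both axes; ties resolve to the smallest absolute lag.
    """
    cursor = np.atleast_2d(cursor)
    handle = np.atleast_2d(handle)
    n = cursor.shape[0]
    if handle.shape[0] != n:
        raise ValueError("trajectories must have equal length")
    best_lag, best_cov = 0, -np.inf
    for lag in sorted(range(-max_lag, max_lag + 1), key=abs):
        if lag >= 0:
            c, h = cursor[: n - lag], handle[lag:]
        else:
            c, h = cursor[-lag:], handle[: n + lag]
        if c.shape[0] < 2:
            continue
        cov = float(
            np.sum((c - c.mean(axis=0)) * (h - h.mean(axis=0))) / (c.shape[0] - 1)
        )
        if cov > best_cov:
            best_lag, best_cov = lag, cov
    return best_lag


@dataclass(frozen=True)
class TrackingAccuracy:
    """Tracking-fidelity summary of a set of trials (one table cell).

    ``r_x``/``r_y`` are per-axis Pearson correlations averaged over trials,
    ``lag_ms`` the median over trials of the cross-covariance lag, and
    ``d_cm`` the mean cursor-handle distance.  Correlations of constant
    trajectories are undefined and excluded from the average (NaN if all
    trials are degenerate).
    """

    r_x: float
    r_y: float
    lag_ms: float
    d_cm: float
    n_trials: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0.0 or b.std() == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def tracking_accuracy(
    trials,
    display_rate: float = 75.0,
    max_lag_s: float = 0.5,
) -> TrackingAccuracy:
    """Aggregate tracking fidelity over trials.

    ``trials`` is an iterable of ``(cursor, handle)`` position-array pairs on
    a common frame grid (e.g. the frames of one phase of each trial).
    """
    max_lag = int(round(max_lag_s * display_rate))
    rxs, rys, lags, ds = [], [], [], []
    n = 0
    for cursor, handle in trials:
        cursor = np.atleast_2d(np.asarray(cursor, dtype=float))
        handle = np.atleast_2d(np.asarray(handle, dtype=float))
        n += 1
        rxs.append(_pearson(cursor[:, 0], handle[:, 0]))
        rys.append(_pearson(cursor[:, 1], handle[:, 1]))
        trial_max_lag = min(max_lag, cursor.shape[0] - 2)
        lags.append(lag_of_max_cross_covariance(cursor, handle, trial_max_lag))
        ds.append(float(np.linalg.norm(cursor - handle, axis=1).mean()))
    if n == 0:
        raise ValueError("no trials supplied")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        r_x = float(np.nanmean(rxs))
        r_y = float(np.nanmean(rys))
    lag_ms = float(np.median(lags) / display_rate * 1000.0)
    return TrackingAccuracy(r_x, r_y, lag_ms, float(np.mean(ds)), n)
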