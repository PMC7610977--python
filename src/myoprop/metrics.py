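"""Per-trial performance metrics.

*Target mismatch* is the primary error measure: the Euclidean distance
between cursor and target centers averaged over the hold period, normalized
by the start-to-target distance, so that 1.0 corresponds to a cursor parked
at the start and 0 to perfect matching.

Cursor error is further decomposed in polar coordinates about the start
point into an absolute radial error |eps_r| (an error in overall
contraction magnitude, normalized like the mismatch) and an absolute
angular error |eps| in degrees (an error in the balance between the two
muscles).  For 1D targets the cursor is confined to the target ray, no
angular error exists, and the radial error coincides with the target
mismatch.

Window means are taken over four half-open 0.5 s windows from target
appearance: early movement [0, 0.5), late movement [0.5, 1.0), early hold
[1.0, 1.5) and late hold [1.5, 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_WINDOWS",
    "WINDOW_NAMES",
    "TrialMetrics",
    "target_mismatch",
    "polar_errors",
    "window_means",
    "trial_metrics",
]

DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = (
    (0.0, 0.5),
    (0.5, 1.0),
    (1.0, 1.5),
    (1.5, 2.0),
)
WINDOW_NAMES = ("early_move", "late_move", "early_hold", "late_hold")

#: Cursor radii (as a fraction of the start-target distance) below which the
#: polar angle of the cursor is treated as undefined.
ANGLE_EXCLUSION_FRACTION = 0.05


@dataclass(frozen=True)
class TrialMetrics:
    """Metrics of a single trial.

    ``radial_error`` / ``angular_error`` are per-frame series on the post-cue
    frame grid (angular is None for 1D targets; undefined frames are NaN).
    ``radial_window_means`` / ``angular_window_means`` follow
    :data:`WINDOW_NAMES`; empty windows are NaN.
    """

    mismatch: float
    radial_error: np.ndarray
    angular_error: np.ndarray | None
    radial_window_means: tuple[float, ...]
    angular_window_means: tuple[float, ...] | None


def target_mismatch(hold_positions, target_position, start_point=(0.0, 0.0)) -> float:
    """Hold-phase mean cursor-target distance over the start-target distance."""
    pos = np.atleast_2d(np.asarray(hold_positions, dtype=float))
    if pos.shape[0] == 0:
        raise ValueError("hold-phase trajectory is empty")
    target = np.asarray(target_position, dtype=float) - np.asarray(
        start_point, dtype=float
    )
    rel = pos - np.asarray(start_point, dtype=float)
    denom = np.linalg.norm(target)
    if denom == 0.0:
        raise ValueError("target coincides with the start point; mismatch undefined")
    return float(np.linalg.norm(rel - target, axis=1).mean() / denom)


def polar_errors(
    positions,
    target_position,
    start_point=(0.0, 0.0),
    angle_exclusion_fraction: float = ANGLE_EXCLUSION_FRACTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute radial and angular error series about the start point.

    Radial error is |r_cursor - r_target| / r_target, so that on the target
    ray it equals the target mismatch.  Angular error is the absolute
    cursor-target angle difference in degrees, wrapped to [0, 180]; frames
    whose cursor radius is below ``angle_exclusion_fraction * r_target``
    have no well-defined angle and are returned as NaN.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float)) - np.asarray(
        start_point, dtype=float
    )
    target = np.asarray(target_position, dtype=float) - np.asarray(
        start_point, dtype=float
    )
    r_t = np.linalg.norm(target)
    if r_t == 0.0:
        raise ValueError("target coincides with the start point")
    theta_t = np.rad2deg(np.arctan2(target[1], target[0]))
    r_c = np.linalg.norm(pos, axis=1)
    eps_r = np.abs(r_c - r_t) / r_t
    theta_c = np.rad2deg(np.arctan2(pos[:, 1], pos[:, 0]))
    eps_ang = np.abs((theta_c - theta_t + 180.0) % 360.0 - 180.0)
    eps_ang = np.where(r_c < angle_exclusion_fraction * r_t, np.nan, eps_ang)
    return eps_r, eps_ang


def window_means(
    series,
    frame_times,
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS,
) -> tuple[float, ...]:
    """Mean of a per-frame series over half-open time windows [a, b).

    NaN frames (undefined values) are excluded; a window with no defined
    frames yields NaN.
    """
    series = np.asarray(series, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    out = []
    for a, b in windows:
        mask = (frame_times >= a) & (frame_times < b)
        vals = series[mask]
        vals = vals[np.isfinite(vals)]
        out.append(float(vals.mean()) if vals.size else float("nan"))
    return tuple(out)


def trial_metrics(
    positions,
    frame_times,
    target_position,
    is_2d: bool,
    hold_window: tuple[float, float] = (1.0, 2.0),
    start_point=(0.0, 0.0),
) -> TrialMetrics:
    """Compute the full metric set for one trial.

    ``positions``/``frame_times`` cover the post-cue part of the trial
    (t >= 0); the hold phase is the half-open window ``hold_window``.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    post = frame_times >= 0.0
    pos, frame_times = pos[post], frame_times[post]
    hold = (frame_times >= hold_window[0]) & (frame_times < hold_window[1])
    mismatch = target_mismatch(pos[hold], target_position, start_point)
    eps_r, eps_ang = polar_errors(pos, target_position, start_point)
    radial_means = window_means(eps_r, frame_times)
    if is_2d:
        angular = eps_ang
        angular_means = window_means(eps_ang, frame_times)
    else:
        angular = None
        angular_means = None
    return TrialMetrics(mismatch, eps_r, angular, radial_means, angular_means)
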