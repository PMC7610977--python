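"""Workspace geometry and the activation-to-cursor control law.

The interface maps the normalized activation of two muscles onto a planar
cursor.  Each muscle has a fixed *direction of action* (DoA): a unit vector
pointing out from the start zone along which its activation pushes the
cursor.  Cursor position is the vector sum of both DoA vectors scaled by the
respective normalized activation and a fixed length gain,

    x = sum_i  y_n,i * gain_length * DoA_i .

Lateral targets that lie on a DoA are controlled in a one-dimensional mode
in which the activation of the muscle whose DoA is perpendicular to the
target direction is ignored.

Conventions: the origin of all relative positions is the start point, +x is
rightward, +y points toward the targets, and angles are measured
counterclockwise from +x in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfigurationError",
    "WorkspaceGeometry",
    "DoAConfig",
    "target_position",
    "cursor_position",
    "required_activations",
]


class ConfigurationError(ValueError):
    """Raised for invalid workspace or control-law configuration."""


@dataclass(frozen=True)
class WorkspaceGeometry:
    """Center-out task layout.

    Distances are centimetres in the plane of the virtual display.  The
    default layout places four targets of diameter 2.4 cm at 45, 75, 105 and
    135 degrees on a quarter circle of 8.6 cm radius around a circular
    starting zone (diameter 3.6 cm) in the lower part of the workspace.
    """

    start_point: tuple[float, float] = (0.0, 0.0)
    start_zone_radius: float = 1.8
    cursor_radius: float = 0.9
    target_radius: float = 1.2
    ring_radius: float = 8.6
    target_angles_deg: tuple[float, ...] = (45.0, 75.0, 105.0, 135.0)
    display_rate: float = 75.0

    def __post_init__(self) -> None:
        radii = (
            self.start_zone_radius,
            self.cursor_radius,
            self.target_radius,
            self.ring_radius,
        )
        if any(r <= 0 for r in radii):
            raise ConfigurationError("all radii must be positive")
        if self.ring_radius <= self.start_zone_radius + self.target_radius:
            raise ConfigurationError(
                "target ring must clear the start zone: "
                "ring_radius > start_zone_radius + target_radius"
            )
        angles = self.target_angles_deg
        if len(angles) == 0:
            raise ConfigurationError("at least one target angle required")
        if any(not (0.0 < a < 180.0) for a in angles):
            raise ConfigurationError("target angles must lie in (0, 180) degrees")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ConfigurationError("target angles must be strictly increasing")
        if self.display_rate <= 0:
            raise ConfigurationError("display_rate must be positive")

    @property
    def n_targets(self) -> int:
        return len(self.target_angles_deg)

    @property
    def overlap_threshold(self) -> float:
        """Center distance below which cursor and target circles overlap."""
        return self.target_radius + self.cursor_radius


@dataclass(frozen=True)
class DoAConfig:
    """Directions of action of the two control muscles.

    ``angles_deg`` gives the DoA of (muscle 1, muscle 2); the defaults point
    out from the start at 45 and 135 degrees.  ``gain_length`` converts one
    unit of normalized activation (the comfortable-contraction level) into
    centimetres of cursor displacement; by default it equals the target ring
    radius so that full comfortable contraction of a single muscle exactly
    reaches a lateral target.
    """

    angles_deg: tuple[float, float] = (45.0, 135.0)
    gain_length: float = 8.6
    angle_tol_deg: float = 1e-6

    def __post_init__(self) -> None:
        if self.gain_length <= 0:
            raise ConfigurationError("gain_length must be positive")
        d = self.directions
        if abs(np.linalg.det(d)) < 1e-12:
            raise ConfigurationError("DoA directions must be linearly independent")

    @property
    def directions(self) -> np.ndarray:
        """(2, 2) array; row i is the unit DoA vector of muscle i."""
        rad = np.deg2rad(self.angles_deg)
        return np.column_stack([np.cos(rad), np.sin(rad)])

    def aligned_muscle(self, target_angle_deg: float) -> int | None:
        """Index of the muscle whose DoA is collinear with the target ray.

        Returns ``None`` when the target is not on either DoA (a 2D target).
        """
        for i, a in enumerate(self.angles_deg):
            if abs((a - target_angle_deg + 90.0) % 180.0 - 90.0) <= self.angle_tol_deg:
                return i
        return None

    def is_1d_target(self, geometry: WorkspaceGeometry, target_index: int) -> bool:
        angle = _target_angle(geometry, target_index)
        return self.aligned_muscle(angle) is not None


def _target_angle(geometry: WorkspaceGeometry, target_index: int) -> float:
    if not 0 <= target_index < geometry.n_targets:
        raise ConfigurationError(
            f"target_index {target_index} out of range "
            f"[0, {geometry.n_targets})"
        )
    return geometry.target_angles_deg[target_index]


def target_position(geometry: WorkspaceGeometry, target_index: int) -> np.ndarray:
    """Absolute 2D position (cm) of a target center.

    The target sits on the ring of radius ``ring_radius`` around the start
    point at its configured angle.
    """
    angle = np.deg2rad(_target_angle(geometry, target_index))
    offset = geometry.ring_radius * np.array([np.cos(angle), np.sin(angle)])
    return np.asarray(geometry.start_point, dtype=float) + offset


def target_position_rel(geometry: WorkspaceGeometry, target_index: int) -> np.ndarray:
    """Target center relative to the start point."""
    return target_position(geometry, target_index) - np.asarray(
        geometry.start_point, dtype=float
    )


def cursor_position(
    activations,
    doa: DoAConfig,
    target_index: int,
    geometry: WorkspaceGeometry,
) -> np.ndarray:
    """Map a pair of normalized activations to a cursor position.

    Positions are relative to the start point.  Negative normalized
    activations are clamped to zero before the mapping (rectified EMG below
    rest level cannot pull the cursor past the start), and activations above
    one are allowed (overshoot beyond the ring is possible).

    For 1D targets (targets collinear with a DoA) the contribution of the
    non-aligned muscle is zeroed, confining the cursor to the target's ray.
    """
    y = np.asarray(activations, dtype=float)
    if y.shape != (2,):
        raise ValueError(f"expected exactly 2 activation values, got shape {y.shape}")
    y = np.maximum(y, 0.0)
    angle = _target_angle(geometry, target_index)
    aligned = doa.aligned_muscle(angle)
    if aligned is not None:
        mask = np.zeros(2)
        mask[aligned] = 1.0
        y = y * mask
    return doa.gain_length * (y @ doa.directions)


def required_activations(
    target_index: int,
    doa: DoAConfig,
    geometry: WorkspaceGeometry,
) -> np.ndarray:
    """Activation pair that places the cursor exactly on the target center.

    Inverse of :func:`cursor_position`.  For 1D targets the non-aligned
    component is zero by definition.
    """
    angle = _target_angle(geometry, target_index)
    target = target_position_rel(geometry, target_index)
    aligned = doa.aligned_muscle(angle)
    if aligned is not None:
        y = np.zeros(2)
        y[aligned] = geometry.ring_radius / doa.gain_length
        return y
    d = doa.directions
    try:
        y = np.linalg.solve(d.T * doa.gain_length, target)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in DoAConfig
        raise ConfigurationError("DoA direction matrix is singular") from exc
    if not np.all(np.isfinite(y)):
        raise ConfigurationError("required activations are not finite")
    return y
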