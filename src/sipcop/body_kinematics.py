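"""Three-segment seated-lean kinematics.

Forward lean rotates the trunk CoM about the x-axis through theta (trunk top
moving forward, +y).  A leftward lean rotates both trunk and upper-leg terms
about an axis parallel to y through the left femur at (-r, 0, 0).  The CoP on
a level seat is the gravity-line projection of the seat-borne CoM: x passes
through unchanged, y is offset by the distance between body and seat frames.

Closed-form displacement magnitudes (assuming T vertical and U along +y at
upright):

    forward:   |dCoP| = |T| t_m sin(theta)
    combined:  |dCoP| = hypot(|T| t_m sin(theta),
                              (t_m+u_m) r (1-cos(phi)) + |T| t_m cos(theta) sin(phi))

Rightward leans mirror phi about the midline (pivot at (+r, 0, 0)); pass a
negative phi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anthropometry import Anthropometry
from .errors import ValidationError

HALF_PI = math.pi / 2.0


@dataclass(frozen=True)
class LeanPose:
    """Lean angles in radians: theta >= 0 leans forward, phi > 0 leans left,
    phi < 0 leans right."""

    theta: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not (abs(self.theta) < HALF_PI and abs(self.phi) < HALF_PI):
            raise ValidationError(
                f"lean angles must satisfy |theta|, |phi| < pi/2; got {self}"
            )


@dataclass(frozen=True)
class SeatGeometry:
    """Seat-pan geometry.  ``width``/``depth`` are measured between the corner
    load cells, cm.  ``dump_angle_deg`` (rearward seat tilt) is metadata only:
    the CoP is computed in the seat-pan plane.  ``body_origin_offset_y`` maps
    body-frame y to seat-frame y (half seat depth minus half trunk depth)."""

    width: float = 40.0
    depth: float = 40.0
    dump_angle_deg: float = 8.0
    body_origin_offset_y: float = -3.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.depth <= 0:
            raise ValidationError("seat width and depth must be positive")


def _rotate_about_left_femur(v: np.ndarray, phi: float, r: float) -> np.ndarray:
    """Rotate ``v`` about the axis parallel to y through (-r, 0, 0) so that a
    positive phi tips points toward -x (leftward)."""
    c, s = math.cos(phi), math.sin(phi)
    x = v[0] + r
    return np.array([x * c - v[2] * s - r, v[1], x * s + v[2] * c])


def body_com(anthro: Anthropometry, pose: LeanPose) -> np.ndarray:
    """Seat-borne CoM (weighted by t_m, u_m) for a lean pose, cm, body frame.

    The forward rotation applies to the trunk term only (the upper legs stay
    on the seat); the lateral rotation applies to both terms.  A negative phi
    (rightward lean) is evaluated by mirror symmetry about the midline.
    """
    if pose.phi < 0:
        com = body_com(anthro, LeanPose(pose.theta, -pose.phi))
        return np.array([-com[0], com[1], com[2]])
    theta, phi = pose.theta, pose.phi
    c, s = math.cos(theta), math.sin(theta)
    T = anthro.trunk_com
    trunk_fwd = np.array([T[0], T[1] * c + T[2] * s, -T[1] * s + T[2] * c])
    r = anthro.hip_half_width
    trunk = _rotate_about_left_femur(trunk_fwd, phi, r)
    legs = _rotate_about_left_femur(anthro.upper_leg_com, phi, r)
    return anthro.trunk_mass_fraction * trunk + anthro.upper_leg_mass_fraction * legs


def cop_from_com(com: np.ndarray, geom: SeatGeometry) -> np.ndarray:
    """Project a body-frame CoM onto the seat plane: (x, y + offset), cm."""
    return np.array([com[0], com[1] + geom.body_origin_offset_y])


def cop_magnitude_forward(anthro: Anthropometry, theta: float) -> float:
    """CoP displacement magnitude for a pure forward lean: |T| t_m sin(theta)."""
    if not 0.0 <= theta <= HALF_PI:
        raise ValidationError(f"theta must lie in [0, pi/2], got {theta}")
    return anthro.trunk_length * anthro.trunk_mass_fraction * math.sin(theta)


def cop_magnitude_combined(anthro: Anthropometry, theta: float, phi: float) -> float:
    """CoP displacement magnitude for a combined forward and lateral lean.

    Reduces to :func:`cop_magnitude_forward` at phi = 0 and is symmetric in
    the sign of phi (left/right mirror)."""
    if not 0.0 <= theta < HALF_PI:
        raise ValidationError(f"theta must lie in [0, pi/2), got {theta}")
    if not abs(phi) < HALF_PI:
        raise ValidationError(f"|phi| must be < pi/2, got {phi}")
    phi = abs(phi)
    tm = anthro.trunk_length * anthro.trunk_mass_fraction
    lateral = (
        anthro.seat_borne_fraction * anthro.hip_half_width * (1.0 - math.cos(phi))
        + tm * math.cos(theta) * math.sin(phi)
    )
    return math.hypot(tm * math.sin(theta), lateral)
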