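"""Uniform-elasticity beam model of ischial-tuberosity (IT) seat pressure.

The trunk + upper-leg assembly is treated as a rigid beam of length L (the
upper-leg segment, hip at y = 0, knee at y = L) resting on a surface of
uniform elasticity.  Static equilibrium of force and torque with an affine
restoring-force density f(y) = a y + b gives

    f(y) = -2 g m [ (3 CoM_y - 2L) / L^2  -  3 (2 CoM_y - L) y / L^3 ]

which integrates to m g and whose first moment integrates to CoM_y m g.
Dividing f evaluated with a shifted CoM by f at the upright CoM yields the
proportional IT pressure as an affine function of the CoM shift:

    p(dCoM_y) = 1 + 3 (L - 2y) / [3 CoM_y0 (L - 2y) - L (2L - 3y)] * dCoM_y

For a pure forward lean the CoM shift equals the CoP displacement magnitude,
so the bracketed coefficient is the theoretical SIP-CoP slope at the IT
position y = y_IT.  It is negative whenever CoM_y0 < 2L/3 and y_IT < L/2.

Lateral-lean pressure is not modeled analytically (it depends on unverifiable
assumptions about spine motion and IT lift-off); the synthetic-trial
generator instead imposes a configurable lateral slope multiplier >= 1,
consistent with the observation that sideways slopes are steeper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anthropometry import GRAVITY, Anthropometry
from .body_kinematics import cop_magnitude_forward
from .errors import SingularConfigurationError, ValidationError

_SINGULAR_TOL = 1e-12


@dataclass(frozen=True)
class BeamModelParams:
    """Parameters of the beam equilibrium model.

    length: L, upper-leg segment length, cm.
    mass: m, total mass of torso + upper-leg segments, kg.
    com_y: current CoM along y, cm.
    com_y0: upright CoM along y, cm (must be < 2L/3).
    y_eval: evaluation position along y (IT location), cm, in [0, L].
    """

    length: float
    mass: float
    com_y: float
    com_y0: float
    y_eval: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError("beam length must be positive")
        if self.mass <= 0:
            raise ValidationError("beam mass must be positive")
        if not 0.0 <= self.y_eval <= self.length:
            raise ValidationError(
                f"y_eval must lie in [0, L] = [0, {self.length}], got {self.y_eval}"
            )
        if not self.com_y0 < 2.0 * self.length / 3.0:
            raise ValidationError(
                "com_y0 must be < 2L/3 for a finite negative slope at y=0, "
                f"got {self.com_y0} with L={self.length}"
            )


def restoring_force(params: BeamModelParams, y, g: float = GRAVITY):
    """Restoring-force density f(y) in N/cm under static equilibrium.

    Affine in y; integrates over [0, L] to m g, with first moment CoM_y m g.
    Accepts scalar or array y in [0, L].
    """
    y = np.asarray(y, dtype=float)
    L, m, com_y = params.length, params.mass, params.com_y
    if np.any(y < 0) or np.any(y > L):
        raise ValidationError(f"y must lie in [0, L] = [0, {L}]")
    f = -2.0 * g * m * ((3.0 * com_y - 2.0 * L) / L**2 - 3.0 * (2.0 * com_y - L) * y / L**3)
    return f if f.ndim else float(f)


def _slope_coefficient(length: float, com_y0: float, y_eval: float) -> float:
    """Coefficient of dCoM_y in the proportional-pressure expression, per cm."""
    denom = 3.0 * com_y0 * (length - 2.0 * y_eval) - length * (2.0 * length - 3.0 * y_eval)
    if abs(denom) < _SINGULAR_TOL:
        raise SingularConfigurationError(
            f"proportional pressure singular at y={y_eval} with "
            f"CoM_y0={com_y0}, L={length}"
        )
    return 3.0 * (length - 2.0 * y_eval) / denom


def proportional_pressure(params: BeamModelParams, delta_com_y: float) -> float:
    """Proportional IT pressure after a forward CoM shift of ``delta_com_y`` cm.

    Affine in the shift before clipping; equals 1 at zero shift.  Clipped at 0
    because contact pressure cannot be negative (the beam solution admits
    negative densities at extreme shifts, but the analysis only ever uses the
    first 95% of the pressure reduction, which the clip does not touch).
    """
    if delta_com_y < 0:
        raise ValidationError("delta_com_y must be nonnegative")
    coeff = _slope_coefficient(params.length, params.com_y0, params.y_eval)
    return max(0.0, 1.0 + coeff * delta_com_y)


def theoretical_slope(anthro: Anthropometry) -> float:
    """Theoretical proportional-SIP change per cm of CoP shift (negative).

    Evaluates the beam-model pressure slope at the individual's IT position
    y_IT, with L the upper-leg length and CoM_y0 the upright seat-borne CoM.
    """
    return _slope_coefficient(
        anthro.upper_leg_length, anthro.upright_com_y, anthro.it_offset
    )


def theoretical_sine_coefficient(anthro: Anthropometry) -> float:
    """Theoretical coefficient b of CoP = b sin(trunk pitch): |T| t_m, cm.

    Assumes the trunk CoM vector is vertical at upright, i.e. equals the CoP
    magnitude of a forward lean at theta = pi/2.
    """
    return cop_magnitude_forward(anthro, np.pi / 2.0)
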