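"""Body-model parameters and supine bed-mat mass estimation.

The seated-lean model treats the wheelchair user as three rigid segments
(trunk, upper legs, lower legs) joined by hinges near the sacrum.  The lower
legs rest on the footrests and carry none of the seat-borne load, so only the
trunk and upper-leg segments enter the model.  Their mass fractions and
center-of-mass (CoM) vectors are estimated from a single supine frame of a
bed-sized pressure mat with the body segmented by palpated landmark rows
(calcaneus, mid patella, ASIS, xyphoid process, sternoclavicular joint,
vertex).

Coordinate conventions (body frame): x left-right with left negative,
y back-front with forward positive, z up; origin at the trunk / upper-leg
hinge.  Lengths are exposed in cm; force arithmetic is SI (N, kg, m/s^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError

#: Standard gravitational acceleration, m/s^2.
GRAVITY = 9.80665

#: Center-to-center pitch of the bed-mat sensing elements, cm.
BED_CELL_PITCH_CM = 2.86

#: Body segments delimited by the six landmark rows, ordered foot to head.
SEGMENTS = ("lower_leg", "upper_leg", "lower_torso", "upper_torso", "head")

#: Index of the ASIS landmark within the landmark-row sequence.
ASIS_LANDMARK = 2


@dataclass(frozen=True)
class Anthropometry:
    """Per-individual parameters of the seated-lean model.

    Parameters
    ----------
    trunk_com : (3,) array
        CoM vector T of the trunk segment in the upright body frame, cm.
        The closed-form CoP magnitudes assume T is purely vertical.
    upper_leg_com : (3,) array
        CoM vector U of the upper-leg segment, cm (nominally along +y).
    trunk_mass_fraction, upper_leg_mass_fraction : float
        Fractions t_m and u_m of total body mass carried by the trunk and
        upper-leg segments; their sum is the seat-borne fraction.
    upper_leg_length : float
        L, hip-to-knee length of the upper-leg segment, cm.
    hip_half_width : float
        r, distance from the body midline to the femur axis, cm.  Lateral
        leans pivot about the femur on the leaned-toward side.
    it_offset : float
        y_IT, position along y (forward of the hinge) at which ischial-
        tuberosity pressure is evaluated, cm.
    upright_com_y : float
        CoM_y0, seat-borne CoM along y when sitting upright, cm.
    body_mass : float
        Total body mass, kg.
    """

    trunk_com: np.ndarray
    upper_leg_com: np.ndarray
    trunk_mass_fraction: float
    upper_leg_mass_fraction: float
    upper_leg_length: float
    hip_half_width: float
    it_offset: float
    upright_com_y: float
    body_mass: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "trunk_com", np.asarray(self.trunk_com, dtype=float))
        object.__setattr__(
            self, "upper_leg_com", np.asarray(self.upper_leg_com, dtype=float)
        )
        t_m, u_m = self.trunk_mass_fraction, self.upper_leg_mass_fraction
        L = self.upper_leg_length
        if not (0.0 < t_m < 1.0 and 0.0 < u_m < 1.0 and t_m + u_m <= 1.0):
            raise ValidationError(
                f"mass fractions t_m={t_m}, u_m={u_m} must lie in (0,1) and sum to <=1"
            )
        if L <= 0:
            raise ValidationError(f"upper_leg_length must be positive, got {L}")
        if self.hip_half_width < 0:
            raise ValidationError("hip_half_width must be nonnegative")
        if not (0.0 <= self.it_offset < L / 2.0):
            raise ValidationError(
                f"it_offset must lie in [0, L/2) = [0, {L / 2.0}), got {self.it_offset}"
            )
        if not (0.0 <= self.upright_com_y < 2.0 * L / 3.0):
            raise ValidationError(
                "upright_com_y must lie in [0, 2L/3) for a finite negative "
                f"pressure slope, got {self.upright_com_y}"
            )
        if self.body_mass <= 0:
            raise ValidationError("body_mass must be positive")

    @property
    def trunk_length(self) -> float:
        """|T|, cm."""
        return float(np.linalg.norm(self.trunk_com))

    @property
    def seat_borne_fraction(self) -> float:
        """t_m + u_m: fraction of body weight carried by the seat."""
        return self.trunk_mass_fraction + self.upper_leg_mass_fraction

    @property
    def seat_borne_mass(self) -> float:
        """Mass of trunk + upper legs, kg (the beam model's m)."""
        return self.seat_borne_fraction * self.body_mass


@dataclass(frozen=True)
class BedMatFrame:
    """One supine frame of the bed-sized pressure mat.

    ``forces`` holds per-cell forces in N with the body axis along rows
    (row 0 at the feet).  ``landmark_rows`` are the six palpated landmark
    rows, strictly increasing, foot to head.  A cell belongs to the segment
    of its row band; a landmark row itself starts the next segment
    (half-open bands), and the outermost bands extend to the grid edges so
    that every cell is assigned.
    """

    forces: np.ndarray
    landmark_rows: tuple = field(default=())
    cell_pitch_cm: float = BED_CELL_PITCH_CM

    def __post_init__(self) -> None:
        forces = np.asarray(self.forces, dtype=float)
        object.__setattr__(self, "forces", forces)
        object.__setattr__(self, "landmark_rows", tuple(int(r) for r in self.landmark_rows))
        if forces.ndim != 2:
            raise ValidationError("bed-mat frame must be a 2-D grid")
        if np.any(forces < 0):
            raise ValidationError("bed-mat cell forces must be nonnegative")
        rows = self.landmark_rows
        if len(rows) != len(SEGMENTS) + 1:
            raise ValidationError(
                f"expected {len(SEGMENTS) + 1} landmark rows, got {len(rows)}"
            )
        if any(b <= a for a, b in zip(rows, rows[1:])):
            raise ValidationError(f"landmark rows must be strictly increasing: {rows}")
        if rows[0] < 0 or rows[-1] >= forces.shape[0]:
            raise ValidationError(
                f"landmark rows {rows} fall outside the {forces.shape[0]}-row grid"
            )

    @property
    def asis_row(self) -> int:
        return self.landmark_rows[ASIS_LANDMARK]

    def segment_bands(self) -> dict:
        """Half-open row bands ``[lo, hi)`` per segment, outer bands extended
        to the grid edges."""
        rows = self.landmark_rows
        n = self.forces.shape[0]
        edges = [0, *rows[1:-1], n]
        return {seg: (edges[i], edges[i + 1]) for i, seg in enumerate(SEGMENTS)}


def estimate_segment_masses(frame: BedMatFrame, g: float = GRAVITY) -> pd.DataFrame:
    """Estimate per-segment mass and CoM position from a supine bed-mat frame.

    Each segment's mass is the summed cell force in its row band divided by
    ``g``; its CoM along the body axis is the force-weighted centroid of its
    cells, converted to cm.  ``com_cm`` is measured from the grid origin
    (row 0 center); ``com_body_cm`` subtracts the ASIS landmark row position,
    matching the body frame in which segment CoM vectors are expressed.

    Returns a DataFrame indexed by segment with columns ``mass_kg``,
    ``com_cm``, ``com_body_cm``.  Masses sum exactly to the total frame
    force / g.
    """
    total_force = float(frame.forces.sum())
    if total_force <= 0:
        raise DegenerateInputError("bed-mat frame carries no force")
    row_force = frame.forces.sum(axis=1)
    row_pos_cm = np.arange(frame.forces.shape[0]) * frame.cell_pitch_cm
    asis_cm = frame.asis_row * frame.cell_pitch_cm

    records = []
    for seg, (lo, hi) in frame.segment_bands().items():
        f = row_force[lo:hi]
        seg_force = float(f.sum())
        mass = seg_force / g
        if seg_force > 0:
            com = float(np.dot(f, row_pos_cm[lo:hi]) / seg_force)
        else:
            com = float("nan")
        records.append(
            {"segment": seg, "mass_kg": mass, "com_cm": com, "com_body_cm": com - asis_cm}
        )
    return pd.DataFrame.from_records(records).set_index("segment")


def anthropometry_from_bedmat(
    frame: BedMatFrame,
    hip_half_width: float = 8.5,
    it_offset: float = 5.0,
    g: float = GRAVITY,
) -> Anthropometry:
    """Build an :class:`Anthropometry` from a supine bed-mat frame.

    The trunk segment aggregates lower torso, upper torso, and head (all mass
    above the hips that the seat carries through the trunk); its CoM distance
    from the ASIS becomes |T| with T taken vertical in the upright posture.
    The upper-leg CoM lies along +y.  The upright seat-borne CoM_y0 is the
    mass-weighted y-position of the two segments (trunk at y=0).

    The supine frame cannot measure ``hip_half_width`` or ``it_offset``;
    these are caliper measurements supplied by the caller.
    """
    seg = estimate_segment_masses(frame, g=g)
    total = seg["mass_kg"].sum()
    trunk_rows = ["lower_torso", "upper_torso", "head"]
    trunk_mass = seg.loc[trunk_rows, "mass_kg"].sum()
    leg_mass = seg.loc["upper_leg", "mass_kg"]
    if trunk_mass <= 0 or leg_mass <= 0:
        raise DegenerateInputError("trunk or upper-leg band carries no force")
    trunk_len = float(
        (seg.loc[trunk_rows, "mass_kg"] * seg.loc[trunk_rows, "com_body_cm"]).sum()
        / trunk_mass
    )
    # Supine rows run foot->head, so the upper-leg CoM sits below the ASIS;
    # seated, that distance points forward along +y.
    leg_y = float(-seg.loc["upper_leg", "com_body_cm"])
    t_m = float(trunk_mass / total)
    u_m = float(leg_mass / total)
    bands = frame.segment_bands()
    lo, hi = bands["upper_leg"]
    leg_len = (hi - lo) * frame.cell_pitch_cm
    com_y0 = u_m * leg_y / (t_m + u_m)
    return Anthropometry(
        trunk_com=np.array([0.0, 0.0, trunk_len]),
        upper_leg_com=np.array([0.0, leg_y, 0.0]),
        trunk_mass_fraction=t_m,
        upper_leg_mass_fraction=u_m,
        upper_leg_length=leg_len,
        hip_half_width=hip_half_width,
        it_offset=it_offset,
        upright_com_y=com_y0,
        body_mass=float(total),
    )
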