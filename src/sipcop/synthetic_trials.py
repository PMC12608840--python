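"""Synthetic pressure-redistribution (PR) trials and cohorts.

This module is the stand-in for raw human trials: it composes the lean
kinematics and the beam pressure model forward into the three sensor streams
the estimation pipeline consumes -- corner load cells at 125 Hz, a 16x16 seat
pressure mat at a jittered nominal rate, and IMU pitch/roll channels at
100 Hz -- with configurable noise and a ground-truth table for recovery
tests.

Conditions mirror the study protocol: forward, leftward, and rightward leans,
three repetitions each, starting either upright ("situp") or reclined at the
backrest, on air / foam / own cushions.  Lateral trials superimpose a forward
component (theta ramps together with phi), and the offloaded side's pressure
slope is the forward-lean beam slope times a configurable lateral multiplier
>= 1 (the lateral response is not modeled analytically).

All randomness derives from ``SimulationConfig.seed``: each trial draws its
RNG from the seed plus a CRC32 hash of its condition, so cohorts are
reproducible trial-by-trial and independent of generation order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .anthropometry import GRAVITY, Anthropometry
from .body_kinematics import LeanPose, SeatGeometry, body_com, cop_from_com
from .errors import ValidationError
from .it_pressure_model import theoretical_sine_coefficient, theoretical_slope

DIRECTIONS = ("forward", "left", "right")
CUSHIONS = ("air", "foam", "own")
START_POSITIONS = ("backrest", "situp")
IMU_SENSORS = ("sternum", "pelvis", "femur_l", "femur_r")

MAT_SHAPE = (16, 16)

_UPRIGHT = LeanPose(0.0, 0.0)


@dataclass(frozen=True)
class TrialCondition:
    """Identity of one PR maneuver recording."""

    participant_id: str
    direction: str
    cushion: str = "own"
    start_position: str = "backrest"
    repetition: int = 1
    group: str = "AB"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"direction must be one of {DIRECTIONS}")
        if self.cushion not in CUSHIONS:
            raise ValidationError(f"cushion must be one of {CUSHIONS}")
        if self.start_position not in START_POSITIONS:
            raise ValidationError(f"start_position must be one of {START_POSITIONS}")
        if self.repetition < 1:
            raise ValidationError("repetition must be >= 1")

    def key(self) -> str:
        return (
            f"{self.participant_id}|{self.cushion}|{self.start_position}|"
            f"{self.direction}|{self.repetition}"
        )


@dataclass
class Trial:
    """One maneuver's three sensor streams plus pre-transfer tare frames.

    loadcell_forces columns are ordered (back-left, back-right, front-left,
    front-right), N.  mat_frames is (n, 16, 16) with row 0 at the back of the
    seat and column 0 at the user's left.  imu maps sensor name to an (n, 2)
    array of (pitch, roll) in degrees.
    """

    condition: TrialCondition
    loadcell_t: np.ndarray
    loadcell_forces: np.ndarray
    tare_frames: np.ndarray
    mat_t: np.ndarray
    mat_frames: np.ndarray
    imu_t: np.ndarray
    imu: dict

    def __post_init__(self) -> None:
        for name, t in (("loadcell", self.loadcell_t), ("mat", self.mat_t), ("imu", self.imu_t)):
            t = np.asarray(t, dtype=float)
            if t.size and np.any(np.diff(t) <= 0):
                raise ValidationError(f"{name} timestamps must be strictly increasing")
        if np.any(np.asarray(self.mat_frames) < 0):
            raise ValidationError("mat pressures must be nonnegative")
        lo = max(self.loadcell_t[0], self.mat_t[0], self.imu_t[0])
        hi = min(self.loadcell_t[-1], self.mat_t[-1], self.imu_t[-1])
        if hi <= lo:
            raise ValidationError("sensor streams do not overlap in time")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one participant's trials.

    Trajectory: angles ramp linearly over ``ramp_s`` after ``settle_s`` of
    upright sitting (backrest starts prepend ``backrest_pre_s`` of coming off
    a ``backrest_recline_deg`` recline with ``backrest_weight_frac`` of the
    seat-borne weight on the backrest, so peak seat pressure occurs at the
    upright instant).  Noise SDs default to plausible magnitudes for the
    instrument classes involved; they are package choices, not measured
    values, and tests vary them.
    """

    anthropometry: Optional[Anthropometry] = None
    geometry: SeatGeometry = field(default_factory=SeatGeometry)
    seed: int = 0

    loadcell_hz: float = 125.0
    imu_hz: float = 100.0
    mat_hz: float = 15.0
    mat_jitter_frac: float = 0.2

    settle_s: float = 1.0
    ramp_s: float = 8.0
    hold_s: float = 2.0
    backrest_pre_s: float = 3.0
    backrest_recline_deg: float = 10.0
    backrest_weight_frac: float = 0.25

    max_forward_deg: float = 40.0
    max_lateral_deg: float = 30.0
    lateral_forward_ratio: float = 0.5
    lateral_slope_multiplier: float = 1.45
    loaded_side_gain: float = 0.25

    baseline_peak: float = 60.0
    mat_ambient: float = 2.0
    it_centers: tuple = ((9, 4), (9, 10))

    noise_loadcell_n: float = 0.5
    noise_mat: float = 1.0
    noise_imu_deg: float = 0.5
    tare_weight_n: float = 15.0
    tare_duration_s: float = 0.5
    knee_cop_bias_cm: float = 0.0

    pelvis_pitch_gain: float = 0.6
    femur_pitch_gain: float = 0.15
    femur_lift_gain: float = 0.5

    def __post_init__(self) -> None:
        for name in ("noise_loadcell_n", "noise_mat", "noise_imu_deg"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.lateral_slope_multiplier < 1.0:
            raise ValidationError("lateral_slope_multiplier must be >= 1")
        if not 0.0 <= self.mat_jitter_frac < 0.5:
            raise ValidationError("mat_jitter_frac must lie in [0, 0.5)")
        if self.max_forward_deg >= 90.0 or self.max_lateral_deg >= 90.0:
            raise ValidationError("lean trajectory must stay below pi/2")


def noiseless(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of ``cfg`` with every noise source and the mat clock jitter off."""
    return replace(
        cfg, noise_loadcell_n=0.0, noise_mat=0.0, noise_imu_deg=0.0, mat_jitter_frac=0.0
    )


def corner_forces_from_cop(total_force, cop, geom: SeatGeometry) -> np.ndarray:
    """Distribute a total force over the four corner load cells for a given CoP.

    Uses the bilinear (separable in x and y) distribution, the unique
    separable nonnegative scheme that the corner-centroid CoP formula inverts
    exactly inside the seat rectangle.  Accepts scalars or arrays; returns
    forces ordered (back-left, back-right, front-left, front-right).
    """
    cop = np.asarray(cop, dtype=float)
    total_force = np.asarray(total_force, dtype=float)
    x, y = cop[..., 0], cop[..., 1]
    w, d = geom.width, geom.depth
    if np.any(np.abs(x) > w / 2 + 1e-12) or np.any(np.abs(y) > d / 2 + 1e-12):
        raise ValidationError("CoP lies outside the seat rectangle")
    u = x / w + 0.5  # fraction of force on the right pair
    v = y / d + 0.5  # fraction of force on the front pair
    forces = np.stack(
        [
            total_force * (1 - u) * (1 - v),
            total_force * u * (1 - v),
            total_force * (1 - u) * v,
            total_force * u * v,
        ],
        axis=-1,
    )
    return forces


def render_mat_frame(
    prop_left: float,
    prop_right: float,
    baseline_peak: float,
    it_centers: Sequence[Sequence[int]],
    noise_sd: float,
    rng: np.random.Generator,
    ambient: float = 2.0,
    shape: tuple = MAT_SHAPE,
) -> np.ndarray:
    """Render one pressure-mat frame with a 2x2 hot block per IT.

    Each block (anchored at its ``it_centers`` entry, which is the top-left
    cell of the 2x2 block) reads ``baseline_peak`` times its proportional
    pressure, floored at the ambient level; every other cell sits at
    ``ambient``.  Gaussian noise of SD ``noise_sd`` is added and the frame is
    clipped at zero.
    """
    if prop_left < 0 or prop_right < 0:
        raise ValidationError("proportional pressures must be nonnegative")
    for r, c in it_centers:
        if not (0 <= r <= shape[0] - 2 and 0 <= c <= shape[1] - 2):
            raise ValidationError(
                f"IT block anchored at ({r}, {c}) does not fit a 2x2 block "
                f"on a {shape} grid"
            )
    frame = np.full(shape, ambient, dtype=float)
    for (r, c), prop in zip(it_centers, (prop_left, prop_right)):
        frame[r : r + 2, c : c + 2] = max(baseline_peak * prop, ambient)
    if noise_sd > 0:
        frame = frame + rng.normal(0.0, noise_sd, size=shape)
    return np.clip(frame, 0.0, None)


def _trial_rng(cfg: SimulationConfig, cond: TrialCondition) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, zlib.crc32(cond.key().encode())])
    )


def _trajectory(cfg: SimulationConfig, cond: TrialCondition, t: np.ndarray):
    """Return (theta_eff, phi_signed, backrest_frac) at times ``t``.

    theta_eff is the signed trunk pitch (negative while reclined at the
    backrest); phi_signed is positive for leftward, negative for rightward
    lean; backrest_frac is the fraction of seat-borne weight still resting
    on the backrest.
    """
    pre = cfg.backrest_pre_s if cond.start_position == "backrest" else 0.0
    lean_start = pre + cfg.settle_s
    u = np.clip((t - lean_start) / cfg.ramp_s, 0.0, 1.0)
    if cond.direction == "forward":
        theta = u * math.radians(cfg.max_forward_deg)
        phi = np.zeros_like(t)
    else:
        phi_mag = u * math.radians(cfg.max_lateral_deg)
        theta = cfg.lateral_forward_ratio * phi_mag
        phi = phi_mag if cond.direction == "left" else -phi_mag
    if pre > 0:
        w = np.clip(1.0 - t / pre, 0.0, 1.0)
        theta = theta - w * math.radians(cfg.backrest_recline_deg)
        kappa = cfg.backrest_weight_frac * w
    else:
        kappa = np.zeros_like(t)
    return theta, phi, kappa


def _cop_displacement(anthro: Anthropometry, theta: np.ndarray, phi: np.ndarray):
    """Signed CoP displacement (dx, dy) from upright, cm (closed form)."""
    tm = anthro.trunk_length * anthro.trunk_mass_fraction
    dy = tm * np.sin(theta)
    lat = (
        anthro.seat_borne_fraction * anthro.hip_half_width * (1.0 - np.cos(np.abs(phi)))
        + tm * np.cos(theta) * np.sin(np.abs(phi))
    )
    dx = -np.sign(phi) * lat
    return dx, dy


def _proportional_traces(cfg: SimulationConfig, cond: TrialCondition, t: np.ndarray):
    """Noiseless proportional IT pressures (left, right) at times ``t``."""
    anthro = cfg.anthropometry
    theta, phi, kappa = _trajectory(cfg, cond, t)
    slope = theoretical_slope(anthro)
    dx, dy = _cop_displacement(anthro, theta, phi)
    # Pressure responds to the lean away from upright; the pre-lean backrest
    # phase is handled by the weight fraction kappa instead.
    mag = np.hypot(dx, np.clip(dy, 0.0, None))
    if cond.direction == "forward":
        p_off = p_on = np.clip(1.0 + slope * mag, 0.0, None)
    else:
        p_off = np.clip(1.0 + slope * cfg.lateral_slope_multiplier * mag, 0.0, None)
        p_on = np.clip(1.0 + cfg.loaded_side_gain * abs(slope) * mag, 0.0, None)
    scale = 1.0 - kappa
    if cond.direction == "right":
        return p_off * scale, p_on * scale
    return p_on * scale, p_off * scale


def simulate_trial(cfg: SimulationConfig, cond: TrialCondition) -> Trial:
    """Generate one synthetic trial under ``cfg`` for condition ``cond``.

    Noiseless runs are exactly consistent with the closed-form model: the
    final CoP displacement magnitude equals the Eq.-style closed forms for
    the trajectory's angles, and the proportional IT pressure is affine in
    CoP magnitude with the beam-model slope (times the lateral multiplier on
    the offloaded side of a sideways lean).
    """
    if cfg.anthropometry is None:
        raise ValidationError("SimulationConfig.anthropometry is required")
    anthro = cfg.anthropometry
    rng = _trial_rng(cfg, cond)
    pre = cfg.backrest_pre_s if cond.start_position == "backrest" else 0.0
    total = pre + cfg.settle_s + cfg.ramp_s + cfg.hold_s

    upright_cop = cop_from_com(body_com(anthro, _UPRIGHT), cfg.geometry)
    weight = anthro.seat_borne_mass * GRAVITY

    def cop_at(t: np.ndarray) -> np.ndarray:
        theta, phi, _ = _trajectory(cfg, cond, t)
        dx, dy = _cop_displacement(anthro, theta, phi)
        if cfg.knee_cop_bias_cm:
            lean_start = pre + cfg.settle_s
            u = np.clip((t - lean_start) / cfg.ramp_s, 0.0, 1.0)
            dy = dy + cfg.knee_cop_bias_cm * u
        return np.stack([upright_cop[0] + dx, upright_cop[1] + dy], axis=-1)

    # Load cells: participant weight at the trial CoP plus the cushion+mat
    # tare weight centered on the seat.
    lc_t = np.arange(0.0, total, 1.0 / cfg.loadcell_hz)
    _, _, kappa = _trajectory(cfg, cond, lc_t)
    lc_forces = corner_forces_from_cop(weight * (1.0 - kappa), cop_at(lc_t), cfg.geometry)
    lc_forces = lc_forces + corner_forces_from_cop(
        cfg.tare_weight_n, np.zeros(2), cfg.geometry
    )
    n_tare = max(1, int(round(cfg.tare_duration_s * cfg.loadcell_hz)))
    tare = np.tile(
        corner_forces_from_cop(cfg.tare_weight_n, np.zeros(2), cfg.geometry), (n_tare, 1)
    )
    if cfg.noise_loadcell_n > 0:
        lc_forces = lc_forces + rng.normal(0.0, cfg.noise_loadcell_n, lc_forces.shape)
        tare = tare + rng.normal(0.0, cfg.noise_loadcell_n, tare.shape)

    # Pressure mat: nominal-rate clock with uniform jitter (background-task
    # slowdowns), one frame per tick.
    period = 1.0 / cfg.mat_hz
    n_mat = int(math.floor(total / period))
    mat_t = np.arange(n_mat) * period
    if cfg.mat_jitter_frac > 0:
        mat_t = mat_t + rng.uniform(
            -cfg.mat_jitter_frac / 2, cfg.mat_jitter_frac / 2, n_mat
        ) * period
        mat_t[0] = max(mat_t[0], 0.0)
    p_left, p_right = _proportional_traces(cfg, cond, mat_t)
    mat_frames = np.stack(
        [
            render_mat_frame(
                pl, pr, cfg.baseline_peak, cfg.it_centers, cfg.noise_mat, rng,
                ambient=cfg.mat_ambient,
            )
            for pl, pr in zip(p_left, p_right)
        ]
    )

    # IMUs: mounted so upright reads ~90 deg pitch; pelvis and femur channels
    # are scaled copies of the trunk trajectory (no separate pelvis model).
    imu_t = np.arange(0.0, total, 1.0 / cfg.imu_hz)
    theta, phi, _ = _trajectory(cfg, cond, imu_t)
    th_deg, ph_deg = np.degrees(theta), np.degrees(phi)
    lift = cfg.femur_lift_gain * np.abs(ph_deg)
    imu = {
        "sternum": np.stack([90.0 + th_deg, ph_deg], axis=-1),
        "pelvis": np.stack([90.0 + cfg.pelvis_pitch_gain * th_deg, 0.6 * ph_deg], axis=-1),
        "femur_l": np.stack(
            [90.0 + cfg.femur_pitch_gain * th_deg + np.where(ph_deg < 0, lift, 0.0),
             0.2 * ph_deg], axis=-1,
        ),
        "femur_r": np.stack(
            [90.0 + cfg.femur_pitch_gain * th_deg + np.where(ph_deg > 0, lift, 0.0),
             0.2 * ph_deg], axis=-1,
        ),
    }
    if cfg.noise_imu_deg > 0:
        imu = {k: v + rng.normal(0.0, cfg.noise_imu_deg, v.shape) for k, v in imu.items()}

    return Trial(
        condition=cond,
        loadcell_t=lc_t,
        loadcell_forces=lc_forces,
        tare_frames=tare,
        mat_t=mat_t,
        mat_frames=mat_frames,
        imu_t=imu_t,
        imu=imu,
    )


#: Default per-participant parameter ranges for cohort generation (uniform
#: draws).  Chosen to span adult seated anthropometry and to reproduce the
#: order of magnitude of per-individual theoretical slopes (~ -0.03 to -0.07
#: per cm) and sine coefficients (~10-25 cm) typical of this population.
DEFAULT_COHORT_RANGES = {
    "body_mass": (55.0, 95.0),
    "trunk_length": (26.0, 36.0),
    "trunk_mass_fraction": (0.50, 0.62),
    "upper_leg_mass_fraction": (0.20, 0.28),
    "upper_leg_length": (35.0, 45.0),
    "hip_half_width": (7.0, 10.0),
    "upright_com_y": (8.0, 14.0),
    "it_offset": (3.0, 7.0),
    "upper_leg_com_y": (14.0, 20.0),
}


def draw_anthropometry(rng: np.random.Generator, ranges: dict = None) -> Anthropometry:
    """Draw one participant's anthropometry uniformly from ``ranges``."""
    r = dict(DEFAULT_COHORT_RANGES)
    if ranges:
        r.update(ranges)
    u = {k: float(rng.uniform(*v)) for k, v in r.items()}
    return Anthropometry(
        trunk_com=np.array([0.0, 0.0, u["trunk_length"]]),
        upper_leg_com=np.array([0.0, u["upper_leg_com_y"], 0.0]),
        trunk_mass_fraction=u["trunk_mass_fraction"],
        upper_leg_mass_fraction=u["upper_leg_mass_fraction"],
        upper_leg_length=u["upper_leg_length"],
        hip_half_width=u["hip_half_width"],
        it_offset=u["it_offset"],
        upright_com_y=u["upright_com_y"],
        body_mass=u["body_mass"],
    )


def make_cohort(
    n_participants: int = 10,
    seed: int = 0,
    base_cfg: Optional[SimulationConfig] = None,
    ranges: Optional[dict] = None,
    directions: Sequence[str] = DIRECTIONS,
    repetitions: int = 3,
    cushions: Sequence[str] = ("own",),
    start_positions: Sequence[str] = ("backrest",),
    group_labels: Optional[Sequence[str]] = None,
):
    """Generate a synthetic cohort and its ground-truth table.

    Returns ``(trials, truth)`` where ``trials`` is a list of
    :class:`Trial` (participants x cushions x starts x directions x
    repetitions) and ``truth`` is a DataFrame of per-participant generating
    parameters and slopes (forward beam slope, lateral slopes with the
    multiplier applied, and the sine coefficient |T| t_m).
    """
    if n_participants < 2:
        raise ValidationError("a cohort needs at least 2 participants")
    base_cfg = base_cfg or SimulationConfig()
    if group_labels is None:
        group_labels = ["AB" if i % 2 == 0 else "MWU" for i in range(n_participants)]
    trials, truth_rows = [], []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, 1_000_000 + i])
        )
        anthro = draw_anthropometry(rng, ranges)
        cfg = replace(base_cfg, anthropometry=anthro, seed=seed)
        slope = theoretical_slope(anthro)
        truth_rows.append(
            {
                "participant_id": pid,
                "group": group_labels[i],
                "body_mass": anthro.body_mass,
                "trunk_length": anthro.trunk_length,
                "trunk_mass_fraction": anthro.trunk_mass_fraction,
                "upper_leg_mass_fraction": anthro.upper_leg_mass_fraction,
                "upper_leg_length": anthro.upper_leg_length,
                "hip_half_width": anthro.hip_half_width,
                "upright_com_y": anthro.upright_com_y,
                "it_offset": anthro.it_offset,
                "slope_forward": slope,
                "slope_left": slope * cfg.lateral_slope_multiplier,
                "slope_right": slope * cfg.lateral_slope_multiplier,
                "sine_b": theoretical_sine_coefficient(anthro),
            }
        )
        for cushion in cushions:
            for start in start_positions:
                for direction in directions:
                    for rep in range(1, repetitions + 1):
                        cond = TrialCondition(
                            participant_id=pid,
                            direction=direction,
                            cushion=cushion,
                            start_position=start,
                            repetition=rep,
                            group=group_labels[i],
                        )
                        trials.append(simulate_trial(cfg, cond))
    return trials, pd.DataFrame(truth_rows)
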