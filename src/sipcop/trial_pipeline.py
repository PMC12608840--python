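"""Estimation pipeline: from raw sensor streams to SIP-CoP relationships.

Order of operations per trial, mirroring the study's processing chain:

1. tare the load cells with pre-transfer frames (cushion + mat weight off);
2. compute the CoP from the four corner forces;
3. align the three streams on the pressure mat's timestamps (lowest rate)
   by nearest-in-time pairing;
4. average the 2x2 cell block under each ischial tuberosity (IT) to one
   pressure per side, zero angles / CoP on the first half-second;
5. normalize pressures by the trial's maximum mean-IT pressure and re-base
   CoP origin and angle zeros at that maximum (the upright instant);
6. keep only the first 95% of the SIP reduction (the linear regime);
7. fit proportional pressure on CoP magnitude by ordinary least squares,
   pooling the three repetitions of a condition;
8. separately fit dCoP_y = b sin(trunk pitch) on the first 90% of samples.

Thresholds for a target proportional offload divide the target by |slope|;
Bland-Altman statistics compare fitted against theoretical slopes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .body_kinematics import SeatGeometry
from .errors import (
    DegenerateInputError,
    NoReductionError,
    ValidationError,
)
from .synthetic_trials import Trial, TrialCondition

IMU_CHANNELS = (
    "sternum_pitch", "sternum_roll", "pelvis_pitch", "pelvis_roll",
    "femur_l_pitch", "femur_l_roll", "femur_r_pitch", "femur_r_roll",
)


@dataclass(frozen=True)
class ItRegion:
    """The 2x2 mat-cell block under each IT, as top-left (row, col) anchors."""

    left: tuple
    right: tuple

    def __post_init__(self) -> None:
        for name, anchor in (("left", self.left), ("right", self.right)):
            r, c = anchor
            if not (0 <= r <= 14 and 0 <= c <= 14):
                raise ValidationError(f"{name} IT block anchor {anchor} out of grid")
        lr, lc = self.left
        rr, rc = self.right
        if lc + 1 >= rc:
            raise ValidationError(
                "left IT block must lie strictly left of the right block"
            )

    def cells(self, side: str) -> tuple:
        r, c = self.left if side == "left" else self.right
        return tuple((r + i, c + j) for i in range(2) for j in range(2))

    def block_mean(self, frames: np.ndarray, side: str) -> np.ndarray:
        r, c = self.left if side == "left" else self.right
        return np.asarray(frames)[..., r : r + 2, c : c + 2].mean(axis=(-2, -1))


@dataclass
class SipCopSeries:
    """Aligned per-mat-sample records for one trial.

    ``data`` columns: t_s, cop_x, cop_y (absolute seat frame, cm), cop_mag,
    cop_angle_deg (relative to ``cop_origin``), prop_left, prop_right (raw IT
    block means before normalization, proportional pressures after), the
    zeroed IMU channels, pairing gaps, and an ``excluded`` flag for samples
    before the re-zero instant.
    """

    data: pd.DataFrame
    cop_origin: np.ndarray
    condition: Optional[TrialCondition] = None
    normalized: bool = False
    rezero_index: int = 0


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of proportional pressure on CoP magnitude for one condition."""

    slope: float
    intercept: float
    r_squared: float
    n_samples: int
    condition: Optional[object] = None
    std_error: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValidationError("a regression needs at least 3 samples")
        if not -1e-9 <= self.r_squared <= 1.0 + 1e-9:
            raise ValidationError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class ThresholdResult:
    """CoP magnitude required for a target proportional SIP reduction."""

    direction: str
    slope_used: float
    target_reduction: float
    cop_threshold: float


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray
    loa_multiplier: float = 1.96


def cop_from_forces(forces, geom: SeatGeometry) -> np.ndarray:
    """CoP (x, y) in cm from corner forces ordered (BL, BR, FL, FR).

    x = w (F_FR + F_BR - F_FL - F_BL) / (2 sum F),
    y = d (F_FL + F_FR - F_BL - F_BR) / (2 sum F).
    Accepts one frame (4,) or a stack (n, 4).
    """
    f = np.asarray(forces, dtype=float)
    total = f.sum(axis=-1)
    if np.any(total <= 0):
        raise DegenerateInputError(
            "nonpositive total force: pre-transfer frame or sensor fault"
        )
    bl, br, fl, fr = f[..., 0], f[..., 1], f[..., 2], f[..., 3]
    x = geom.width * ((fr + br) - (fl + bl)) / (2.0 * total)
    y = geom.depth * ((fl + fr) - (bl + br)) / (2.0 * total)
    return np.stack([x, y], axis=-1)


def tare(series: np.ndarray, tare_frames: np.ndarray) -> np.ndarray:
    """Subtract the per-channel mean of the pre-transfer frames."""
    tare_frames = np.asarray(tare_frames, dtype=float)
    if tare_frames.ndim != 2 or tare_frames.shape[0] < 1:
        raise ValidationError("need at least one tare frame")
    return np.asarray(series, dtype=float) - tare_frames.mean(axis=0)


def _nearest(ts: np.ndarray, t: np.ndarray):
    """Indices of the nearest elements of sorted ``ts`` to each ``t``."""
    idx = np.searchsorted(ts, t)
    idx = np.clip(idx, 1, len(ts) - 1)
    left = ts[idx - 1]
    right = ts[idx]
    idx = idx - (t - left < right - t)
    return idx, np.abs(ts[idx] - t)


def align_streams(
    trial: Trial,
    geom: SeatGeometry,
    region: ItRegion,
    max_gap_s: float = 0.05,
    zero_window_s: float = 0.5,
) -> SipCopSeries:
    """Pair each mat frame with the nearest load-cell and IMU samples.

    The mat has the lowest rate, so its timestamps drive the output: one row
    per mat frame, with the nearest-in-time tared load-cell CoP and zeroed
    IMU angles, and the raw mean pressure of each IT block.  Mat frames with
    no counterpart within ``max_gap_s`` (or a nonpositive tared force sum)
    are dropped with a warning.  Angle zeros and the CoP origin come from
    each stream's first ``zero_window_s`` of data.
    """
    tared = tare(trial.loadcell_forces, trial.tare_frames)
    lc_idx, lc_gap = _nearest(trial.loadcell_t, trial.mat_t)
    imu_idx, imu_gap = _nearest(trial.imu_t, trial.mat_t)
    keep = (lc_gap <= max_gap_s) & (imu_gap <= max_gap_s)
    total = tared[lc_idx].sum(axis=-1)
    keep &= total > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} mat frame(s): pairing gap > {max_gap_s} s "
            "or nonpositive tared force",
            stacklevel=2,
        )
    if not keep.any():
        raise DegenerateInputError("no mat frames could be paired")

    cop = cop_from_forces(tared[lc_idx[keep]], geom)
    lc_zero = trial.loadcell_t <= trial.loadcell_t[0] + zero_window_s
    origin = cop_from_forces(tared[lc_zero], geom).mean(axis=0)
    rel = cop - origin
    mag = np.hypot(rel[:, 0], rel[:, 1])
    angle = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))

    imu_zero = trial.imu_t <= trial.imu_t[0] + zero_window_s
    cols = {
        "t_s": trial.mat_t[keep],
        "cop_x": cop[:, 0],
        "cop_y": cop[:, 1],
        "cop_mag": mag,
        "cop_angle_deg": angle,
        "prop_left": region.block_mean(trial.mat_frames[keep], "left"),
        "prop_right": region.block_mean(trial.mat_frames[keep], "right"),
    }
    for sensor in ("sternum", "pelvis", "femur_l", "femur_r"):
        sig = trial.imu[sensor]
        zeros = sig[imu_zero].mean(axis=0)
        picked = sig[imu_idx[keep]] - zeros
        cols[f"{sensor}_pitch"] = picked[:, 0]
        cols[f"{sensor}_roll"] = picked[:, 1]
    cols["gap_lc_s"] = lc_gap[keep]
    cols["gap_imu_s"] = imu_gap[keep]
    cols["excluded"] = np.zeros(int(keep.sum()), dtype=bool)
    return SipCopSeries(
        data=pd.DataFrame(cols),
        cop_origin=origin,
        condition=trial.condition,
    )


def select_it_regions(
    static_frames: np.ndarray,
    fallback_forward_frames: Optional[np.ndarray] = None,
    tie_tol: float = 1e-9,
) -> ItRegion:
    """Locate the 2x2 block of highest mean static pressure under each IT.

    The grid is split at its column midline (left IT in columns 0-7, right in
    8-15) and every 2x2 window wholly inside a half is scored by its summed
    mean static pressure.  Near-ties (within ``tie_tol``) are resolved by
    persistence during the first forward-lean trial -- the block whose mean
    stays above half its own maximum for the most frames -- and any remaining
    tie by the lowest (row, col) anchor.
    """
    frames = np.asarray(static_frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    mean = frames.mean(axis=0)
    n_rows, n_cols = mean.shape
    half = n_cols // 2
    anchors = {}
    for side, (c_lo, c_hi) in (("left", (0, half)), ("right", (half, n_cols))):
        if mean[:, c_lo:c_hi].sum() <= 0:
            raise DegenerateInputError(f"{side} half of the mat carries no pressure")
        cands = [
            ((r, c), mean[r : r + 2, c : c + 2].sum())
            for r in range(n_rows - 1)
            for c in range(c_lo, c_hi - 1)
        ]
        best = max(s for _, s in cands)
        tied = sorted(a for a, s in cands if s >= best - tie_tol)
        if len(tied) > 1 and fallback_forward_frames is not None:
            scores = []
            for r, c in tied:
                trace = np.asarray(fallback_forward_frames)[:, r : r + 2, c : c + 2].sum(
                    axis=(1, 2)
                )
                scores.append(int((trace >= 0.5 * trace.max()).sum()))
            top = max(scores)
            tied = [a for a, s in zip(tied, scores) if s == top]
        anchors[side] = tied[0]
    return ItRegion(left=anchors["left"], right=anchors["right"])


def normalize_and_rezero(
    series: SipCopSeries, peak_window_s: float = 0.5
) -> SipCopSeries:
    """Normalize IT pressures by the trial maximum and re-base zeros there.

    The mean of the two IT pressures peaks when the participant sits fully
    upright; all pressures are divided by that maximum, and the CoP origin
    and angle zeros are re-based at the peak-time sample.  Samples before the
    peak are flagged excluded.  Idempotent.

    The peak is located and valued on a centered ``peak_window_s`` moving
    average of the mean-IT trace rather than on a single sample: the raw
    maximum of a noisy trace is biased upward (it selects the largest noise
    excursion), which would systematically flatten every fitted slope.  On
    noise-free data with an upright dwell at least as long as the window the
    two definitions coincide exactly.
    """
    df = series.data.copy()
    mean_trace = (df["prop_left"].to_numpy() + df["prop_right"].to_numpy()) / 2.0
    if len(df) == 0 or not np.isfinite(mean_trace).any():
        raise DegenerateInputError("empty series")
    dt = float(np.median(np.diff(df["t_s"]))) if len(df) > 1 else peak_window_s
    w = max(1, int(round(peak_window_s / max(dt, 1e-9))))
    w += 1 - w % 2  # centered window: odd length
    smoothed = (
        pd.Series(mean_trace).rolling(w, center=True, min_periods=1).mean().to_numpy()
    )
    peak = int(np.argmax(smoothed))
    mmax = smoothed[peak]
    if mmax <= 0:
        raise DegenerateInputError("maximum mean IT pressure is zero")
    df["prop_left"] = df["prop_left"] / mmax
    df["prop_right"] = df["prop_right"] / mmax
    origin = np.array([df["cop_x"].iloc[peak], df["cop_y"].iloc[peak]])
    rel_x = df["cop_x"].to_numpy() - origin[0]
    rel_y = df["cop_y"].to_numpy() - origin[1]
    df["cop_mag"] = np.hypot(rel_x, rel_y)
    df["cop_angle_deg"] = np.degrees(np.arctan2(rel_y, rel_x))
    for col in IMU_CHANNELS:
        df[col] = df[col] - df[col].iloc[peak]
    df["excluded"] = np.arange(len(df)) < peak
    return SipCopSeries(
        data=df,
        cop_origin=origin,
        condition=series.condition,
        normalized=True,
        rezero_index=peak,
    )


def tracked_pressure(series: SipCopSeries, direction: Optional[str] = None) -> np.ndarray:
    """The proportional pressure the analysis tracks for a lean direction:
    the mean of both ITs for forward leans, the offloaded side for lateral
    leans (right IT for a left lean and vice versa)."""
    if direction is None:
        direction = series.condition.direction if series.condition else "forward"
    df = series.data
    if direction == "left":
        return df["prop_right"].to_numpy()
    if direction == "right":
        return df["prop_left"].to_numpy()
    return (df["prop_left"].to_numpy() + df["prop_right"].to_numpy()) / 2.0


def truncate_to_95(
    series: SipCopSeries,
    direction: Optional[str] = None,
    fraction: float = 0.95,
) -> SipCopSeries:
    """Keep the re-zeroed prefix covering the first 95% of the SIP reduction.

    With p the tracked proportional pressure and p_min its minimum after the
    re-zero instant, samples are kept from the re-zero time until p first
    reaches p_min + (1 - fraction) (1 - p_min); later samples (the nonlinear
    plateau) are dropped.  A trial with no reduction raises
    :class:`NoReductionError` and must be excluded.
    """
    if not series.normalized:
        raise ValidationError("truncate_to_95 requires a normalized series")
    df = series.data.iloc[series.rezero_index :].reset_index(drop=True)
    p = tracked_pressure(
        SipCopSeries(df, series.cop_origin, series.condition, True, 0), direction
    )
    p_min = float(p.min())
    if p_min >= 1.0 - 1e-12:
        raise NoReductionError("no SIP reduction in trial; excluded")
    threshold = p_min + (1.0 - fraction) * (1.0 - p_min)
    cut = int(np.argmax(p <= threshold))
    out = df.iloc[: cut + 1].reset_index(drop=True)
    return SipCopSeries(
        data=out,
        cop_origin=series.cop_origin,
        condition=series.condition,
        normalized=True,
        rezero_index=0,
    )


def fit_sip_cop_line(
    series: Union[SipCopSeries, Sequence[SipCopSeries]],
    direction: Optional[str] = None,
    condition: Optional[object] = None,
) -> RegressionResult:
    """OLS of tracked proportional pressure on CoP magnitude, pooling the
    raw samples of all supplied (repetition) series."""
    series_list = [series] if isinstance(series, SipCopSeries) else list(series)
    mags, props = [], []
    for s in series_list:
        df = s.data[~s.data["excluded"]]
        mags.append(df["cop_mag"].to_numpy())
        props.append(
            tracked_pressure(
                SipCopSeries(df, s.cop_origin, s.condition, s.normalized, 0), direction
            )
        )
    x = np.concatenate(mags)
    y = np.concatenate(props)
    if len(x) < 3:
        raise ValidationError("need at least 3 pooled samples for a regression")
    if np.ptp(x) <= 0:
        raise DegenerateInputError("zero CoP variance; cannot fit SIP-CoP line")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_samples=len(x),
        condition=condition
        if condition is not None
        else (series_list[0].condition if len(series_list) == 1 else None),
        std_error=float(fit.stderr),
    )


def fit_sine(
    series: Union[SipCopSeries, Sequence[SipCopSeries]],
    fraction: float = 0.90,
):
    """Least-squares b in dCoP_y = b sin(sternum pitch change).

    Only the first ``fraction`` of each series' samples (counted from the
    re-zero instant) enter the fit, excluding the end-of-lean discontinuities
    and plateaus.  Returns ``(b, r_squared)``.
    """
    series_list = [series] if isinstance(series, SipCopSeries) else list(series)
    ys, ss = [], []
    for s in series_list:
        df = s.data.iloc[s.rezero_index :]
        n90 = max(3, int(math.floor(fraction * len(df))))
        df = df.iloc[:n90]
        dy = df["cop_y"].to_numpy() - s.cop_origin[1]
        ys.append(dy)
        ss.append(np.sin(np.radians(df["sternum_pitch"].to_numpy())))
    y = np.concatenate(ys)
    s_ = np.concatenate(ss)
    if len(y) < 3:
        raise ValidationError("need at least 3 samples in the first 90% to fit")
    denom = float(np.dot(s_, s_))
    if denom <= 1e-12:
        raise DegenerateInputError("all angles zero; sine fit degenerate")
    b = float(np.dot(y, s_) / denom)
    resid = y - b * s_
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    r2 = 1.0 if ss_tot <= 1e-15 and ss_res <= 1e-15 else 1.0 - ss_res / max(ss_tot, 1e-300)
    return b, r2


def cop_threshold(slope: float, target_reduction: float) -> float:
    """CoP magnitude (cm) needed for a target proportional SIP reduction:
    target / |slope|, for a negative slope."""
    if slope >= 0:
        raise ValidationError(f"slope must be negative, got {slope}")
    if not 0.0 <= target_reduction <= 1.0:
        raise ValidationError("target_reduction must lie in [0, 1]")
    return target_reduction / abs(slope)


def bland_altman(
    pairs: Iterable, loa_multiplier: float = 1.96
) -> BlandAltmanResult:
    """Agreement statistics between fitted and theoretical slopes.

    Differences are fitted - theoretical; limits of agreement are
    mean_diff +/- ``loa_multiplier`` * SD(diff).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValidationError("need at least 2 (fitted, theoretical) pairs")
    fitted, theoretical = arr[:, 0], arr[:, 1]
    diffs = fitted - theoretical
    means = (fitted + theoretical) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - loa_multiplier * sd_diff,
        loa_high=mean_diff + loa_multiplier * sd_diff,
        means=means,
        diffs=diffs,
        loa_multiplier=loa_multiplier,
    )


# ---------------------------------------------------------------------------
# Cohort-level driver


@dataclass
class CohortResults:
    """Outputs of :func:`process_cohort`."""

    regressions: pd.DataFrame
    sine_fits: pd.DataFrame
    lmm_rows: pd.DataFrame
    regions: dict
    exclusions: list


def process_cohort(
    trials: Sequence[Trial],
    geom: Optional[SeatGeometry] = None,
    max_gap_s: float = 0.05,
    zero_window_s: float = 0.5,
    truncation: float = 0.95,
    sine_fraction: float = 0.90,
    static_window_s: float = 1.0,
) -> CohortResults:
    """Run the full per-trial pipeline over a cohort and pool per condition.

    IT regions are located per participant from the opening static window of
    their first forward trial (with the whole trial as the persistence
    fallback).  Repetitions of each participant x cushion x start x direction
    condition are pooled into one regression; forward conditions also get a
    sine fit.  Trials without a pressure reduction are excluded and listed.
    """
    geom = geom or SeatGeometry()
    by_participant: dict = {}
    for tr in trials:
        by_participant.setdefault(tr.condition.participant_id, []).append(tr)

    reg_rows, sine_rows, lmm_parts, exclusions = [], [], [], []
    regions = {}
    for pid in sorted(by_participant):
        p_trials = by_participant[pid]
        ref = next(
            (t for t in p_trials if t.condition.direction == "forward"), p_trials[0]
        )
        static = ref.mat_frames[ref.mat_t <= ref.mat_t[0] + static_window_s]
        region = select_it_regions(static, fallback_forward_frames=ref.mat_frames)
        regions[pid] = region

        by_cond: dict = {}
        for tr in p_trials:
            c = tr.condition
            by_cond.setdefault((c.cushion, c.start_position, c.direction), []).append(tr)
        for (cushion, start, direction), group in sorted(by_cond.items()):
            kept = []
            for tr in group:
                try:
                    s = align_streams(
                        tr, geom, region, max_gap_s=max_gap_s,
                        zero_window_s=zero_window_s,
                    )
                    s = normalize_and_rezero(s)
                    s = truncate_to_95(s, direction=direction, fraction=truncation)
                    kept.append(s)
                except (NoReductionError, DegenerateInputError) as exc:
                    exclusions.append((tr.condition.key(), str(exc)))
            if not kept:
                continue
            cond_label = f"{cushion}-{start}-{direction}"
            fit = fit_sip_cop_line(kept, direction=direction, condition=cond_label)
            grp = group[0].condition.group
            reg_rows.append(
                {
                    "participant": pid,
                    "group": grp,
                    "condition": cond_label,
                    "cushion": cushion,
                    "start_position": start,
                    "direction": direction,
                    "slope": fit.slope,
                    "se": fit.std_error,
                    "intercept": fit.intercept,
                    "r2": fit.r_squared,
                    "n": fit.n_samples,
                }
            )
            if direction == "forward":
                b, r2 = fit_sine(kept, fraction=sine_fraction)
                sine_rows.append(
                    {
                        "participant": pid,
                        "group": grp,
                        "cushion": cushion,
                        "start_position": start,
                        "b_fitted": b,
                        "r2": r2,
                    }
                )
            for s in kept:
                df = s.data
                lmm_parts.append(
                    pd.DataFrame(
                        {
                            "participant": pid,
                            "group": grp,
                            "cushion": cushion,
                            "start_position": start,
                            "direction": direction,
                            "cop_mag": df["cop_mag"].to_numpy(),
                            "prop_pressure": tracked_pressure(s, direction),
                        }
                    )
                )
    return CohortResults(
        regressions=pd.DataFrame(reg_rows),
        sine_fits=pd.DataFrame(sine_rows),
        lmm_rows=pd.concat(lmm_parts, ignore_index=True)
        if lmm_parts
        else pd.DataFrame(),
        regions=regions,
        exclusions=exclusions,
    )
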