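"""Behavioural measures for force-field reaching trials.

Two scalar measures quantify adaptation:

* **Target error (TE)** -- signed x-deviation (mm) of the movement endpoint
  from the straight start->target line.  The endpoint is the hand position at
  the first sample (after movement onset) where hand speed falls below
  20 mm/s, mirroring the online endpoint-lock trigger.  ``|TE|`` larger than
  the target radius (7.5 mm) defines task failure.
* **Lateral deviation (LD)** -- signed x-deviation (mm) of the hand path at
  mid-reach, y = 75 mm, linearly interpolated at the first crossing.

Also here: resampling of x at fixed y stations for participant-averaged
paths, trial-epoch summaries, baseline subtraction, and the trial-exclusion
and participant-screening rules (reach distance < 75 mm excludes a trial;
baseline |LD| must average below 4.5 mm over the last 20 baseline trials;
participants with unstable late de-adaptation are flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

TARGET_RADIUS_MM = 7.5
#: failure bound for the kinematic-plan layer: the full target circle
#: (15 mm diameter) -- a reach "fails" when the endpoint misses the target,
#: while statistical tests compare |TE| with the 7.5 mm radius.
TARGET_SIZE_MM = 15.0
SPEED_THRESHOLD = 0.020  # m/s, endpoint definition
MID_Y_MM = 75.0
MIN_REACH_MM = 75.0

#: y stations (mm) at which averaged trajectories are resampled.
DEFAULT_Y_GRID_MM = (7.5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 110, 120, 130, 140, 150)

#: Trial windows (1-based, inclusive) used for epoch summaries.
DEFAULT_EPOCHS = {
    "adapt_1": (1, 1),
    "adapt_3_5": (3, 5),
    "adapt_136_155": (136, 155),
    "deadapt_1": (156, 156),
    "deadapt_3_5": (158, 160),
    "deadapt_131_150": (286, 305),
}


@dataclass
class TrialRecord:
    trial: int
    phase: str
    te_mm: float
    ld_mm: float
    reach_distance_mm: float
    valid: bool


def _endpoint_index(traj: Trajectory) -> tuple[int, bool]:
    """Index of the endpoint sample (first sub-threshold speed after onset).

    Returns (index, flagged); flagged is True when the speed never falls
    below threshold and the last sample is used instead.
    """
    speeds = traj.speeds
    moving = np.flatnonzero(speeds >= SPEED_THRESHOLD)
    if moving.size == 0:
        return len(speeds) - 1, True
    below = np.flatnonzero(speeds[moving[0]:] < SPEED_THRESHOLD)
    if below.size == 0:
        return len(speeds) - 1, True
    return int(moving[0] + below[0]), False


def target_error(traj: Trajectory) -> float:
    """Signed TE in mm (+x positive)."""
    idx, _ = _endpoint_index(traj)
    return float(traj.positions[idx, 0] * 1000.0)


def endpoint(traj: Trajectory) -> np.ndarray:
    """Endpoint position (m) at the first sub-threshold-speed sample."""
    idx, _ = _endpoint_index(traj)
    return traj.positions[idx].copy()


def reach_distance(traj: Trajectory) -> float:
    """Largest forward distance attained, mm."""
    return float(np.max(traj.positions[:, 1]) * 1000.0)


def _first_crossing_x(traj: Trajectory, y_mm: float) -> float:
    """x (mm) at the first crossing of the given forward distance,
    linearly interpolated between the bracketing samples."""
    y = traj.positions[:, 1] * 1000.0
    x = traj.positions[:, 0] * 1000.0
    at = np.flatnonzero(y >= y_mm)
    if at.size == 0:
        return np.nan
    i = int(at[0])
    if i == 0 or y[i] == y_mm:
        return float(x[i])
    f = (y_mm - y[i - 1]) / (y[i] - y[i - 1])
    return float(x[i - 1] + f * (x[i] - x[i - 1]))


def lateral_deviation(traj: Trajectory) -> float:
    """Signed LD in mm; NaN when the reach never attains y = 75 mm."""
    if reach_distance(traj) < MIN_REACH_MM:
        return np.nan
    return _first_crossing_x(traj, MID_Y_MM)


def resample_x_at_y(traj: Trajectory, y_grid_mm=DEFAULT_Y_GRID_MM) -> np.ndarray:
    """x (mm) at each y station (mm); NaN where the reach falls short."""
    return np.array([_first_crossing_x(traj, y) for y in y_grid_mm])


def trial_record(traj: Trajectory, trial: int, phase: str) -> TrialRecord:
    rd = reach_distance(traj)
    valid = rd >= MIN_REACH_MM
    return TrialRecord(
        trial=trial,
        phase=phase,
        te_mm=target_error(traj),
        ld_mm=lateral_deviation(traj) if valid else np.nan,
        reach_distance_mm=rd,
        valid=valid,
    )


def epoch_summary(series, epochs: dict[str, tuple[int, int]] = DEFAULT_EPOCHS) -> dict[str, float]:
    """Mean of a per-trial series over each named epoch window (1-based,
    inclusive); NaN-valid trials are skipped."""
    series = np.asarray(series, dtype=float)
    out = {}
    for name, (lo, hi) in epochs.items():
        window = series[lo - 1 : hi]
        out[name] = float(np.nanmean(window)) if np.any(np.isfinite(window)) else np.nan
    return out


def baseline_subtract(ld_series, baseline_last20_mean: float) -> np.ndarray:
    """LD series with the participant's baseline mean (last 20 baseline
    trials) removed."""
    return np.asarray(ld_series, dtype=float) - float(baseline_last20_mean)


def exclude_short_reaches(records: list[TrialRecord]) -> list[TrialRecord]:
    """Drop exactly the trials whose reach distance is below 75 mm."""
    return [r for r in records if r.valid]


def screen_participant(baseline_ld_mm) -> bool:
    """Baseline screening: pass iff |mean LD| over the last 20 baseline
    trials is strictly less than 4.5 mm."""
    ld = np.asarray(baseline_ld_mm, dtype=float)
    return bool(abs(np.nanmean(ld[-20:])) < 4.5)


def count_jumps(ld_mm, jump_mm: float = 20.0) -> int:
    """Consecutive-trial sign changes of LD with |delta LD| > jump_mm."""
    ld = np.asarray(ld_mm, dtype=float)
    ld = ld[np.isfinite(ld)]
    if ld.size < 2:
        return 0
    sign_change = np.sign(ld[1:]) * np.sign(ld[:-1]) < 0
    big = np.abs(np.diff(ld)) > jump_mm
    return int(np.sum(sign_change & big))


def flag_unstable_participant(
    deadapt_ld_mm, group_last20_mean: float, group_last20_sd: float
) -> bool:
    """Participant-level exclusion for unstable late de-adaptation.

    True iff the last 100 de-adaptation trials contain at least three large
    jumps across the x-axis (consecutive-trial LD sign change with
    |delta LD| > 20 mm) AND the participant's last-20-trial LD mean lies
    outside 3 s.d. of the group mean.
    """
    ld = np.asarray(deadapt_ld_mm, dtype=float)
    jumps = count_jumps(ld[-100:])
    own_mean = np.nanmean(ld[-20:])
    outlier = abs(own_mean - group_last20_mean) > 3.0 * group_last20_sd
    return bool(jumps >= 3 and outlier)
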