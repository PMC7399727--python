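"""Trial and feature table I/O, cycle selection, and torque-grid resampling.

The interchange format is a long-format CSV, one row per recorded sample.
Columns (exact names)::

    subject_id, group, knee, day, cycle, sweep, sample_idx, torque_nm,
    rot_z_deg, rot_y_deg, rot_x_deg, trans_z_mm, trans_y_mm, trans_x_mm

``rot_z_deg`` is the driven axial rotation (primary motion); the remaining
five channels are the coupled secondary motions.  ``sweep`` is ``ER`` for
sweeps loading towards external rotation (torque non-increasing) and ``IR``
for internal (torque non-decreasing).  Sign convention: external rotation is
negative torque and negative axial rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MonotonicityError, SchemaError

KEY_COLUMNS = ["subject_id", "group", "knee", "day"]
SAMPLE_COLUMNS = ["cycle", "sweep", "sample_idx", "torque_nm"]
CHANNELS = ["rot_z_deg", "rot_y_deg", "rot_x_deg",
            "trans_z_mm", "trans_y_mm", "trans_x_mm"]
TRIAL_COLUMNS = KEY_COLUMNS + SAMPLE_COLUMNS + CHANNELS

FEATURE_COLUMNS = [
    "subject_id", "group", "knee", "day",
    "max_er_deg", "max_ir_deg", "rot_at_zero_deg", "tp_er_deg", "tp_ir_deg",
    "er_laxity_deg", "ir_laxity_deg", "slack_deg",
]

#: Slop allowed on |torque| beyond the nominal limit before warning (N·m).
TORQUE_TOLERANCE = 0.5


@dataclass
class TrialRecord:
    """One device test: all samples for one (subject, knee, day)."""

    subject_id: str
    knee: str
    day: int
    samples: pd.DataFrame  # columns: SAMPLE_COLUMNS + CHANNELS
    group: str = "all"

    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.knee, self.day)

    def to_frame(self) -> pd.DataFrame:
        df = self.samples.copy()
        df.insert(0, "day", self.day)
        df.insert(0, "knee", self.knee)
        df.insert(0, "group", self.group)
        df.insert(0, "subject_id", self.subject_id)
        return df[TRIAL_COLUMNS]


@dataclass
class SampledCurve:
    """Per-sweep channel values interpolated onto a common torque grid.

    ``values`` maps ``(sweep, channel)`` to an array aligned with
    ``torque_grid``; grid points outside a sweep's observed torque range hold
    NaN (never extrapolated).
    """

    torque_grid: np.ndarray
    values: dict[tuple[str, str], np.ndarray]
    meta: dict = field(default_factory=dict)


def _check_sweep_monotone(df: pd.DataFrame, context: str) -> None:
    # a cycle may hold two same-direction sweeps (the lead-in), so split into
    # contiguous runs rather than grouping by value
    run = ((df["cycle"] != df["cycle"].shift())
           | (df["sweep"] != df["sweep"].shift())).cumsum()
    for _, grp in df.groupby(run, sort=False):
        cycle, sweep = grp["cycle"].iloc[0], grp["sweep"].iloc[0]
        tau = grp["torque_nm"].to_numpy(float)
        d = np.diff(tau)
        ok = np.all(d >= -1e-9) if sweep == "IR" else np.all(d <= 1e-9)
        if not ok:
            raise MonotonicityError(
                f"non-monotone torque in sweep ({context}, cycle={cycle}, "
                f"sweep={sweep})"
            )


def trials_to_frame(trials) -> pd.DataFrame:
    return pd.concat([t.to_frame() for t in trials], ignore_index=True)


def frame_to_trials(df: pd.DataFrame, strict: bool = True,
                    validate: bool = True) -> list[TrialRecord]:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError("required column absent: " + ", ".join(missing))
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra and strict:
        raise SchemaError("unknown columns in strict mode: " + ", ".join(extra))
    over = df["torque_nm"].abs() > 6.0 + TORQUE_TOLERANCE
    if validate and over.any():
        warnings.warn(
            f"{int(over.sum())} samples exceed the nominal torque range "
            "(rows kept)", stacklevel=2,
        )
    trials = []
    for (sid, group, knee, day), grp in df.groupby(KEY_COLUMNS, sort=True):
        samples = grp[SAMPLE_COLUMNS + CHANNELS].reset_index(drop=True)
        if validate:
            _check_sweep_monotone(
                samples, f"subject={sid}, knee={knee}, day={day}")
        trials.append(TrialRecord(
            subject_id=str(sid), group=str(group), knee=str(knee),
            day=int(day), samples=samples,
        ))
    return trials


def write_trials(trials, path) -> None:
    trials_to_frame(trials).to_csv(path, index=False, float_format="%.10g")


def read_trials(path, strict: bool = True) -> list[TrialRecord]:
    df = pd.read_csv(path)
    return frame_to_trials(df, strict=strict)


def write_features(features: pd.DataFrame, path) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise SchemaError("required column absent: " + ", ".join(missing))
    features[FEATURE_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError("required column absent: " + ", ".join(missing))
    return df


def extract_third_cycle(trial: TrialRecord) -> TrialRecord:
    """Return the analysis cycle: cycle 3, one ER- and one IR-directed sweep."""
    cycles = set(trial.samples["cycle"])
    if 3 not in cycles:
        raise ValueError(
            f"cycle 3 absent (subject={trial.subject_id}, knee={trial.knee}, "
            f"day={trial.day}; cycles present: {sorted(cycles)})"
        )
    third = trial.samples[trial.samples["cycle"] == 3].reset_index(drop=True)
    return TrialRecord(
        subject_id=trial.subject_id, knee=trial.knee, day=trial.day,
        samples=third, group=trial.group,
    )


def make_torque_grid(torque_limit: float = 6.0, grid_step: float = 0.1) -> np.ndarray:
    if grid_step <= 0:
        raise ValueError(f"grid_step must be positive, got {grid_step}")
    n = int(round(2.0 * torque_limit / grid_step)) + 1
    return np.linspace(-torque_limit, torque_limit, n)


def resample_to_torque_grid(
    cycle: TrialRecord,
    grid_step: float = 0.1,
    torque_limit: float = 6.0,
) -> SampledCurve:
    """Linearly interpolate each channel of each sweep onto a shared grid.

    Interpolation is exact at grid-aligned input torques and never
    extrapolates: grid points outside a sweep's observed torque range are NaN.
    """
    grid = make_torque_grid(torque_limit, grid_step)
    values: dict[tuple[str, str], np.ndarray] = {}
    for sweep, grp in cycle.samples.groupby("sweep", sort=False):
        tau = grp["torque_nm"].to_numpy(float)
        order = np.argsort(tau, kind="stable")
        tau_sorted = tau[order]
        inside = (grid >= tau_sorted[0] - 1e-12) & (grid <= tau_sorted[-1] + 1e-12)
        for ch in CHANNELS:
            y = grp[ch].to_numpy(float)[order]
            out = np.full(grid.shape, np.nan)
            out[inside] = np.interp(grid[inside], tau_sorted, y)
            values[(sweep, ch)] = out
    return SampledCurve(
        torque_grid=grid,
        values=values,
        meta={"subject_id": cycle.subject_id, "knee": cycle.knee,
              "day": cycle.day, "group": cycle.group},
    )
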