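"""Test-retest reliability: ICC(2,1), SEM, MDC90 and pointwise curves.

ICC(2,1) is the two-way random-effects, absolute-agreement, single-
measurement intraclass correlation (Shrout & Fleiss).  For a units × trials
matrix with between-units mean square BMS, trial (column) mean square TMS and
error mean square EMS:

    ICC(2,1) = (BMS - EMS) / (BMS + (k-1)·EMS + k·(TMS - EMS)/n)

The standard error of measurement is the square root of the residual error
variance of the nested subject/knee/day mixed model, in measurement units,
and the minimal detectable change at 90% confidence is
MDC90 = 1.65 · √2 · SEM.

The pointwise ("simple functional") analysis repeats ICC and SEM at every
point of a common torque grid for one motion channel, treating subject-knee
combinations as measurement units and days as trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError
from .io import CHANNELS, SampledCurve, extract_third_cycle, resample_to_torque_grid
from .nested_anova import nested_variance_components

MDC90_FACTOR = 1.65 * np.sqrt(2.0)


@dataclass(frozen=True)
class AnovaMeanSquares:
    """Two-way ANOVA mean squares underlying an ICC(2,1) value."""

    bms: float
    tms: float
    ems: float
    n_units: int
    n_trials: int


@dataclass
class ReliabilityCurve:
    """Pointwise mean, ICC(2,1) and SEM along the torque grid, per sweep."""

    channel: str
    sweep: np.ndarray        # sweep label per row
    torque_grid: np.ndarray
    mean: np.ndarray
    icc: np.ndarray
    sem: np.ndarray
    n_units: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": self.channel, "sweep": self.sweep,
            "torque_nm": self.torque_grid, "mean": self.mean,
            "icc": self.icc, "sem": self.sem, "n_units": self.n_units,
        })


def icc_2_1(matrix, drop_missing: bool = True) -> tuple[float, AnovaMeanSquares]:
    """ICC(2,1) of a units × trials matrix, with the mean squares for audit.

    Rows with missing cells are dropped (with a warning) when
    ``drop_missing`` is true.  A matrix with zero total variance returns an
    ICC of 0 with a warning, since agreement is undefined without variance.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise DesignError("matrix must be 2-D (units × trials)")
    bad = np.isnan(x).any(axis=1)
    if bad.any():
        if not drop_missing:
            raise DesignError("matrix contains missing cells")
        warnings.warn(f"dropping {int(bad.sum())} units with missing cells",
                      stacklevel=2)
        x = x[~bad]
    n, k = x.shape
    if n < 2 or k < 2:
        raise DesignError(f"need at least 2 units and 2 trials, got {n}×{k}")
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    bms = k * np.sum((row_m - grand) ** 2) / (n - 1)
    tms = n * np.sum((col_m - grand) ** 2) / (k - 1)
    ems = np.sum((x - row_m[:, None] - col_m[None, :] + grand) ** 2) \
        / ((n - 1) * (k - 1))
    ms = AnovaMeanSquares(bms=float(bms), tms=float(tms), ems=float(ems),
                          n_units=n, n_trials=k)
    denom = bms + (k - 1) * ems + k * (tms - ems) / n
    if denom <= 0.0:
        warnings.warn("zero total variance; ICC defined as 0", stacklevel=2)
        return 0.0, ms
    return float((bms - ems) / denom), ms


def sem_absolute(residual_variance: float) -> float:
    """SEM = square root of the residual error variance (measurement units)."""
    if residual_variance < 0:
        raise ValueError(f"residual variance must be >= 0, got {residual_variance}")
    return float(np.sqrt(residual_variance))


def mdc90(sem: float) -> float:
    """Minimal detectable change at 90% confidence: 1.65 · √2 · SEM."""
    if sem < 0:
        raise ValueError(f"SEM must be >= 0, got {sem}")
    return float(MDC90_FACTOR * sem)


def interpret_icc(value: float) -> str:
    """Reliability label for an ICC value.

    poor < 0.5 <= moderate < 0.75 <= good <= 0.9 < excellent.  Both interval
    boundaries 0.75 and 0.9 belong to "good".
    """
    if value > 1.0 + 1e-12:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def _unit_day_panel(curves: list[SampledCurve], channel: str, sweep: str):
    """Stack curves into value[unit, day, grid] with unit = subject-knee."""
    units = sorted({(c.meta["subject_id"], c.meta["knee"]) for c in curves})
    days = sorted({c.meta["day"] for c in curves})
    n_grid = curves[0].torque_grid.size
    panel = np.full((len(units), len(days), n_grid), np.nan)
    index = {(u, d): (i, j) for i, u in enumerate(units)
             for j, d in enumerate(days)}
    for c in curves:
        i, j = index[((c.meta["subject_id"], c.meta["knee"]), c.meta["day"])]
        panel[i, j] = c.values[(sweep, channel)]
    return panel, units, days


def pointwise_reliability(
    trials,
    channel: str = "rot_z_deg",
    grid_step: float = 0.1,
    torque_limit: float = 6.0,
    sweeps: tuple[str, ...] = ("ER", "IR"),
    max_missing_frac: float = 0.2,
) -> ReliabilityCurve:
    """Pointwise mean, ICC(2,1) and SEM along the torque grid.

    Every trial's analysis cycle is resampled onto the shared grid.  At each
    grid point, measurement units are subject-knee combinations and trials
    are days: ICC(2,1) comes from :func:`icc_2_1`, and the SEM is the square
    root of the residual variance of the nested subject/knee/day model
    (knee as a fixed effect).  The two sweep directions are analysed
    separately and stacked.

    Units missing a value at a grid point are dropped listwise there; if more
    than ``max_missing_frac`` of units are missing, the point is flagged
    absent (NaN outputs) rather than interpolated.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; choose from {CHANNELS}")
    curves = [
        resample_to_torque_grid(extract_third_cycle(t), grid_step, torque_limit)
        for t in trials
    ]
    if not curves:
        raise DesignError("no trials supplied")
    days_per_unit = {}
    for c in curves:
        days_per_unit.setdefault(
            (c.meta["subject_id"], c.meta["knee"]), set()).add(c.meta["day"])
    day_sets = set(map(frozenset, days_per_unit.values()))
    if len(day_sets) > 1:
        warnings.warn("units measured on unequal day sets; incomplete units "
                      "are dropped pointwise", stacklevel=2)

    grid = curves[0].torque_grid
    all_sweep, all_tau, all_mean, all_icc, all_sem, all_n = [], [], [], [], [], []
    for sweep in sweeps:
        panel, units, days = _unit_day_panel(curves, channel, sweep)
        knee_of_unit = np.array([u[1] for u in units])
        subj_of_unit = np.array([u[0] for u in units])
        for g in range(grid.size):
            mat = panel[:, :, g]
            complete = ~np.isnan(mat).any(axis=1)
            n_ok = int(complete.sum())
            if n_ok < max(2, (1.0 - max_missing_frac) * len(units)):
                all_mean.append(np.nan); all_icc.append(np.nan)
                all_sem.append(np.nan); all_n.append(n_ok)
                continue
            sub = mat[complete]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                icc, _ = icc_2_1(sub, drop_missing=False)
                long = pd.DataFrame({
                    "subject_id": np.repeat(subj_of_unit[complete], len(days)),
                    "knee": np.repeat(knee_of_unit[complete], len(days)),
                    "day": np.tile(days, n_ok),
                    "value": sub.ravel(),
                })
                vc = nested_variance_components(long)
            all_mean.append(float(sub.mean()))
            all_icc.append(icc)
            all_sem.append(sem_absolute(vc.var_residual))
            all_n.append(n_ok)
        all_sweep.extend([sweep] * grid.size)
        all_tau.extend(grid.tolist())
    return ReliabilityCurve(
        channel=channel,
        sweep=np.array(all_sweep),
        torque_grid=np.array(all_tau),
        mean=np.array(all_mean),
        icc=np.array(all_icc),
        sem=np.array(all_sem),
        n_units=np.array(all_n),
    )


def plot_reliability_curve(curve: ReliabilityCurve, path=None):
    """Mean ± SEM band with ICC(2,1) on a secondary axis, per sweep."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sweeps = list(dict.fromkeys(curve.sweep.tolist()))
    fig, axes = plt.subplots(1, len(sweeps), figsize=(5 * len(sweeps), 3.5),
                             squeeze=False)
    for ax, sweep in zip(axes[0], sweeps):
        m = curve.sweep == sweep
        tau, mean, sem, icc = (curve.torque_grid[m], curve.mean[m],
                               curve.sem[m], curve.icc[m])
        ax.plot(tau, mean, color="k", lw=1.2, label="mean")
        ax.fill_between(tau, mean - sem, mean + sem, color="k", alpha=0.25,
                        label="± SEM")
        ax.set_xlabel("torque (N·m)")
        ax.set_ylabel(curve.channel)
        ax.set_title(f"{sweep}-directed sweep")
        ax2 = ax.twinx()
        ax2.plot(tau, icc, ls=":", color="tab:blue", label="ICC(2,1)")
        ax2.set_ylim(0, 1)
        ax2.set_ylabel("ICC(2,1)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
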