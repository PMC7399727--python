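"""Load-deformation curve features.

A knee-rotation test produces a torque-rotation curve: axial torque (N·m)
against tibial axial rotation (degrees).  Under the sign convention used
throughout this package, external rotation corresponds to negative torque and
negative rotation, internal rotation to positive torque and rotation, so the
curve is monotone increasing.

The curve is summarised by eight features.  The maximal rotations are read at
the torque limits.  Two *turning points* separate the compliant play region
from the stiff end regions: each half of the curve (split at the zero-torque
rotation) is fitted with a cubic polynomial tau(theta) and the turning point is
the rotation at which the fitted slope d(tau)/d(theta) crosses a threshold
(default 1 N·m per degree).  Derived quantities:

* ``slack``      -- rotation between the two turning points (the play region),
* ``er_laxity``  -- rotation between the external turning point and max ER,
* ``ir_laxity``  -- rotation between the internal turning point and max IR.

By construction ``er_laxity + slack + ir_laxity == max_ir - max_er``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np

from .errors import FitError, TurningPointError

#: Slope threshold (N·m per degree) defining a turning point.  The criterion is
#: "rate of change of torque equals rate of change of rotation", which is
#: unit-dependent; 1.0 corresponds to torque in N·m and rotation in degrees.
DEFAULT_SLOPE_THRESHOLD = 1.0

MIN_FIT_POINTS = 8

#: Canonical order of the derived (calculated) curve features.
CALCULATED_FEATURES = ("er_laxity", "slack", "ir_laxity")


@dataclass(frozen=True)
class CurveFeatures:
    """Features of one load-deformation curve, all in degrees.

    ``max_er`` is the most external (most negative) rotation reached,
    ``max_ir`` the most internal.  ``rot_at_zero`` is the rotation at zero
    torque.  ``tp_er``/``tp_ir`` are the turning points.
    """

    max_er: float
    max_ir: float
    rot_at_zero: float
    tp_er: float
    tp_ir: float
    er_laxity: float
    ir_laxity: float
    slack: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_turning_points(
        cls, max_er: float, max_ir: float, rot_at_zero: float,
        tp_er: float, tp_ir: float,
    ) -> "CurveFeatures":
        """Assemble features from raw anchor points.

        The laxity/slack identities are applied here so every construction
        path satisfies the decomposition identity exactly.
        """
        if not (max_er <= tp_er <= tp_ir <= max_ir):
            raise TurningPointError(
                "turning points out of order: expected "
                f"max_er ({max_er:.3f}) <= tp_er ({tp_er:.3f}) <= "
                f"tp_ir ({tp_ir:.3f}) <= max_ir ({max_ir:.3f})"
            )
        return cls(
            max_er=max_er,
            max_ir=max_ir,
            rot_at_zero=rot_at_zero,
            tp_er=tp_er,
            tp_ir=tp_ir,
            er_laxity=tp_er - max_er,
            ir_laxity=max_ir - tp_ir,
            slack=tp_ir - tp_er,
        )


@dataclass(frozen=True)
class CubicFit:
    """Least-squares cubic tau(theta) over one half of the curve.

    ``coef`` holds (a0, a1, a2, a3) in ascending order, torque in N·m as a
    function of rotation in degrees.  ``side`` is ``"external"`` or
    ``"internal"``.
    """

    coef: tuple[float, float, float, float]
    domain: tuple[float, float]
    residual_rms: float
    side: str

    def slope(self, theta):
        a0, a1, a2, a3 = self.coef
        return a1 + 2.0 * a2 * np.asarray(theta) + 3.0 * a3 * np.asarray(theta) ** 2

    def __call__(self, theta):
        a0, a1, a2, a3 = self.coef
        t = np.asarray(theta)
        return a0 + a1 * t + a2 * t**2 + a3 * t**3


def fit_cubic_half(theta, torque, side: str = "internal") -> CubicFit:
    """Fit a cubic polynomial tau(theta) to one half of the curve.

    Parameters
    ----------
    theta, torque
        Rotation (degrees) and torque (N·m) samples of one half.
    side
        ``"external"`` or ``"internal"``; carried through for root selection.
    """
    theta = np.asarray(theta, dtype=float)
    torque = np.asarray(torque, dtype=float)
    if theta.shape != torque.shape or theta.ndim != 1:
        raise FitError("theta and torque must be 1-D arrays of equal length")
    if theta.size < MIN_FIT_POINTS:
        raise FitError(
            f"insufficient points for cubic fit: {theta.size} < {MIN_FIT_POINTS}"
        )
    if np.ptp(theta) == 0.0:
        raise FitError("rank-deficient design: all rotation values equal")
    design = np.vander(theta, 4, increasing=True)
    coef, res, rank, _ = np.linalg.lstsq(design, torque, rcond=None)
    if rank < 4:
        raise FitError("rank-deficient design: rotation values are degenerate")
    resid = torque - design @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    lo, hi = float(theta.min()), float(theta.max())
    return CubicFit(coef=tuple(float(c) for c in coef), domain=(lo, hi),
                    residual_rms=rms, side=side)


def find_turning_point(
    fit: CubicFit,
    center: float,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
) -> float:
    """Rotation at which the fitted slope crosses the threshold.

    Solves d(tau)/d(theta) = ``slope_threshold`` on the fit's quadratic
    derivative.  Admissible roots lie inside the fit domain and have the slope
    *increasing away from the curve centre* (the slope must exceed the
    threshold on the stiff side of the root and fall below it towards the play
    region).  Among admissible roots the one nearest ``center`` is returned.
    """
    a0, a1, a2, a3 = fit.coef
    # quadratic: 3 a3 x^2 + 2 a2 x + (a1 - threshold) = 0
    poly = np.array([3.0 * a3, 2.0 * a2, a1 - slope_threshold])
    if abs(poly[0]) < 1e-300 and abs(poly[1]) < 1e-300:
        raise TurningPointError(
            f"no turning point on {fit.side} side: fitted slope is constant"
        )
    roots = np.roots(poly)
    lo, hi = fit.domain
    span = hi - lo
    tol = 1e-9 * max(1.0, span)
    outward = -1.0 if fit.side == "external" else 1.0
    candidates = []
    for r in roots:
        if abs(r.imag) > 1e-8:
            continue
        x = float(r.real)
        if not (lo - tol <= x <= hi + tol):
            continue
        # Slope must increase moving outward (towards the stiff extreme).
        eps = 1e-6 * max(1.0, span)
        if fit.slope(x + outward * eps) <= fit.slope(x - outward * eps):
            continue
        candidates.append(x)
    if not candidates:
        raise TurningPointError(
            f"no turning point on {fit.side} side: fitted slope never crosses "
            f"{slope_threshold} N·m/deg inside [{lo:.3f}, {hi:.3f}]"
        )
    dists = [abs(x - center) for x in candidates]
    order = np.argsort(dists)
    if len(candidates) > 1 and abs(dists[order[0]] - dists[order[1]]) < tol:
        raise TurningPointError(
            f"ambiguous turning point on {fit.side} side: two admissible roots "
            "equidistant from the curve centre"
        )
    return candidates[int(order[0])]


def _zero_crossing(theta: np.ndarray, torque: np.ndarray) -> float:
    """Rotation at zero torque by linear interpolation along the sweep."""
    order = np.argsort(torque, kind="stable")
    return float(np.interp(0.0, torque[order], theta[order]))


def compute_features(
    cycle,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
    channel: str = "rot_z_deg",
):
    """Extract :class:`CurveFeatures` from one analysis cycle.

    ``cycle`` is a :class:`rkt.io.TrialRecord` holding exactly one ER-directed
    and one IR-directed sweep (use :func:`rkt.io.extract_third_cycle` first),
    or a :class:`rkt.io.SampledCurve`.

    The zero-torque rotation is the mean of the two sweeps' zero crossings.
    The curve is split there; the external half (from the ER-directed sweep)
    and internal half (IR-directed sweep) each get a cubic fit, so each
    turning point is estimated from the branch loading towards its own
    extreme.  Max rotations are read at the torque extremes of the
    corresponding loading sweep.
    """
    from .io import SampledCurve, TrialRecord  # local import to avoid a cycle

    if isinstance(cycle, TrialRecord):
        df = cycle.samples
        sweeps = set(df["sweep"])
        if sweeps != {"ER", "IR"}:
            raise ValueError(
                f"cycle must contain exactly one ER and one IR sweep, got {sorted(sweeps)}"
            )
        if df.groupby("sweep").ngroups != 2 or set(df["cycle"]) - {df["cycle"].iloc[0]}:
            if len(set(df["cycle"])) > 1:
                raise ValueError(
                    "multiple cycles present; extract the analysis cycle first"
                )
        er = df[df["sweep"] == "ER"]
        ir = df[df["sweep"] == "IR"]
        theta_er = er[channel].to_numpy(float)
        tau_er = er["torque_nm"].to_numpy(float)
        theta_ir = ir[channel].to_numpy(float)
        tau_ir = ir["torque_nm"].to_numpy(float)
        context = f"subject={cycle.subject_id} knee={cycle.knee} day={cycle.day}"
    elif isinstance(cycle, SampledCurve):
        tau_er = tau_ir = cycle.torque_grid
        theta_er = cycle.values[("ER", channel)]
        theta_ir = cycle.values[("IR", channel)]
        keep_er = ~np.isnan(theta_er)
        keep_ir = ~np.isnan(theta_ir)
        theta_er, tau_er = theta_er[keep_er], tau_er[keep_er]
        theta_ir, tau_ir = theta_ir[keep_ir], tau_ir[keep_ir]
        context = str(cycle.meta)
    else:
        raise TypeError(f"unsupported input type {type(cycle).__name__}")

    try:
        z_er = _zero_crossing(theta_er, tau_er)
        z_ir = _zero_crossing(theta_ir, tau_ir)
        rot_at_zero = 0.5 * (z_er + z_ir)

        max_er = float(theta_er[np.argmin(tau_er)])
        max_ir = float(theta_ir[np.argmax(tau_ir)])

        ext_mask = theta_er <= rot_at_zero
        int_mask = theta_ir >= rot_at_zero
        fit_ext = fit_cubic_half(theta_er[ext_mask], tau_er[ext_mask], side="external")
        fit_int = fit_cubic_half(theta_ir[int_mask], tau_ir[int_mask], side="internal")
        tp_er = find_turning_point(fit_ext, rot_at_zero, slope_threshold)
        tp_ir = find_turning_point(fit_int, rot_at_zero, slope_threshold)
        return CurveFeatures.from_turning_points(
            max_er=max_er, max_ir=max_ir, rot_at_zero=rot_at_zero,
            tp_er=tp_er, tp_ir=tp_ir,
        )
    except (FitError, TurningPointError) as exc:
        raise type(exc)(f"{exc} [{context}]") from exc


def extract_cohort_features(
    trials,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
    on_error: str = "raise",
):
    """Extract features for every trial in a cohort.

    Returns a DataFrame in the feature-table schema (see :mod:`rkt.io`).
    ``on_error="skip"`` drops trials whose extraction fails, with a warning.
    """
    import pandas as pd

    from .io import extract_third_cycle

    rows = []
    for trial in trials:
        try:
            feats = compute_features(extract_third_cycle(trial), slope_threshold)
        except (FitError, TurningPointError, ValueError):
            if on_error == "skip":
                warnings.warn(
                    f"feature extraction failed for subject={trial.subject_id} "
                    f"knee={trial.knee} day={trial.day}; trial skipped",
                    stacklevel=2,
                )
                continue
            raise
        rows.append({
            "subject_id": trial.subject_id,
            "group": trial.group,
            "knee": trial.knee,
            "day": trial.day,
            "max_er_deg": feats.max_er,
            "max_ir_deg": feats.max_ir,
            "rot_at_zero_deg": feats.rot_at_zero,
            "tp_er_deg": feats.tp_er,
            "tp_ir_deg": feats.tp_ir,
            "er_laxity_deg": feats.er_laxity,
            "ir_laxity_deg": feats.ir_laxity,
            "slack_deg": feats.slack,
        })
    return pd.DataFrame(rows)
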