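"""Analytic torque-rotation curve family and its exact feature oracle.

The generator models the passive torque response of the knee to axial
rotation as a piecewise-smooth, strictly monotone curve with three regions:
a compliant *play* region of low constant slope around the curve centre and
two exponentially stiffening end regions.  With ``u = theta - c`` (degrees
from the curve centre) and torque in N·m:

    tau(u) = k_p * u
             + A_ir * (exp(beta * max(0, u - h)) - 1)
             - A_er * (exp(beta * max(0, -u - h)) - 1)

* ``k_p``   -- play-region slope (N·m/deg), well below the turning-point
  slope threshold;
* ``h``     -- half-width of the play region (deg);
* ``A_er``, ``A_ir`` -- stiffening amplitudes (N·m) of the external and
  internal side;
* ``beta``  -- stiffening rate (1/deg).

The *exact* features of such a curve (turning points where d(tau)/d(theta)
crosses the threshold, max rotations at the torque limits) are computed here
by root finding on the analytic curve and its derivative.  This is the
independent oracle against which the cubic-fit estimator in
:mod:`rkt.features` is validated; the two never share code.

Calibration inverts the family: given target slack and laxities it solves for
``h`` and the side amplitudes so that the exact features reproduce the
targets.  Not every feature combination is expressible: beyond a turning
point the slope exceeds the threshold, so the torque rise from turning point
to maximal rotation exceeds ``laxity * threshold``; with a ±6 N·m sweep this
caps the laxity each side can reach.  Infeasible targets raise
:class:`~rkt.errors.CalibrationError`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import lambertw

from .errors import CalibrationError, TurningPointError
from .features import DEFAULT_SLOPE_THRESHOLD, CurveFeatures

__all__ = [
    "CurveParams",
    "torque",
    "slope",
    "rotation_at_torque",
    "true_features",
    "features_from_torque",
    "calibrate_curve_params",
    "max_feasible_laxity",
]


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one torque-rotation curve."""

    center: float        # c: rotation at zero torque, deg
    half_play: float     # h: half-width of the play region, deg
    play_slope: float    # k_p: N·m/deg
    amp_er: float        # A_er: stiffening amplitude, external side, N·m
    amp_ir: float        # A_ir: internal side, N·m
    rate: float          # beta: 1/deg
    torque_limit: float = 6.0

    def __post_init__(self):
        if self.half_play <= 0 or self.rate <= 0 or self.torque_limit <= 0:
            raise ValueError("half_play, rate and torque_limit must be positive")
        if not 0.0 < self.play_slope:
            raise ValueError("play_slope must be positive")
        if self.amp_er <= 0 or self.amp_ir <= 0:
            raise ValueError("stiffening amplitudes must be positive")

    def shifted(self, delta: float) -> "CurveParams":
        """Same curve translated by ``delta`` degrees of rotation."""
        return replace(self, center=self.center + delta)


def torque(params: CurveParams, theta):
    """Torque (N·m) at rotation ``theta`` (deg); vectorised."""
    u = np.asarray(theta, dtype=float) - params.center
    p = params
    out = p.play_slope * u
    out = out + p.amp_ir * np.expm1(p.rate * np.maximum(0.0, u - p.half_play))
    out = out - p.amp_er * np.expm1(p.rate * np.maximum(0.0, -u - p.half_play))
    return out


def slope(params: CurveParams, theta):
    """d(tau)/d(theta) (N·m/deg) at rotation ``theta``; vectorised."""
    u = np.asarray(theta, dtype=float) - params.center
    p = params
    out = np.full_like(u, p.play_slope, dtype=float)
    ir = u > p.half_play
    er = u < -p.half_play
    out = out + np.where(ir, p.amp_ir * p.rate * np.exp(p.rate * (u - p.half_play)), 0.0)
    out = out + np.where(er, p.amp_er * p.rate * np.exp(p.rate * (-u - p.half_play)), 0.0)
    return out


def _stiff_rotation(amp: float, kp: float, beta: float, h: float, tau: float) -> float:
    """Solve ``kp*u + amp*(exp(beta*(u-h)) - 1) = tau`` for ``u >= h``.

    Uses the Lambert W closed form when it is numerically safe, otherwise
    bisection.  ``tau`` must be >= kp*h (the torque at the play edge).
    """
    # a*exp(w) + b*w = c  with  w = beta*(u - h)
    a = amp
    b = kp / beta
    c = tau + amp - kp * h
    z = c / b
    if z < 650.0:  # exp(z) stays finite in double precision
        arg = (a / b) * np.exp(z)
        w = z - float(lambertw(arg).real)
        return h + w / beta
    f = lambda u: kp * u + amp * np.expm1(beta * (u - h)) - tau
    hi = h + 1.0
    while f(hi) < 0.0:
        hi = h + 2.0 * (hi - h)
    return brentq(f, h, hi, xtol=1e-12)


def rotation_at_torque(params: CurveParams, tau):
    """Invert the monotone curve: rotation (deg) at torque ``tau``; vectorised."""
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    p = params
    edge = p.play_slope * p.half_play
    out = np.empty_like(tau_arr)
    for i, t in enumerate(tau_arr):
        if t > edge:
            u = _stiff_rotation(p.amp_ir, p.play_slope, p.rate, p.half_play, t)
        elif t < -edge:
            u = -_stiff_rotation(p.amp_er, p.play_slope, p.rate, p.half_play, -t)
        else:
            u = t / p.play_slope
        out[i] = u
    out = out + p.center
    return out if np.ndim(tau) else float(out[0])


def features_from_torque(
    torque_fn,
    dtorque_fn,
    torque_limit: float,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
    search_halfwidth: float = 200.0,
    center_hint: float = 0.0,
    n_grid: int = 20001,
) -> CurveFeatures:
    """Dense-numeric feature oracle for an arbitrary monotone torque curve.

    Works directly on callables ``torque_fn(theta)`` and ``dtorque_fn(theta)``
    so it is independent of both the generator parameterisation and the
    cubic-fit estimator.  Max rotations solve ``tau = ±torque_limit``; the
    zero-torque rotation solves ``tau = 0``; turning points are located by a
    dense scan (``n_grid`` points per side) for a sign change of
    ``dtorque_fn - slope_threshold`` moving outward from the centre, refined
    with Brent's method.
    """
    lo, hi = center_hint - search_halfwidth, center_hint + search_halfwidth
    if torque_fn(hi) < torque_limit or torque_fn(lo) > -torque_limit:
        raise ValueError("torque limits not reached inside the search window")
    max_ir = brentq(lambda t: torque_fn(t) - torque_limit, center_hint, hi, xtol=1e-12)
    max_er = brentq(lambda t: torque_fn(t) + torque_limit, lo, center_hint, xtol=1e-12)
    rot_at_zero = brentq(torque_fn, max_er, max_ir, xtol=1e-12)

    def _scan(side: str) -> float:
        end = max_ir if side == "internal" else max_er
        grid = np.linspace(rot_at_zero, end, n_grid)
        g = np.asarray(dtorque_fn(grid), dtype=float) - slope_threshold
        sign_change = np.nonzero((g[:-1] < 0.0) & (g[1:] >= 0.0))[0]
        if sign_change.size == 0:
            raise TurningPointError(f"no turning point on {side} side")
        i = int(sign_change[0])  # nearest the play region
        a, b = grid[i], grid[i + 1]
        if g[i + 1] == 0.0:
            return float(b)
        return brentq(lambda t: dtorque_fn(t) - slope_threshold, a, b, xtol=1e-12)

    tp_ir = _scan("internal")
    tp_er = _scan("external")
    return CurveFeatures.from_turning_points(
        max_er=max_er, max_ir=max_ir, rot_at_zero=rot_at_zero,
        tp_er=tp_er, tp_ir=tp_ir,
    )


def true_features(
    params: CurveParams,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
) -> CurveFeatures:
    """Exact features of a generator curve (dense-numeric oracle)."""
    if params.play_slope >= slope_threshold:
        raise TurningPointError(
            f"play slope {params.play_slope} is not below the slope threshold "
            f"{slope_threshold}; no turning point exists"
        )
    return features_from_torque(
        lambda t: torque(params, t),
        lambda t: slope(params, t),
        params.torque_limit,
        slope_threshold=slope_threshold,
        center_hint=params.center,
    )


def _side_geometry(vstar: float, h: float, kp: float, beta: float,
                   threshold: float, torque_limit: float):
    """Amplitude, turning point and laxity for one side given the distance
    ``vstar`` between play edge and turning point."""
    amp = (threshold - kp) * np.exp(-beta * vstar) / beta
    u_max = _stiff_rotation(amp, kp, beta, h, torque_limit)
    return amp, h + vstar, u_max - (h + vstar)


def max_feasible_laxity(
    slack: float, play_slope: float, stiffening_rate: float,
    torque_limit: float = 6.0,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
) -> float:
    """Largest laxity one side can express at the given slack.

    Evaluated at the limit where the turning point sits at the play edge
    (``vstar -> 0``) with ``h = slack/2``; slightly conservative because any
    sub-threshold approach region shrinks ``h``.
    """
    _, _, lax = _side_geometry(
        1e-9, slack / 2.0, play_slope, stiffening_rate, slope_threshold, torque_limit
    )
    return lax


def min_feasible_slack(
    er_laxity: float, ir_laxity: float,
    play_slope: float, stiffening_rate: float,
    torque_limit: float = 6.0,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
) -> float:
    """Smallest slack expressible at the given laxities.

    The slack spans the play region plus the sub-threshold approach region of
    each side; the latter widens as the target laxity shrinks, so small
    laxities impose a floor on slack.  Evaluated in the ``h -> 0`` limit.
    """
    kp, beta, th = play_slope, stiffening_rate, slope_threshold
    h = 1e-6
    total = 2.0 * h
    for lax in (er_laxity, ir_laxity):
        def excess(vstar: float) -> float:
            return _side_geometry(vstar, h, kp, beta, th, torque_limit)[2] - lax

        lo = 1e-9
        if excess(lo) < 0.0:
            return np.inf  # laxity itself infeasible
        hi = 1.0
        while excess(hi) > 0.0 and hi < 1e4:
            hi *= 2.0
        total += brentq(excess, lo, hi, xtol=1e-6)
    return total


def calibrate_curve_params(
    target,
    play_slope: float,
    stiffening_rate: float,
    torque_limit: float = 6.0,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
    tol: float = 1e-6,
) -> CurveParams:
    """Solve for the curve whose exact features match ``target``.

    ``target`` needs attributes ``slack``, ``er_laxity``, ``ir_laxity`` and
    ``rot_at_zero`` (a :class:`~rkt.features.CurveFeatures` works, as does any
    namespace).  ``play_slope`` and ``stiffening_rate`` are fixed family
    constants; the half-play width and the two side amplitudes are solved
    numerically (nested Brent iterations) so that the oracle turning points
    reproduce the target slack and laxities to well within 0.01 degrees.
    """
    kp, beta, th = play_slope, stiffening_rate, slope_threshold
    if not 0.0 < kp < th:
        raise CalibrationError(
            f"play_slope must lie in (0, {th}) (below the turning-point slope "
            f"threshold); got {kp}"
        )
    if beta <= 0.0:
        raise CalibrationError(f"stiffening_rate must be positive; got {beta}")
    slack = float(target.slack)
    laxities = {"er": float(target.er_laxity), "ir": float(target.ir_laxity)}
    if slack <= 0.0 or min(laxities.values()) <= 0.0:
        raise CalibrationError(
            f"target slack and laxities must be positive; got slack={slack}, "
            f"laxities={laxities}"
        )

    def _solve_side(h: float, lax: float) -> tuple[float, float]:
        """vstar and amplitude reproducing ``lax`` at half-play ``h``."""
        def excess(vstar: float) -> float:
            return _side_geometry(vstar, h, kp, beta, th, torque_limit)[2] - lax

        lo = 1e-9
        if excess(lo) < 0.0:
            cap = _side_geometry(lo, h, kp, beta, th, torque_limit)[2]
            raise CalibrationError(
                f"target laxity {lax:.3f} deg exceeds the {cap:.3f} deg cap of the "
                f"curve family at play_slope={kp}, stiffening_rate={beta}, "
                f"torque_limit={torque_limit}, slope_threshold={th}"
            )
        hi = 1.0
        while excess(hi) > 0.0:
            hi *= 2.0
            if hi > 1e4:
                raise CalibrationError(
                    f"laxity solve failed to bracket for target {lax:.3f} deg"
                )
        vstar = brentq(excess, lo, hi, xtol=tol)
        amp = (th - kp) * np.exp(-beta * vstar) / beta
        return vstar, amp

    def slack_excess(h: float) -> float:
        v_er, _ = _solve_side(h, laxities["er"])
        v_ir, _ = _solve_side(h, laxities["ir"])
        return 2.0 * h + v_er + v_ir - slack

    h_hi = slack / 2.0
    # Back off from h = slack/2 if the torque budget there cannot host the
    # laxities (kp*h eats into the stiff-region budget).
    for _ in range(60):
        try:
            ex_hi = slack_excess(h_hi)
            break
        except CalibrationError:
            h_hi *= 0.95
    else:
        raise CalibrationError(
            f"no curve in the family reproduces slack={slack:.3f} with laxities "
            f"{laxities} at play_slope={kp}, stiffening_rate={beta}"
        )
    if ex_hi < 0.0:
        raise CalibrationError(
            f"slack target {slack:.3f} deg unreachable: sub-threshold approach "
            f"regions alone exceed it at play_slope={kp}, stiffening_rate={beta}"
        )
    h_lo = 1e-6
    ex_lo = slack_excess(h_lo)
    if ex_lo > 0.0:
        raise CalibrationError(
            f"slack target {slack:.3f} deg smaller than the minimal slack "
            f"{slack + ex_lo:.3f} deg of the family at play_slope={kp}, "
            f"stiffening_rate={beta} (turning-point approach regions too wide)"
        )
    h = brentq(slack_excess, h_lo, h_hi, xtol=tol)
    _, amp_er = _solve_side(h, laxities["er"])
    _, amp_ir = _solve_side(h, laxities["ir"])
    return CurveParams(
        center=float(target.rot_at_zero),
        half_play=h,
        play_slope=kp,
        amp_er=amp_er,
        amp_ir=amp_ir,
        rate=beta,
        torque_limit=torque_limit,
    )
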