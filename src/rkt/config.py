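"""Generator and pipeline configuration.

:class:`GeneratorConfig` holds everything needed to simulate a cohort of
knee-rotation trials: the device protocol constants (±6 N·m torque-limited
sweeps, 3 cycles with 4 external and 3 internal sweeps), the population
feature means, the nested variance structure (subject, knee-within-subject,
day-within-subject, residual) per feature, the curve-family shape constants,
sensor noise, and group mean offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import yaml

FEATURES = ("slack", "er_laxity", "ir_laxity", "rot_at_zero")
VC_NAMES = ("subject", "knee", "day", "residual")


def _default_mu() -> dict[str, float]:
    # Population means (degrees).  Slack matches healthy adult cohorts;
    # laxity means sit inside the curve family's expressible envelope (the
    # unity-slope turning-point criterion caps laxity at ~4.3 deg per side at
    # a 6 N·m sweep limit; see docs/methods.md).
    return {"slack": 16.6, "er_laxity": 2.6, "ir_laxity": 2.8, "rot_at_zero": 0.0}


def _default_variance_components() -> dict[str, dict[str, float]]:
    # degrees^2, per feature: subject / knee-within-subject / day / residual.
    return {
        "slack":       {"subject": 9.0, "knee": 1.0, "day": 1.9, "residual": 0.3},
        "er_laxity":   {"subject": 1.1, "knee": 0.1, "day": 0.3, "residual": 0.1},
        "ir_laxity":   {"subject": 0.6, "knee": 0.2, "day": 0.3, "residual": 0.04},
        "rot_at_zero": {"subject": 4.0, "knee": 1.0, "day": 1.0, "residual": 0.25},
    }


def _default_group_offsets() -> dict[str, dict[str, float]]:
    # Additive mean shifts per group label (degrees); "F" carries the
    # female-minus-male differences observed in healthy cohorts.
    return {
        "M": {},
        "F": {"slack": 2.6, "er_laxity": 1.0, "ir_laxity": 0.5},
    }


def _default_coupling() -> dict[str, float]:
    # Linear gains mapping axial rotation (deg) to secondary channels
    # (deg/deg for rotations, mm/deg for translations).
    return {"rot_y_deg": 0.10, "rot_x_deg": 0.15,
            "trans_z_mm": 0.03, "trans_y_mm": 0.08, "trans_x_mm": 0.05}


def pointwise_regime_variances() -> dict[str, dict[str, float]]:
    """Variance scales for emulating pointwise curve reliability.

    The default (feature-regime) residuals express day-to-day feature
    scatter as genuine curve shifts, which dominates the pointwise residual.
    When the quantity of interest is the pointwise reliability of the
    *rotation signal* itself, most short-term scatter is sensor noise, so
    curve-level residuals are kept near zero and the subject/day structure
    carries the variance.  With these scales the pointwise axial-rotation
    SEM is sensor-noise dominated (< 0.3 deg) and the pointwise ICC lands in
    the good-reliability band.
    """
    return {
        "slack":       {"subject": 9.0, "knee": 1.0, "day": 0.8, "residual": 0.02},
        "er_laxity":   {"subject": 1.1, "knee": 0.1, "day": 0.05, "residual": 0.01},
        "ir_laxity":   {"subject": 0.6, "knee": 0.2, "day": 0.05, "residual": 0.01},
        "rot_at_zero": {"subject": 4.0, "knee": 1.0, "day": 0.5, "residual": 0.02},
    }


@dataclass
class GeneratorConfig:
    """Study-design and curve-shape parameters of the synthetic cohort."""

    n_subjects: int = 25
    n_days: int = 5
    knees: tuple[str, ...] = ("L", "R")
    mu_features: dict[str, float] = field(default_factory=_default_mu)
    variance_components: dict[str, dict[str, float]] = field(
        default_factory=_default_variance_components)
    play_slope: float = 0.08          # N·m/deg, inside the play region
    stiffening_rate: float = 0.10     # 1/deg
    torque_limit: float = 6.0         # N·m, sweep reversal torque
    samples_per_sweep: int = 100
    noise_rotation_sd: float = 0.25   # deg; half the tracker's 0.5 deg static
    noise_translation_sd: float = 0.75  # mm; half the tracker's 1.5 mm
    coupling_coeffs: dict[str, float] = field(default_factory=_default_coupling)
    hysteresis_width: float = 0.0     # N·m between sweep directions
    right_knee_offset: float = 3.5    # deg added to rot_at_zero of the right knee
    group_offsets: dict[str, dict[str, float]] = field(
        default_factory=_default_group_offsets)
    group_counts: dict[str, int] | None = None  # subjects per group; None = single group
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if self.samples_per_sweep < 16:
            raise ValueError("samples_per_sweep must be >= 16")
        if not 0.0 < self.play_slope < 1.0:
            raise ValueError("play_slope must lie in (0, 1)")
        if self.stiffening_rate <= 0.0:
            raise ValueError("stiffening_rate must be positive")
        if self.torque_limit <= 0.0:
            raise ValueError("torque_limit must be positive")
        if self.noise_rotation_sd < 0 or self.noise_translation_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        self.knees = tuple(self.knees)
        if len(set(self.knees)) != len(self.knees) or not self.knees:
            raise ValueError("knees must be distinct, non-empty side labels")
        for feat in FEATURES:
            if feat not in self.mu_features:
                raise ValueError(f"mu_features missing entry for {feat!r}")
            vcs = self.variance_components.get(feat)
            if vcs is None:
                raise ValueError(f"variance_components missing entry for {feat!r}")
            for name in VC_NAMES:
                if vcs.get(name, 0.0) < 0.0:
                    raise ValueError(
                        f"variance component {name!r} of {feat!r} is negative")
        if self.group_counts is not None:
            if sum(self.group_counts.values()) != self.n_subjects:
                raise ValueError("group_counts must sum to n_subjects")
            for label in self.group_counts:
                if label not in self.group_offsets:
                    raise ValueError(f"no group_offsets entry for group {label!r}")

    def with_updates(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["knees"] = list(self.knees)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "knees" in d:
            d["knees"] = tuple(d["knees"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
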