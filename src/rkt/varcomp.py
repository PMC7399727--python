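"""Variance decomposition of curve features (the reliability summary table).

For each calculated feature (ER laxity, slack, IR laxity) the observed
variance across a subject × knee × day cohort is partitioned into subject,
knee-within-subject, day-within-subject and residual components with the
nested mixed model of :mod:`rkt.nested_anova` (knee also enters as a fixed
effect).  From the components follow the percentage shares, the SEM
(√residual variance), MDC90, and the ICC(2,1) of the subject-knee × day
feature matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError
from .nested_anova import nested_variance_components
from .reliability import icc_2_1, mdc90, sem_absolute

FEATURE_TABLE_MAP = {
    "er_laxity": "er_laxity_deg",
    "slack": "slack_deg",
    "ir_laxity": "ir_laxity_deg",
}

SUMMARY_COLUMNS = [
    "feature", "var_subject", "pct_subject", "var_knee", "pct_knee",
    "var_day", "pct_day", "var_residual", "pct_residual",
    "sem_deg", "mdc90_deg", "total_variance", "icc_2_1",
]


@dataclass(frozen=True)
class VarianceDecomposition:
    """One feature's variance partition and derived reliability measures."""

    feature: str
    var_subject: float
    var_knee: float
    var_day: float
    var_residual: float
    total: float
    pct_subject: float
    pct_knee: float
    pct_day: float
    pct_residual: float
    sem: float
    mdc90: float
    icc: float
    knee_fixed_effect: float
    truncated: tuple[str, ...] = ()

    def as_row(self) -> dict:
        return {
            "feature": self.feature,
            "var_subject": self.var_subject, "pct_subject": self.pct_subject,
            "var_knee": self.var_knee, "pct_knee": self.pct_knee,
            "var_day": self.var_day, "pct_day": self.pct_day,
            "var_residual": self.var_residual, "pct_residual": self.pct_residual,
            "sem_deg": self.sem, "mdc90_deg": self.mdc90,
            "total_variance": self.total, "icc_2_1": self.icc,
        }


def variance_percentages(
    components: dict[str, float] | tuple[float, float, float, float],
) -> tuple[float, dict[str, float]]:
    """Total variance and one-decimal percentage share of each component."""
    if not isinstance(components, dict):
        components = dict(zip(("subject", "knee", "day", "residual"), components))
    if any(v < 0 for v in components.values()):
        raise ValueError("variance components must be non-negative")
    total = float(sum(components.values()))
    if total == 0.0:
        raise ValueError("no variance to apportion: all components are zero")
    pct = {k: round(100.0 * v / total, 1) for k, v in components.items()}
    return total, pct


def fit_feature_vc(
    feature_table: pd.DataFrame,
    feature: str,
    value_col: str | None = None,
) -> VarianceDecomposition:
    """Fit the nested variance model to one feature of a cohort table.

    ``feature_table`` needs columns subject_id, knee, day and the feature
    value column (``<feature>_deg`` by default).  Returns the variance
    components (negative estimates truncated at zero and flagged), their
    percentage shares, SEM, MDC90, the ICC(2,1) of the subject-knee × day
    matrix, and the estimated right-minus-left fixed shift.
    """
    col = value_col or FEATURE_TABLE_MAP.get(feature, f"{feature}_deg")
    if col not in feature_table.columns:
        raise DesignError(f"feature column absent: {col}")
    df = feature_table.rename(columns={col: "value"})[
        ["subject_id", "knee", "day", "value"]]
    vc = nested_variance_components(df)
    comps = {"subject": vc.var_subject, "knee": vc.var_knee,
             "day": vc.var_day, "residual": vc.var_residual}
    if sum(comps.values()) == 0.0:
        total, pct = 0.0, {k: 0.0 for k in comps}
    else:
        total, pct = variance_percentages(comps)
    sem = sem_absolute(vc.var_residual)

    # ICC(2,1): units are subject-knee combinations, trials are days.
    piv = df.pivot_table(index=["subject_id", "knee"], columns="day",
                         values="value", aggfunc="mean")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc, _ = icc_2_1(piv.to_numpy(float))

    return VarianceDecomposition(
        feature=feature,
        var_subject=vc.var_subject, var_knee=vc.var_knee,
        var_day=vc.var_day, var_residual=vc.var_residual,
        total=total,
        pct_subject=pct["subject"], pct_knee=pct["knee"],
        pct_day=pct["day"], pct_residual=pct["residual"],
        sem=sem, mdc90=mdc90(sem), icc=icc,
        knee_fixed_effect=vc.knee_fixed_effect,
        truncated=vc.truncated,
    )


def feature_reliability_summary(
    feature_table: pd.DataFrame,
    features: tuple[str, ...] = ("er_laxity", "slack", "ir_laxity"),
) -> pd.DataFrame:
    """Variance decomposition table: one row per calculated curve feature."""
    rows = [fit_feature_vc(feature_table, f).as_row() for f in features]
    return pd.DataFrame(rows)[SUMMARY_COLUMNS]
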