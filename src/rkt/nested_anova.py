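"""Balanced nested ANOVA estimator for the subject/knee/day variance model.

Model for one measured quantity y observed on subject s, knee k (left/right)
and day d:

    y_skd = mu + beta * I(k = R) + a_s + b_sk + c_sd + e_skd

with independent Gaussian random intercepts for subject (a), knee-within-
subject (b) and day-within-subject (c), a fixed side effect beta, and
residual e.  For a balanced layout (every subject measured on both knees on
every day) the variance components have a closed-form method-of-moments
solution from the nested ANOVA mean squares, which is unbiased and fast
enough to run at every point of a torque grid.

Expected mean squares (S subjects, K knees, D days), after removing the
fixed side effect:

    MS_subject  = K*D*var_a + D*var_b + K*var_c + var_e    df = S-1
    MS_knee(s)  =             D*var_b           + var_e    df = (S-1)(K-1)
    MS_day(s)   =                       K*var_c + var_e    df = S(D-1)
    MS_resid    =                                 var_e    df = S(K-1)(D-1)

Negative solutions are truncated at zero (the usual boundary behaviour) and
flagged.  One degree of freedom is absorbed from the knee stratum by the
fixed side effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError


@dataclass(frozen=True)
class NestedComponents:
    """Variance components (units of y squared) and the fixed side effect."""

    var_subject: float
    var_knee: float
    var_day: float
    var_residual: float
    knee_fixed_effect: float  # mean(R) - mean(L), units of y
    truncated: tuple[str, ...]  # components clipped at the zero boundary
    n_subjects: int
    n_knees: int
    n_days: int

    @property
    def total(self) -> float:
        return (self.var_subject + self.var_knee + self.var_day
                + self.var_residual)


def _to_cube(df: pd.DataFrame, value_col: str):
    """Pivot (subject, knee, day, value) rows to a complete S×K×D array."""
    subjects = sorted(df["subject_id"].unique())
    knees = sorted(df["knee"].unique())
    days = sorted(df["day"].unique())
    piv = df.pivot_table(index="subject_id", columns=["knee", "day"],
                         values=value_col, aggfunc="mean")
    full_cols = pd.MultiIndex.from_product([knees, days])
    piv = piv.reindex(index=subjects, columns=full_cols)
    cube = piv.to_numpy(float).reshape(len(subjects), len(knees), len(days))
    incomplete = np.isnan(cube).any(axis=(1, 2))
    if incomplete.any():
        dropped = [s for s, bad in zip(subjects, incomplete) if bad]
        warnings.warn(
            f"unbalanced design: dropping {len(dropped)} incomplete subjects "
            f"({', '.join(map(str, dropped[:5]))}{'...' if len(dropped) > 5 else ''})",
            stacklevel=3,
        )
        cube = cube[~incomplete]
        subjects = [s for s, bad in zip(subjects, incomplete) if not bad]
    return cube, subjects, knees, days


def nested_variance_components(
    df: pd.DataFrame, value_col: str = "value"
) -> NestedComponents:
    """Fit the nested model to a long-format (subject, knee, day, value) table."""
    required = {"subject_id", "knee", "day", value_col}
    missing = required - set(df.columns)
    if missing:
        raise DesignError("missing columns: " + ", ".join(sorted(missing)))
    cube, subjects, knees, days = _to_cube(df, value_col)
    S, K, D = cube.shape
    if S < 2:
        raise DesignError(f"need >= 2 complete subjects, have {S}")
    if D < 2:
        raise DesignError(f"need >= 2 days, have {D}")

    # Fixed side effect: right-minus-left contrast of knee means; remove the
    # per-knee global means so it cannot leak into the variance strata.
    knee_means = cube.mean(axis=(0, 2))
    if K == 2 and set(knees) == {"L", "R"}:
        beta = float(knee_means[knees.index("R")] - knee_means[knees.index("L")])
    elif K >= 2:
        beta = float(knee_means.max() - knee_means.min())
    else:
        beta = 0.0
    y = cube - knee_means[None, :, None]

    grand = y.mean()
    sub_m = y.mean(axis=(1, 2))          # per subject
    sk_m = y.mean(axis=2)                # subject × knee
    sd_m = y.mean(axis=1)                # subject × day

    ms_sub = K * D * np.sum((sub_m - grand) ** 2) / (S - 1)
    df_knee = (S - 1) * (K - 1) if K > 1 else 0
    if K > 1:
        ss_knee = D * np.sum((sk_m - sub_m[:, None]) ** 2)
        ms_knee = ss_knee / df_knee
    else:
        ms_knee = 0.0
    ms_day = K * np.sum((sd_m - sub_m[:, None]) ** 2) / (S * (D - 1))
    resid = (y - sk_m[:, :, None] - sd_m[:, None, :] + sub_m[:, None, None])
    df_res = S * (K - 1) * (D - 1) if K > 1 else S * (D - 1) - (D - 1)
    if K > 1:
        ms_res = np.sum(resid ** 2) / df_res
    else:
        # single knee: day interaction is the finest stratum
        ms_res = ms_day
    var_e = ms_res
    var_c = (ms_day - ms_res) / K
    var_b = (ms_knee - ms_res) / D if K > 1 else 0.0
    var_a = (ms_sub - ms_knee - ms_day + ms_res) / (K * D) if K > 1 \
        else (ms_sub - ms_day) / (K * D)

    truncated = []
    out = {}
    for name, v in (("subject", var_a), ("knee", var_b),
                    ("day", var_c), ("residual", var_e)):
        if v < 0.0:
            truncated.append(name)
            v = 0.0
        out[name] = float(v)
    if K == 1:
        warnings.warn("single knee per subject: var_knee fixed at 0",
                      stacklevel=2)
    return NestedComponents(
        var_subject=out["subject"], var_knee=out["knee"], var_day=out["day"],
        var_residual=out["residual"], knee_fixed_effect=beta,
        truncated=tuple(truncated), n_subjects=S, n_knees=K, n_days=D,
    )
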