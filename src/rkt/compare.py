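"""Normality-gated comparisons of curve features between knees and groups.

Paired left/right comparisons use a two-tailed paired t test when the paired
differences pass a Shapiro-Wilk normality gate (alpha 0.05), otherwise the
Wilcoxon signed-rank test.  Between-group (e.g. sex) comparisons analyse
each leg separately on first-day data and use a pooled-variance independent
t test when both groups pass the gate, otherwise Mann-Whitney U.  Post-hoc
power is computed from the noncentral t distribution at the observed
standardized effect size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .varcomp import FEATURE_TABLE_MAP

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    normal: bool


@dataclass(frozen=True)
class GroupComparisonResult:
    feature: str
    grouping: str               # "side" or the group column name
    groups: tuple[GroupSummary, ...]
    test_used: str
    statistic: float
    p_value: float
    power: float | None = None


def normality_gate(values, alpha: float = ALPHA) -> tuple[bool, float]:
    """Shapiro-Wilk normality gate: normal when p > alpha.

    A zero-variance sample cannot be tested; it is reported non-normal with a
    warning (p = NaN).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DesignError(f"normality test needs n >= 3, got {x.size}")
    if np.ptp(x) == 0.0:
        warnings.warn("zero-variance sample; treating as non-normal",
                      stacklevel=2)
        return False, float("nan")
    stat, p = stats.shapiro(x)
    return bool(p > alpha), float(p)


def _summary(label: str, x: np.ndarray, normal: bool) -> GroupSummary:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return GroupSummary(label=label, n=int(x.size), mean=float(x.mean()),
                        sd=float(x.std(ddof=1)), median=float(med),
                        q1=float(q1), q3=float(q3), normal=normal)


def _feature_col(feature: str) -> str:
    return FEATURE_TABLE_MAP.get(feature, feature if feature.endswith("_deg")
                                 else f"{feature}_deg")


def compare_sides(
    features: pd.DataFrame,
    feature: str,
    day: int | None = None,
    alpha: float = ALPHA,
) -> GroupComparisonResult:
    """Paired left-vs-right comparison of one feature.

    Uses one value per subject per knee (``day`` selects a test day; default
    is each subject's first day).  Subjects lacking either side are dropped
    with a warning.
    """
    col = _feature_col(feature)
    if col not in features.columns:
        raise DesignError(f"feature column absent: {col}")
    df = features.copy()
    if day is None:
        day = int(df["day"].min())
    df = df[df["day"] == day]
    piv = df.pivot_table(index="subject_id", columns="knee", values=col,
                         aggfunc="mean")
    for side in ("L", "R"):
        if side not in piv.columns:
            raise DesignError(f"no {side} knee data on day {day}")
    unpaired = piv[["L", "R"]].isna().any(axis=1)
    if unpaired.any():
        warnings.warn(f"dropping {int(unpaired.sum())} unpaired subjects",
                      stacklevel=2)
        piv = piv[~unpaired]
    left = piv["L"].to_numpy(float)
    right = piv["R"].to_numpy(float)
    if left.size < 2:
        raise DesignError(f"need >= 2 paired subjects, have {left.size}")
    diffs = right - left
    if np.ptp(diffs) == 0.0:
        # identical sides: no evidence of a difference
        normal = True
        test_used, statistic, p = "paired t", 0.0, 1.0
    else:
        normal, _ = normality_gate(diffs, alpha)
        if normal:
            res = stats.ttest_rel(right, left)
            test_used, statistic, p = "paired t", res.statistic, res.pvalue
        else:
            res = stats.wilcoxon(right, left)
            test_used, statistic, p = "Wilcoxon signed-rank", res.statistic, res.pvalue
    return GroupComparisonResult(
        feature=feature, grouping="side",
        groups=(_summary("L", left, normal), _summary("R", right, normal)),
        test_used=test_used, statistic=float(statistic), p_value=float(p),
    )


def compare_groups(
    features: pd.DataFrame,
    feature: str,
    knee: str,
    group_col: str = "group",
    alpha: float = ALPHA,
) -> GroupComparisonResult:
    """Independent two-group comparison of one feature on one leg.

    First-day values only; pooled-variance t test when both groups pass the
    normality gate, otherwise Mann-Whitney U.  Post-hoc power of the
    two-sided t at the observed effect size is attached.
    """
    col = _feature_col(feature)
    if col not in features.columns:
        raise DesignError(f"feature column absent: {col}")
    df = features[(features["knee"] == knee)]
    if df.empty:
        raise DesignError(f"no data for knee {knee!r}")
    first_day = int(df["day"].min())
    df = df[df["day"] == first_day]
    labels = sorted(df[group_col].unique())
    if len(labels) != 2:
        raise DesignError(
            f"expected exactly 2 group labels, found {labels}")
    xs = [df[df[group_col] == g][col].to_numpy(float) for g in labels]
    for g, x in zip(labels, xs):
        if x.size < 2:
            raise DesignError(f"group {g!r} has n={x.size} < 2")
    gates = [normality_gate(x, alpha)[0] if x.size >= 3 else False for x in xs]
    if all(gates):
        res = stats.ttest_ind(xs[0], xs[1], equal_var=True)
        test_used, statistic, p = "independent t", res.statistic, res.pvalue
    else:
        res = stats.mannwhitneyu(xs[0], xs[1], alternative="two-sided")
        test_used, statistic, p = "Mann-Whitney U", res.statistic, res.pvalue
    pw = posthoc_power(xs[0].mean(), xs[0].std(ddof=1), xs[0].size,
                       xs[1].mean(), xs[1].std(ddof=1), xs[1].size,
                       alpha=alpha)
    return GroupComparisonResult(
        feature=feature, grouping=group_col,
        groups=tuple(_summary(g, x, gate)
                     for g, x, gate in zip(labels, xs, gates)),
        test_used=test_used, statistic=float(statistic), p_value=float(p),
        power=pw,
    )


def summary_ttest(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics: (t, df, p).

    ``variant="pooled"`` assumes equal variances (Student); ``"welch"`` uses
    the Welch-Satterthwaite correction.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    equal_var = {"pooled": True, "welch": False}[variant]
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=equal_var)
    if equal_var:
        dof = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        dof = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(dof), float(res.pvalue)


def posthoc_power(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    alpha: float = ALPHA,
) -> float:
    """Power of a two-sided pooled t test at the observed effect size.

    Computed from the noncentral t distribution with noncentrality
    |mean1 - mean2| / (s_pooled · √(1/n1 + 1/n2)).  At zero effect this
    equals alpha.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    dof = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / dof)
    ncp = abs(mean1 - mean2) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    power = (1.0 - stats.nct.cdf(tcrit, dof, ncp)
             + stats.nct.cdf(-tcrit, dof, ncp))
    return float(power)


def comparison_table(
    features: pd.DataFrame,
    group_col: str = "group",
    feature_names: tuple[str, ...] = ("er_laxity", "slack", "ir_laxity"),
    knees: tuple[str, ...] = ("L", "R"),
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-leg group comparison of every calculated feature."""
    rows = []
    for knee in knees:
        for feat in feature_names:
            r = compare_groups(features, feat, knee, group_col, alpha)
            g1, g2 = r.groups
            rows.append({
                "leg": knee, "feature": feat,
                "group1": g1.label, "n1": g1.n, "mean1": g1.mean, "sd1": g1.sd,
                "group2": g2.label, "n2": g2.n, "mean2": g2.mean, "sd2": g2.sd,
                "test_used": r.test_used, "statistic": r.statistic,
                "p_value": r.p_value, "power": r.power,
            })
    return pd.DataFrame(rows)


def side_comparison_table(
    features: pd.DataFrame,
    feature_names: tuple[str, ...] = ("er_laxity", "slack", "ir_laxity"),
    alpha: float = ALPHA,
) -> pd.DataFrame:
    rows = []
    for feat in feature_names:
        r = compare_sides(features, feat, alpha=alpha)
        left, right = r.groups
        rows.append({
            "feature": feat, "n_pairs": left.n,
            "mean_L": left.mean, "sd_L": left.sd,
            "mean_R": right.mean, "sd_R": right.sd,
            "test_used": r.test_used, "statistic": r.statistic,
            "p_value": r.p_value,
        })
    return pd.DataFrame(rows)
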