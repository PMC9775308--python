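"""UV radiant-exposure arithmetic and group-comparison statistics.

Radiant exposure (J/cm²) integrates irradiance (mW/cm²) over the daily
exposure window; the weekly total is the daily dose times the number of
exposure days.  Group comparisons follow the study convention: per-sample
metrics are normalized to the mean of the biological-replicate control group,
pairs are compared by a two-tailed unpaired t-test, and three or more groups
by one-way ANOVA with Tukey's HSD post hoc test.  Significance is flagged at
0.05 (*) and 0.01 (**).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

SECONDS_PER_HOUR = 3600.0


@dataclass
class ExposureSchedule:
    """UVA exposure regimen: irradiance, daily window, and duration."""

    irradiance_mw_cm2: float
    hours_per_day: float
    days: int = 1
    irradiance_tolerance_mw_cm2: float = 0.0

    def __post_init__(self) -> None:
        if self.irradiance_mw_cm2 <= 0 or self.days < 1:
            raise ValueError("irradiance must be > 0 and days >= 1")
        if self.hours_per_day < 0:
            raise ValueError("hours per day must be >= 0")


@dataclass
class DoseResult:
    """Radiant exposure per day and in total, in J/cm²."""

    daily_j_cm2: float
    total_j_cm2: float
    daily_interval_j_cm2: tuple[float, float] | None = None


@dataclass
class GroupComparison:
    """Outcome of a control-normalized group comparison."""

    normalized_values: dict
    statistic: float
    p_value: float
    test_name: str
    pairwise_p: dict = field(default_factory=dict)

    @property
    def significance(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def radiant_exposure(schedule: ExposureSchedule) -> DoseResult:
    """Convert an exposure schedule to daily and total radiant exposure.

    daily [J/cm²] = irradiance [mW/cm²] × exposure seconds per day / 1000;
    total = daily × days.  No rounding is applied.

    >>> radiant_exposure(ExposureSchedule(0.45, 2, 7)).daily_j_cm2
    3.24
    """
    daily = schedule.irradiance_mw_cm2 * schedule.hours_per_day * SECONDS_PER_HOUR / 1000.0
    interval = None
    if schedule.irradiance_tolerance_mw_cm2 > 0:
        span = schedule.irradiance_tolerance_mw_cm2 * schedule.hours_per_day * SECONDS_PER_HOUR / 1000.0
        interval = (daily - span, daily + span)
    return DoseResult(daily, daily * schedule.days, interval)


def normalize_to_control(values, control_values) -> np.ndarray:
    """Divide every value by the mean of the control group.

    The control group itself normalizes to mean exactly 1; treatment values
    become fold-changes relative to control.
    """
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size == 0:
        raise ValueError("control set is empty")
    ref = control_values.mean()
    if ref <= 0:
        raise ValueError("control mean must be positive")
    return np.asarray(values, dtype=float) / ref


def compare_groups(*groups, method: str = "auto", equal_var: bool = True) -> GroupComparison:
    """Two-tailed t-test for two groups; ANOVA + Tukey HSD for more.

    ``method`` may be ``"t_test"``, ``"anova_tukey"`` or ``"auto"`` (pick by
    group count).  The t-test pools variances by default (``equal_var=True``);
    set ``equal_var=False`` for Welch's correction.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    if method == "auto":
        method = "t_test" if len(arrays) == 2 else "anova_tukey"
    normalized = {i: a for i, a in enumerate(arrays)}
    if method == "t_test":
        if len(arrays) != 2:
            raise ValueError("t_test requires exactly two groups")
        a, b = arrays
        if a.std() == 0 and b.std() == 0:
            if np.allclose(a.mean(), b.mean()):
                return GroupComparison(normalized, 0.0, 1.0, "t_test")
            raise ValueError("zero variance in both groups with different means")
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        name = "t_test" if equal_var else "welch_t_test"
        return GroupComparison(normalized, float(res.statistic), float(res.pvalue), name)
    if method == "anova_tukey":
        f = stats.f_oneway(*arrays)
        tukey = stats.tukey_hsd(*arrays)
        pairwise = {
            (i, j): float(tukey.pvalue[i, j])
            for i in range(len(arrays))
            for j in range(i + 1, len(arrays))
        }
        return GroupComparison(normalized, float(f.statistic), float(f.pvalue), "anova_tukey", pairwise)
    raise ValueError(f"unknown method {method!r}")
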