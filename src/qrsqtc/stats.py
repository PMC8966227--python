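"""Two-group comparison pipeline for interval variables.

The analysis contrasts patients who developed ventricular tachycardia or
fibrillation (VT/VF) after the admission ECG against those who did not:
per-group mean ± SD, Shapiro-Wilk normality per group, Brown-Forsythe
homogeneity of variance, then a two-tailed Student (pooled-variance)
unpaired t-test at alpha = 0.05.

Descriptive SDs default to the *population* convention (divisor n); this
is the convention that reproduces the source tables' printed SD values.
Sample SD (divisor n - 1) is available via ``sd_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats as sps

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import Cohort

__all__ = [
    "Descriptives",
    "GroupComparison",
    "BoxplotSummary",
    "descriptives",
    "shapiro_wilk",
    "brown_forsythe",
    "pooled_t_test",
    "welch_t_test",
    "compare_groups",
    "boxplot_summary",
    "COMPARISON_VARIABLES",
]

COMPARISON_VARIABLES = ("ratio", "qrs_ms", "qtc_ms", "hr_bpm")


@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sd: float
    sd_mode: str  # "population" (divisor n) or "sample" (divisor n-1)


@dataclass(frozen=True)
class BoxplotSummary:
    """Numeric twin of a box plot: median, quartile box, 5/95 whiskers."""

    median: float
    p25: float
    p75: float
    p5: float
    p95: float


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_yes: Descriptives
    group_no: Descriptives
    shapiro_p_yes: float
    shapiro_p_no: float
    brown_forsythe_p: float
    t_stat: float
    df: int
    p_two_tailed: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < self.alpha


def descriptives(values: Sequence[float], sd_mode: str = "population") -> Descriptives:
    """Mean and SD of a sample; population SD divides by n, sample by n - 1."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("descriptives of an empty list are undefined")
    if sd_mode not in ("population", "sample"):
        raise ValueError(f"sd_mode must be 'population' or 'sample', got {sd_mode!r}")
    ddof = 0 if sd_mode == "population" else 1
    sd = 0.0 if x.size == 1 else float(np.std(x, ddof=ddof))
    return Descriptives(n=int(x.size), mean=float(np.mean(x)), sd=sd, sd_mode=sd_mode)


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got n={x.size}")
    if x.size > 5000:
        raise ValueError(f"Shapiro-Wilk p-value unreliable above n=5000, got n={x.size}")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def brown_forsythe(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Brown-Forsythe equal-variance test (Levene on deviations from medians)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Brown-Forsythe needs n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.0, 1.0  # no within-group spread at all: variances trivially equal
    stat, p = sps.levene(a, b, center="median")
    return float(stat), float(p)


def pooled_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, int, float]:
    """Student two-sample t-test with pooled variance, two-tailed.

    Returns (t, df, p) with df = n_a + n_b - 2.  Degenerate zero-variance
    input: equal means give (0, df, 1); unequal means are an error because
    t is undefined.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs n >= 2 per group")
    df = int(a.size + b.size - 2)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


def welch_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch unequal-variance alternative; returns (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs n >= 2 per group")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1) / a.size, np.var(b, ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(t), float(df), float(p)


def compare_groups(
    cohort: "Cohort",
    variable: str,
    alpha: float = 0.05,
    sd_mode: str = "population",
    printed_precision: bool = True,
) -> GroupComparison:
    """Full two-group pipeline for one variable, split by VT/VF outcome.

    ``printed_precision`` affects only ``variable="ratio"``: when True
    (reproduction mode) the analysis uses the two-decimal printed ratio
    values; when False, full-precision QRS/QTc quotients.
    """
    if variable not in COMPARISON_VARIABLES:
        raise ValueError(f"variable must be one of {COMPARISON_VARIABLES}")
    yes, no = cohort.split_by_outcome()
    for name, grp in (("VT/VF=yes", yes), ("VT/VF=no", no)):
        if len(grp) < 3:
            raise ValueError(f"group {name} has n={len(grp)} < 3")
    a = yes.values(variable, printed_precision=printed_precision)
    b = no.values(variable, printed_precision=printed_precision)
    _, sp_a = shapiro_wilk(a)
    _, sp_b = shapiro_wilk(b)
    _, bf_p = brown_forsythe(a, b)
    t, df, p = pooled_t_test(a, b)
    return GroupComparison(
        variable=variable,
        group_yes=descriptives(a, sd_mode),
        group_no=descriptives(b, sd_mode),
        shapiro_p_yes=sp_a,
        shapiro_p_no=sp_b,
        brown_forsythe_p=bf_p,
        t_stat=t,
        df=df,
        p_two_tailed=p,
        alpha=alpha,
    )


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Median and 5/25/75/95 percentiles (linear-interpolation convention)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("boxplot_summary of an empty list is undefined")
    p5, p25, med, p75, p95 = np.percentile(x, [5, 25, 50, 75, 95], method="linear")
    return BoxplotSummary(
        median=float(med), p25=float(p25), p75=float(p75), p5=float(p5), p95=float(p95)
    )
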