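"""Cohort-level statistics: normality-gated t-tests and intraobserver variability.

Continuous parameters are summarized as mean +/- SEM (SD/sqrt(n)). Matched
data (pre vs post within an arm) are compared with a paired t-test when the
D'Agostino-Pearson omnibus test does not reject normality of the paired
differences at 0.05, and with the Wilcoxon signed-rank test otherwise;
unmatched data (between-arm change scores) with Welch's t-test, falling
back to the Mann-Whitney rank-sum test. Every result records which test
ran. Two-sided p-values throughout; 0.05 is the significance threshold.

The intraobserver protocol repeats the measurement of a set of ECGs and
reports, per parameter, the mean absolute inter-run difference, its SEM,
and a percentage relative to the parameter's mean absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

ALPHA_NORMALITY: float = 0.05
#: D'Agostino-Pearson needs a minimum sample size for its moment z-scores.
MIN_N_NORMALITY: int = 8


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-group comparison."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    mean_diff: float            # mean(b) - mean(a); for paired: mean of (b - a)
    test_name: str              # "paired-t" | "welch-t" | "signed-rank" | "rank-sum"
    statistic: float
    df: float | None
    p_value: float
    normality_p: tuple[float | None, ...]
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


@dataclass(frozen=True)
class VariabilityResult:
    """Intraobserver variability of one parameter across two runs."""

    parameter: str
    mean_abs_diff: float
    sem_abs_diff: float
    percent: float

    def __post_init__(self) -> None:
        if min(self.mean_abs_diff, self.sem_abs_diff, self.percent) < 0:
            raise ValueError("variability components must be >= 0")


def sem(values: np.ndarray) -> float:
    """Standard error of the mean, SD/sqrt(n) with ddof=1."""
    values = np.asarray(values, float)
    n = len(values)
    if n < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(n))


def normality(values) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus K2 test.

    Combines the skewness and kurtosis z-scores into K2 = z_s^2 + z_k^2,
    chi-square distributed with 2 df under normality. Requires n >= 8.
    """
    values = np.asarray(values, float)
    if len(values) < MIN_N_NORMALITY:
        raise StatsError(
            f"normality test needs n >= {MIN_N_NORMALITY}, got {len(values)}"
        )
    stat, p = _st.normaltest(values)
    return float(stat), float(p)


def _is_normal(values: np.ndarray) -> float | None:
    """Normality p-value, or None when n is too small to test (assume normal)."""
    if len(values) < MIN_N_NORMALITY:
        return None
    return normality(values)[1]


def paired_compare(pre, post) -> ComparisonResult:
    """Within-arm pre/post comparison on matched measurements.

    Paired t-test on the differences when their distribution passes the
    normality gate (or is too small to test); Wilcoxon signed-rank
    otherwise.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if len(pre) != len(post):
        raise StatsError(f"length mismatch: {len(pre)} vs {len(post)}")
    if len(pre) < 3:
        raise StatsError("paired comparison needs n >= 3")
    diffs = pre - post
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise StatsError("degenerate paired data: zero-variance differences")

    norm_p = _is_normal(diffs)
    if norm_p is None or norm_p > ALPHA_NORMALITY:
        res = _st.ttest_rel(pre, post)
        name, stat, df, p = "paired-t", res.statistic, float(res.df), res.pvalue
    else:
        # normal approximation: deterministic, fast, adequate at cohort sizes
        res = _st.wilcoxon(pre, post, method="approx")
        name, stat, df, p = "signed-rank", res.statistic, None, res.pvalue
    return ComparisonResult(
        mean_a=float(pre.mean()), mean_b=float(post.mean()),
        sem_a=sem(pre), sem_b=sem(post),
        mean_diff=float((post - pre).mean()),
        test_name=name, statistic=float(stat), df=df, p_value=float(p),
        normality_p=(norm_p,), n=(len(pre),),
    )


def unpaired_compare(a, b, equal_var: bool = False) -> ComparisonResult:
    """Between-arm comparison of two unmatched samples (e.g. change scores).

    Welch's t-test by default (Student's when ``equal_var``) if both groups
    pass the normality gate; Mann-Whitney rank-sum otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if min(len(a), len(b)) < 3:
        raise StatsError("unpaired comparison needs n >= 3 per group")
    norm_pa, norm_pb = _is_normal(a), _is_normal(b)
    both_normal = all(p is None or p > ALPHA_NORMALITY for p in (norm_pa, norm_pb))
    if both_normal:
        res = _st.ttest_ind(a, b, equal_var=equal_var)
        name, stat, df, p = (
            "student-t" if equal_var else "welch-t",
            res.statistic, float(res.df), res.pvalue,
        )
    else:
        res = _st.mannwhitneyu(a, b, alternative="two-sided")
        name, stat, df, p = "rank-sum", res.statistic, None, res.pvalue
    return ComparisonResult(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=sem(a), sem_b=sem(b),
        mean_diff=float(b.mean() - a.mean()),
        test_name=name, statistic=float(stat), df=df, p_value=float(p),
        normality_p=(norm_pa, norm_pb), n=(len(a), len(b)),
    )


def intraobserver(run1, run2, parameter: str = "") -> VariabilityResult:
    """Raw and percentage variability between two measurement runs.

    Percentage uses the mean absolute parameter value across both runs as
    the denominator.
    """
    run1 = np.asarray(run1, float)
    run2 = np.asarray(run2, float)
    if len(run1) != len(run2):
        raise StatsError(f"length mismatch: {len(run1)} vs {len(run2)}")
    if len(run1) == 0:
        raise StatsError("empty measurement vectors")
    abs_diff = np.abs(run1 - run2)
    denom = float(np.mean(np.abs(np.concatenate([run1, run2]))))
    percent = 0.0 if denom == 0 else float(abs_diff.mean() / denom * 100.0)
    return VariabilityResult(
        parameter=parameter,
        mean_abs_diff=float(abs_diff.mean()),
        sem_abs_diff=sem(abs_diff),
        percent=percent,
    )
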