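"""Statistical layer: two-group comparison, intraclass-correlation
reliability with Landis-Koch interpretation, and bivariate regression.

The ICC model is ICC(2,1): two-way random effects, absolute agreement,
single measures -- readers/reads are crossed with subjects and the
single-measure agreement coefficient is the conservative standard choice.
It is computed from the two-way ANOVA mean squares

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with n subjects (rows) and k raters (columns). t-tests and regressions
delegate to scipy.stats behind this module's result types.
"""
from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "ICCResult",
    "RegressionResult",
    "student_t",
    "icc",
    "interpret_icc",
    "simple_regression",
]


@dataclass(frozen=True)
class TTestResult:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p_two_sided: float


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_subjects: float
    ms_raters: float
    ms_error: float
    category: str


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    p: float


def student_t(group_a, group_b, welch: bool = False) -> TTestResult:
    """Two-sample t-test; pooled variance (Student) by default, Welch on
    request. Two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return TTestResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t=float(res.statistic),
        df=df,
        p_two_sided=float(res.pvalue),
    )


def interpret_icc(value: float) -> str:
    """Landis-Koch agreement bands: slight < 0.20, fair 0.21-0.40,
    moderate 0.41-0.60, substantial 0.61-0.80, almost perfect > 0.80."""
    if value > 1.0 + 1e-12:
        raise ValueError("ICC cannot exceed 1")
    if value <= 0.20:
        return "slight"
    if value <= 0.40:
        return "fair"
    if value <= 0.60:
        return "moderate"
    if value <= 0.80:
        return "substantial"
    return "almost perfect"


def icc(ratings) -> ICCResult:
    """ICC(2,1) (two-way random, absolute agreement, single measures) for
    a complete subjects x raters matrix."""
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")
    if np.isnan(x).any():
        raise ValueError("ratings matrix must be complete")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: all ratings identical across cells")
    value = float((msr - mse) / denom)
    return ICCResult(
        icc=value,
        ms_subjects=float(msr),
        ms_raters=float(msc),
        ms_error=float(mse),
        category=interpret_icc(value),
    )


def simple_regression(x, y) -> RegressionResult:
    """Least-squares line of y on x with Pearson r and its two-sided p
    (t = r sqrt((n-2)/(1-r^2)))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p=float(res.pvalue),
    )
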