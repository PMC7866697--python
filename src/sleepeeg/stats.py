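"""Group-comparison statistics: pooled t, Holm-Sidak step-down adjustment,
simple linear regression, and robust outlier flagging.

The classical (pooled-variance) Student's t is the default two-group test,
with Welch's correction available by flag.  Outlier flagging approximates a
robust false-discovery screen with median/MAD residuals; it flags, never
removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

__all__ = [
    "TestResult",
    "RegressionResult",
    "two_sample_t",
    "holm_sidak_adjust",
    "simple_regression",
    "flag_outliers",
]


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float


def two_sample_t(a, b, welch: bool = False) -> TestResult:
    """Two-sided two-sample t test; pooled variance unless ``welch``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = sst.ttest_ind(a, b, equal_var=not welch)
    df = res.df if welch else a.size + b.size - 2
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        method="welch_t" if welch else "student_t",
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(sst.sem(a)),
        sem_b=float(sst.sem(b)),
    )


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Step-down Sidak adjustment.

    Sort ascending; ``adj_i = 1 - (1 - p_i)^(m - i)`` (0-based rank i);
    enforce monotone nondecreasing down the sorted list; restore the input
    order; clip to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, val)
        adj_sorted[rank] = running
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def simple_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with an F test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression degenerate")
    res = sst.linregress(x, y)
    n = x.size
    f = float(res.rvalue**2 / (1 - res.rvalue**2) * (n - 2)) if abs(res.rvalue) < 1 else float("inf")
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        f_statistic=f,
        df=(1, n - 2),
        p_value=float(res.pvalue),
    )


def flag_outliers(values, q_frac: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Robust outlier screen: flag points whose median/MAD z-score exceeds
    the two-sided normal quantile at ``q_frac``.

    This is a documented approximation of a robust-regression FDR test; it
    returns ``(kept_values, flags)`` and never silently removes anything.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        flags = x != med
    else:
        z = np.abs(x - med) / (1.4826 * mad)
        flags = z > sst.norm.ppf(1 - q_frac / 2.0)
    return x[~flags], flags
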