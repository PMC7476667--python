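"""Accuracy, repeatability, and correlation statistics for the morphometry.

* relative error against a reference measurement,
* single-measure absolute-agreement intraclass correlation ICC(2,1) from a
  two-way random-effects ANOVA (subjects x raters/methods),
* paired t-tests of one method against a reference, and
* Pearson correlation with least-squares regression of a measure against
  intraocular pressure.

Degenerate inputs are flagged, never silently clipped: a negative ICC is
reported as computed, an all-identical ratings table yields a flagged NaN,
and a zero-variance paired difference yields a flagged degenerate or
infinite t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ICCResult",
    "PairedTTestResult",
    "CorrelationResult",
    "relative_error",
    "icc_two_way_random",
    "paired_ttest",
    "pearson_linreg",
]


@dataclass(frozen=True)
class ICCResult:
    value: float
    model: str = "two-way random effects"
    form: str = "ICC(2,1) absolute agreement, single measure"
    n_subjects: int = 0
    n_raters: int = 0
    negative: bool = False
    undefined: bool = False


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    p_value: float
    mean_difference: float
    df: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    p_value: float
    n: int


def relative_error(measured: float, reference: float) -> float:
    """|measured - reference| / reference, for a strictly positive reference."""
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    return abs(measured - reference) / reference


def icc_two_way_random(table: np.ndarray) -> ICCResult:
    """ICC(2,1): single-measure absolute agreement under a two-way random model.

    ``table`` is a complete (n subjects x k raters) array.  From the two-way
    ANOVA mean squares (rows MS_R, columns MS_C, residual MS_E):

        ICC = (MS_R - MS_E) /
              (MS_R + (k - 1) MS_E + (k / n)(MS_C - MS_E))

    Systematic rater offsets enter through MS_C, so this form penalises
    absolute disagreement, not just inconsistency.  Negative estimates are
    returned as computed with ``negative=True``; an all-identical table is
    undefined and returns a flagged NaN.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings table must be 2-D (subjects x raters)")
    if np.isnan(x).any():
        raise ValueError("ratings table must be complete (no missing cells)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        return ICCResult(
            value=float("nan"), n_subjects=n, n_raters=k, undefined=True
        )
    value = (ms_r - ms_e) / denom
    return ICCResult(
        value=float(value), n_subjects=n, n_raters=k, negative=value < 0
    )


def paired_ttest(x: np.ndarray, y: np.ndarray) -> PairedTTestResult:
    """Two-sided paired t-test on d = x - y.

    t = mean(d) / (sd(d) / sqrt(n)) with n - 1 degrees of freedom.  A
    zero-variance difference is flagged: with zero mean the statistic is
    degenerate (t = 0, p = 1); otherwise t is infinite with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean_d == 0.0:
            return PairedTTestResult(0.0, 1.0, 0.0, df, degenerate=True)
        t = float(np.inf) if mean_d > 0 else float(-np.inf)
        return PairedTTestResult(t, 0.0, mean_d, df, degenerate=True)
    t = mean_d / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTTestResult(float(t), float(p), mean_d, df)


def pearson_linreg(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation with least-squares regression of y on x.

    Two-sided p-value via t = r sqrt((n - 2) / (1 - r^2)).  Zero variance in
    either variable leaves r undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson r undefined: a variable has zero variance")
    res = sps.linregress(x, y)
    return CorrelationResult(
        r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n=n,
    )
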