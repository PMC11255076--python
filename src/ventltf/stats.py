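"""Statistical procedures used by the decomposition pipeline.

Variance homogeneity (Bartlett), chi-square critical values, combination of
independent error sources, standard errors, and paired comparisons.  The
Bartlett statistic is computed from summary statistics (sample variances and
group sizes) because that is the form the group bookkeeping produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "VarianceSample",
    "BartlettResult",
    "bartlett_statistic",
    "chi2_quantile",
    "combine_sd",
    "standard_error",
    "paired_t",
]


@dataclass(frozen=True)
class VarianceSample:
    """A group's sample variance ((L/min)^2) and size."""

    variance: float
    n: int

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        if self.n < 2:
            raise ValueError("group size must be at least 2")


@dataclass(frozen=True)
class BartlettResult:
    statistic: float  # corrected statistic T = numerator / C
    uncorrected: float  # numerator, for diagnostics
    correction: float  # Bartlett correction factor C
    df: int
    p_value: float


def bartlett_statistic(samples: Sequence[VarianceSample]) -> BartlettResult:
    """Bartlett test of variance equality from summary statistics.

    T = [(N-k)*ln(sp^2) - sum_i (n_i - 1)*ln(s_i^2)] / C

    with pooled variance sp^2, N total observations, k groups, and
    C = 1 + (sum_i 1/(n_i - 1) - 1/(N-k)) / (3*(k-1)).  Under equal
    variances T ~ chi-square with k-1 degrees of freedom.  The uncorrected
    numerator is reported alongside for diagnostics.
    """
    if len(samples) < 2:
        raise ValueError("need at least two variance samples")
    s2 = np.array([s.variance for s in samples], dtype=float)
    n = np.array([s.n for s in samples], dtype=float)
    if np.any(s2 == 0):
        raise ValueError("zero variance in a group: Bartlett statistic undefined")
    k = len(samples)
    N = n.sum()
    sp2 = ((n - 1) * s2).sum() / (N - k)
    numerator = (N - k) * np.log(sp2) - ((n - 1) * np.log(s2)).sum()
    C = 1.0 + (np.sum(1.0 / (n - 1)) - 1.0 / (N - k)) / (3.0 * (k - 1))
    T = numerator / C
    df = k - 1
    return BartlettResult(
        statistic=float(T),
        uncorrected=float(numerator),
        correction=float(C),
        df=df,
        p_value=float(sps.chi2.sf(T, df)),
    )


def chi2_quantile(p: float, df: int) -> float:
    """Inverse CDF of the chi-square distribution (critical value)."""
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(sps.chi2.ppf(p, df))


def combine_sd(sds: Sequence[float]) -> float:
    """Combine independent error sources: sqrt of the summed variances."""
    arr = np.asarray(sds, dtype=float)
    if np.any(arr < 0):
        raise ValueError("standard deviations must be non-negative")
    return float(np.sqrt(np.sum(arr**2)))


def standard_error(sd: float, n: int) -> float:
    """Standard error of a mean: sd / sqrt(n)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n < 1:
        raise ValueError("n must be at least 1")
    return float(sd / np.sqrt(n))


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Paired t test on matched series; returns (t, two-sided p), df = n-1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be matched 1-d series of length >= 2")
    d = x - y
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences: t statistic undefined")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
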