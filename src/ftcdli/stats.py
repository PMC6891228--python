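"""Group-level statistics on raw values or printed summaries.

All tests here are the classical parametric forms used in small-sample
laterality studies: one-sample and pooled-variance two-sample t-tests
(with Cohen's d), Pearson chi-square on lateralisation-category counts,
Pearson correlation, and the Fisher-z comparison of two independent
correlations.  Every operation accepts either raw values or a
``GroupSummary`` (mean, sd, n), because published group contrasts must be
reproducible from printed summaries alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as _ss

__all__ = [
    "GroupSummary",
    "TTestResult",
    "ChiSquareResult",
    "CorrelationResult",
    "FisherZResult",
    "summarize",
    "one_sample_t",
    "two_sample_t_summary",
    "chi_square",
    "pearson_r",
    "fisher_z_compare",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: sample mean, sample SD (ddof=1), n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float
    d: float


class ChiSquareResult(NamedTuple):
    chi2: float
    df: int
    p: float


class CorrelationResult(NamedTuple):
    r: float
    p: float


class FisherZResult(NamedTuple):
    z: float
    p_one_tailed: float
    p_two_tailed: float


def summarize(values: Sequence[float]) -> GroupSummary:
    """Condense raw values into a GroupSummary (sample SD, ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("values must be a non-empty 1-d sequence")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return GroupSummary(mean=float(np.mean(x)), sd=sd, n=int(x.size))


def _as_summary(data: GroupSummary | Sequence[float]) -> GroupSummary:
    if isinstance(data, GroupSummary):
        return data
    return summarize(data)


def one_sample_t(data: GroupSummary | Sequence[float], mu0: float = 0.0) -> TTestResult:
    """One-sample t-test of the mean against ``mu0``, two-tailed.

    ``d`` is Cohen's d, (mean - mu0) / sd.
    """
    s = _as_summary(data)
    if s.n < 2:
        raise ValueError("one_sample_t requires n >= 2")
    if s.sd <= 0:
        raise ValueError("one_sample_t requires sd > 0")
    se = s.sd / math.sqrt(s.n)
    t = (s.mean - mu0) / se
    df = s.n - 1
    p = 2.0 * _ss.t.sf(abs(t), df)
    d = (s.mean - mu0) / s.sd
    return TTestResult(t=t, df=df, p=p, d=d)


def two_sample_t_summary(
    a: GroupSummary | Sequence[float], b: GroupSummary | Sequence[float]
) -> TTestResult:
    """Pooled-variance (Student) two-sample t-test, two-tailed, from summaries.

    Cohen's d uses the pooled SD.  Difference is a.mean - b.mean.
    """
    sa, sb = _as_summary(a), _as_summary(b)
    if sa.n < 2 or sb.n < 2:
        raise ValueError("two_sample_t_summary requires n >= 2 in both groups")
    df = sa.n + sb.n - 2
    sp2 = ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / df
    sp = math.sqrt(sp2)
    diff = sa.mean - sb.mean
    if sp == 0.0:
        if diff != 0.0:
            raise ValueError("pooled SD is zero but means differ")
        return TTestResult(t=0.0, df=df, p=1.0, d=0.0)
    t = diff / (sp * math.sqrt(1.0 / sa.n + 1.0 / sb.n))
    p = 2.0 * _ss.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, p=p, d=diff / sp)


def pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    """Pooled standard deviation of two groups (Student's t denominator)."""
    df = a.n + b.n - 2
    if df < 1:
        raise ValueError("pooled_sd requires n1 + n2 >= 3")
    return math.sqrt(((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df)


def chi_square(table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-square of independence, no continuity correction.

    Expected counts come from the table margins; df = (rows-1)(cols-1).
    Expected counts below 5 trigger a warning but are not fatal.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if obs.sum() <= 0:
        raise ValueError("grand total must be > 0")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column margin")
    chi2, p, df, expected = _ss.chi2_contingency(obs, correction=False)
    if np.any(expected < 5):
        warnings.warn(
            "some expected counts are below 5; the chi-square approximation "
            "may be inaccurate",
            stacklevel=2,
        )
    return ChiSquareResult(chi2=float(chi2), df=int(df), p=float(p))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with two-tailed p (t transform, df=n-2)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if xa.size < 3:
        raise ValueError("pearson_r requires at least 3 pairs")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("pearson_r is undefined for constant input")
    res = _ss.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> FisherZResult:
    """Compare two independent correlations via the Fisher z-transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); normal reference.
    Both one- and two-tailed p-values are reported.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("fisher_z_compare requires n > 3 in both groups")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p_one = float(_ss.norm.sf(abs(z)))
    return FisherZResult(z=z, p_one_tailed=p_one, p_two_tailed=2.0 * p_one)
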