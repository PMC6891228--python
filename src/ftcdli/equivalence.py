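"""Equivalence testing (TOST) and directional Bayes factors for group nulls.

A non-significant group difference does not show the groups are alike; it
may only reflect low power.  Two complementary tools quantify support for
the null:

* **TOST** (two one-sided tests): pick a smallest effect size of interest
  (SESOI) derived from the critical statistic of a reference study, then
  test whether the observed difference is significantly *inside* the band
  (-SESOI, +SESOI).  Equivalence is declared when both one-sided tests
  reject, which is the same event as the 90% CI lying inside the bounds.

* **Bayes factor with a half-normal prior**: the alternative places all
  its mass on the predicted direction with smaller effects more likely
  (half-normal with scale ``prior_sd``); the evidence is the ratio of the
  marginal likelihood of the observed difference under that prior to its
  likelihood under the point null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import integrate as _integrate
from scipy import stats as _ss

from .stats import GroupSummary, pooled_sd

__all__ = [
    "EquivalenceResult",
    "BayesResult",
    "critical_t",
    "critical_d",
    "sesoi_raw_units",
    "tost",
    "bayes_factor_directional",
    "halfnormal_marginal_closed_form",
]


@dataclass(frozen=True)
class EquivalenceResult:
    """Outcome of a TOST equivalence test on two group summaries."""

    diff: float               # a.mean - b.mean, caller fixes the orientation
    se: float                 # pooled standard error of the difference
    df: int
    sesoi_raw: float          # symmetric bound, raw LI units
    alpha: float
    t_lower: float            # test against the -bound (H0: diff <= -bound)
    t_upper: float            # test against the +bound (H0: diff >= +bound)
    p_lower: float
    p_upper: float
    ci90: tuple[float, float]
    ci95: tuple[float, float]
    verdict_equivalent: bool
    verdict_reject_upper: bool
    verdict_reject_lower: bool


@dataclass(frozen=True)
class BayesResult:
    """Directional Bayes factor; ``bf`` is evidence for the alternative (BF10)."""

    bf: float
    bf_null: float            # reciprocal: evidence for the null (BF01)
    obs_diff: float           # prediction-aligned sign (positive = as predicted)
    se: float
    prior_sd: float
    prior_family: str
    marginal_alt: float       # m1, marginal likelihood under the prior
    marginal_null: float      # m0, likelihood at effect = 0


def critical_t(alpha: float, df: int) -> float:
    """Two-tailed critical value of Student's t (upper alpha/2 quantile)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(_ss.t.ppf(1.0 - alpha / 2.0, df))


def critical_d(t_crit: float, n1: int, n2: int) -> float:
    """Smallest Cohen's d a two-sample design of size n1/n2 can detect at t_crit."""
    if n1 < 2 or n2 < 2:
        raise ValueError("critical_d requires n1, n2 >= 2")
    return t_crit * math.sqrt(1.0 / n1 + 1.0 / n2)


def sesoi_raw_units(d_crit: float, pooled_sd_value: float) -> float:
    """Convert a critical effect size into raw measurement units (the SESOI)."""
    if pooled_sd_value <= 0:
        raise ValueError("pooled_sd must be > 0")
    return d_crit * pooled_sd_value


def tost(
    a: GroupSummary, b: GroupSummary, bound: float, alpha: float = 0.05
) -> EquivalenceResult:
    """Two one-sided pooled-variance t-tests of ``a.mean - b.mean`` against ±bound.

    The caller chooses the orientation by argument order (e.g. hearing - deaf).
    Equivalence holds iff both one-sided tests reject at ``alpha``, equivalently
    iff the (1 - 2*alpha) CI — the 90% CI at alpha = .05 — lies inside the bounds.
    """
    if bound <= 0:
        raise ValueError("equivalence bound must be > 0")
    if a.n < 2 or b.n < 2:
        raise ValueError("tost requires n >= 2 in both groups")
    df = a.n + b.n - 2
    sp = pooled_sd(a, b)
    se = sp * math.sqrt(1.0 / a.n + 1.0 / b.n)
    if se == 0:
        raise ValueError("standard error of the difference is zero")
    diff = a.mean - b.mean

    t_lower = (diff + bound) / se     # H0: diff <= -bound, reject for large t
    t_upper = (diff - bound) / se     # H0: diff >= +bound, reject for small t
    p_lower = float(_ss.t.sf(t_lower, df))
    p_upper = float(_ss.t.cdf(t_upper, df))

    def _ci(level: float) -> tuple[float, float]:
        tq = float(_ss.t.ppf(0.5 + level / 2.0, df))
        return (diff - tq * se, diff + tq * se)

    reject_lower = p_lower < alpha
    reject_upper = p_upper < alpha
    return EquivalenceResult(
        diff=diff,
        se=se,
        df=df,
        sesoi_raw=bound,
        alpha=alpha,
        t_lower=t_lower,
        t_upper=t_upper,
        p_lower=p_lower,
        p_upper=p_upper,
        ci90=_ci(1.0 - 2.0 * alpha),
        ci95=_ci(1.0 - alpha),
        verdict_equivalent=reject_lower and reject_upper,
        verdict_reject_upper=reject_upper,
        verdict_reject_lower=reject_lower,
    )


def halfnormal_marginal_closed_form(obs_diff: float, se: float, prior_sd: float) -> float:
    """Closed-form marginal likelihood under a half-normal(0, prior_sd) prior.

    The Gaussian product identity gives, with s^2 = se^2 + prior_sd^2,

        m1 = 2 * N(obs; 0, s) * Phi(mu_post / sd_post),
        mu_post = obs * prior_sd^2 / s^2,
        sd_post = sqrt(se^2 * prior_sd^2 / s^2).
    """
    s2 = se**2 + prior_sd**2
    mu_post = obs_diff * prior_sd**2 / s2
    sd_post = math.sqrt(se**2 * prior_sd**2 / s2)
    return float(
        2.0
        * _ss.norm.pdf(obs_diff, loc=0.0, scale=math.sqrt(s2))
        * _ss.norm.cdf(mu_post / sd_post)
    )


def _marginal_alt(obs_diff: float, se: float, prior_sd: float, family: str) -> float:
    """Marginal likelihood of obs_diff under the directional prior, by quadrature."""
    if family == "half-normal":
        def prior(delta: float) -> float:
            return 2.0 * _ss.norm.pdf(delta, loc=0.0, scale=prior_sd)
        lo, hi = 0.0, 10.0 * math.sqrt(se**2 + prior_sd**2)
    elif family == "normal":
        def prior(delta: float) -> float:
            return _ss.norm.pdf(delta, loc=0.0, scale=prior_sd)
        half = 10.0 * math.sqrt(se**2 + prior_sd**2)
        lo, hi = -half, half
    elif family == "uniform":
        # uniform on [0, prior_sd]: directional box prior of width prior_sd
        def prior(delta: float) -> float:
            return 1.0 / prior_sd if 0.0 <= delta <= prior_sd else 0.0
        lo, hi = 0.0, prior_sd
    else:
        raise ValueError(f"unknown prior family {family!r}")

    val, _err = _integrate.quad(
        lambda d: _ss.norm.pdf(obs_diff, loc=d, scale=se) * prior(d),
        lo,
        hi,
        epsabs=1e-10,
        epsrel=1e-10,
        limit=200,
    )
    return float(val)


def bayes_factor_directional(
    obs_diff: float,
    se: float,
    prior_sd: float,
    family: str = "half-normal",
) -> BayesResult:
    """Bayes factor for a directional alternative over the point null.

    ``obs_diff`` must be sign-aligned so that positive values are in the
    predicted direction (the half-normal prior puts all mass on delta >= 0).
    Returns BF10 = m1 / m0 along with its reciprocal and both marginals.
    The alternative marginal is computed by adaptive quadrature; the
    half-normal case has a closed form used as a cross-check in tests.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    m0 = float(_ss.norm.pdf(obs_diff, loc=0.0, scale=se))
    m1 = _marginal_alt(obs_diff, se, prior_sd, family)
    bf = m1 / m0
    return BayesResult(
        bf=bf,
        bf_null=1.0 / bf,
        obs_diff=obs_diff,
        se=se,
        prior_sd=prior_sd,
        prior_family=family,
        marginal_alt=m1,
        marginal_null=m0,
    )
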