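"""Binomial rate CIs, score CIs for rate differences, margin decisions.

Single-group rates get Clopper-Pearson exact intervals.  Between-group
differences get the score-type ("standardized asymptotic") interval: the set
of differences delta for which the score statistic, with variance evaluated
at the maximum-likelihood estimates constrained to p1 - p2 = delta, does not
exceed the normal quantile.  The default applies the Miettinen-Nurminen
N/(N-1) small-sample variance factor; the uncorrected Mee variant is exposed
behind a flag.  Unlike the Wald interval, the score interval stays
informative when an observed rate is 0% or 100% - the usual situation for
near-ceiling vaccine seroresponse rates.

Non-inferiority of the test group is declared when the lower confidence
bound for (test rate - reference rate) clears a negative margin, compared on
unrounded bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ProportionCI",
    "DifferenceCI",
    "NonInfDecision",
    "exact_ci",
    "score_diff_ci",
    "decide_noninferiority",
    "round_half_away",
]


@dataclass(frozen=True)
class ProportionCI:
    """A single-group rate with exact confidence bounds, on the % scale."""

    x: int
    n: int
    rate_pct: float
    lower_pct: float
    upper_pct: float
    level: float


@dataclass(frozen=True)
class DifferenceCI:
    """A between-group rate difference (group1 - group2), in percentage points."""

    x1: int
    n1: int
    x2: int
    n2: int
    diff_pct: float
    lower_pct: float
    upper_pct: float
    level: float
    method: str


@dataclass(frozen=True)
class NonInfDecision:
    margin_pct: float
    met: bool


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for rates and bounds)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def exact_ci(x: int, n: int, level: float = 0.95) -> ProportionCI:
    """Clopper-Pearson exact interval for a binomial proportion.

    Bounds come from the beta-quantile inversion of the binomial tail
    equations; x = 0 pins the lower bound at 0 and x = n the upper at 100.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else stats.beta.ppf(alpha / 2.0, x, n - x + 1)
    upper = 1.0 if x == n else stats.beta.isf(alpha / 2.0, x + 1, n - x)
    return ProportionCI(
        x=x,
        n=n,
        rate_pct=100.0 * x / n,
        lower_pct=100.0 * lower,
        upper_pct=100.0 * upper,
        level=level,
    )


def _constrained_mle(p1h: float, p2h: float, n1: int, n2: int, delta: float) -> tuple[float, float]:
    """Closed-form MLE of (p1, p2) under the constraint p1 - p2 = delta.

    Solves the constrained-likelihood cubic (Farrington-Manning) by the
    trigonometric method; exact up to floating point, no iteration.
    """
    theta = n2 / n1
    a = 1.0 + theta
    b = -(1.0 + theta + p1h + theta * p2h + delta * (theta + 2.0))
    c = delta * delta + delta * (2.0 * p1h + theta + 1.0) + p1h + theta * p2h
    d = -p1h * delta * (1.0 + delta)
    v = (b / (3.0 * a)) ** 3 - b * c / (6.0 * a * a) + d / (2.0 * a)
    s2 = (b / (3.0 * a)) ** 2 - c / (3.0 * a)
    s = math.sqrt(max(s2, 0.0))
    u = s if v >= 0 else -s
    if u == 0.0:
        p1t = -b / (3.0 * a)
    else:
        w = (math.pi + math.acos(min(1.0, max(-1.0, v / u**3)))) / 3.0
        p1t = 2.0 * u * math.cos(w) - b / (3.0 * a)
    p1t = min(1.0, max(0.0, p1t))
    p2t = min(1.0, max(0.0, p1t - delta))
    return p1t, p2t


def _score_stat(
    x1: int, n1: int, x2: int, n2: int, delta: float, corrected: bool
) -> float:
    """Score statistic for H0: p1 - p2 = delta, constrained-MLE variance."""
    p1h, p2h = x1 / n1, x2 / n2
    p1t, p2t = _constrained_mle(p1h, p2h, n1, n2, delta)
    var = p1t * (1.0 - p1t) / n1 + p2t * (1.0 - p2t) / n2
    if corrected:
        N = n1 + n2
        var *= N / (N - 1.0)
    num = p1h - p2h - delta
    if var <= 0.0:
        if num == 0.0:
            return 0.0
        return math.inf if num > 0 else -math.inf
    return num / math.sqrt(var)


def score_diff_ci(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    level: float = 0.975,
    corrected: bool = True,
) -> DifferenceCI:
    """Score confidence interval for the difference of two proportions.

    Parameters
    ----------
    x1, n1, x2, n2:
        Responder counts and denominators for group 1 (test) and group 2
        (reference).
    level:
        Two-sided confidence level; the trial's non-inferiority objectives
        use 0.975 (Bonferroni across the two sub-cohorts).
    corrected:
        Apply the Miettinen-Nurminen N/(N-1) variance factor (default).
        ``False`` gives the uncorrected Mee interval.

    Bounds are located by Brent root-finding on the monotone score statistic
    to 1e-10 on the proportion scale; the interval is well defined at the
    0/N and N/N boundaries.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both denominators must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts outside their denominators")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    d = x1 / n1 - x2 / n2
    eps = 1e-12

    def f_lower(delta: float) -> float:
        return _score_stat(x1, n1, x2, n2, delta, corrected) - z

    def f_upper(delta: float) -> float:
        return _score_stat(x1, n1, x2, n2, delta, corrected) + z

    # score stat decreases in delta: lower root left of d, upper root right
    if f_lower(-1.0 + eps) > 0.0 and f_lower(d) < 0.0:
        lower = optimize.brentq(f_lower, -1.0 + eps, d, xtol=1e-10)
    else:
        lower = -1.0
    if f_upper(1.0 - eps) < 0.0 and f_upper(d) > 0.0:
        upper = optimize.brentq(f_upper, d, 1.0 - eps, xtol=1e-10)
    else:
        upper = 1.0
    return DifferenceCI(
        x1=x1,
        n1=n1,
        x2=x2,
        n2=n2,
        diff_pct=100.0 * d,
        lower_pct=100.0 * lower,
        upper_pct=100.0 * upper,
        level=level,
        method="miettinen-nurminen" if corrected else "mee",
    )


def decide_noninferiority(ci: DifferenceCI, margin_pct: float) -> NonInfDecision:
    """Non-inferiority holds iff the unrounded lower bound clears the margin."""
    if margin_pct >= 0:
        raise ValueError("rate-difference margin must be negative (e.g. -5 or -10)")
    return NonInfDecision(margin_pct=margin_pct, met=bool(ci.lower_pct >= margin_pct))
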