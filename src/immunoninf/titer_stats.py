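"""Geometric means and baseline-adjusted geometric-mean ratios (ANCOVA).

Antibody concentrations are treated as log10-normal.  Group contrasts are
estimated from an ordinary least-squares fit of

    log10(post) ~ group + log10(pre) [+ country]

so the exponentiated group coefficient is the baseline-adjusted geometric
mean concentration (or titer) ratio, test group over reference group, with a
t-based confidence interval.  Values below the assay cut-off are imputed at
half the cut-off before taking logs, the usual serology convention.

Non-inferiority on the ratio scale is declared when the lower confidence
bound reaches the margin (0.67 in this trial), on unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "GeometricMeanCI",
    "AncovaResult",
    "RatioNonInfDecision",
    "geometric_mean",
    "ancova_ratio",
    "decide_ratio_noninferiority",
]


@dataclass(frozen=True)
class GeometricMeanCI:
    gm: float
    lower: float
    upper: float
    n: int
    level: float


@dataclass(frozen=True)
class AncovaResult:
    """Adjusted geometric means and their ratio for one antigen."""

    antigen: str
    adjusted_gm_1: float
    adjusted_gm_2: float
    ratio: float
    lower: float
    upper: float
    level: float
    covariates: tuple[str, ...]
    n1: int
    n2: int


@dataclass(frozen=True)
class RatioNonInfDecision:
    margin_ratio: float
    met: bool


def _impute(values: np.ndarray, cutoff: float | None) -> np.ndarray:
    if cutoff is None:
        return values
    if cutoff <= 0:
        raise ValueError("assay cut-off must be positive")
    return np.where(values < cutoff, cutoff / 2.0, values)


def geometric_mean(
    concs: Sequence[float], cutoff: float | None = None, level: float = 0.95
) -> GeometricMeanCI:
    """Geometric mean with t-based CI on the log10 scale.

    Values below ``cutoff`` are replaced by ``cutoff / 2`` before the log
    transform.  With a single observation the bounds are undefined (NaN).
    """
    arr = np.asarray(list(concs), dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty list")
    if np.any(arr <= 0) and cutoff is None:
        raise ValueError("non-positive concentration without an assay cut-off to impute at")
    logs = np.log10(_impute(arr, cutoff))
    m = logs.mean()
    n = logs.size
    if n == 1:
        return GeometricMeanCI(gm=10.0**m, lower=np.nan, upper=np.nan, n=1, level=level)
    se = logs.std(ddof=1) / np.sqrt(n)
    t = stats.t.ppf(1.0 - (1.0 - level) / 2.0, n - 1)
    return GeometricMeanCI(
        gm=10.0**m, lower=10.0 ** (m - t * se), upper=10.0 ** (m + t * se), n=n, level=level
    )


def ancova_ratio(
    group1: Sequence[tuple[float, float]],
    group2: Sequence[tuple[float, float]],
    covariates: Sequence[str] = ("baseline",),
    level: float = 0.975,
    antigen: str = "",
    cutoff: float | None = None,
    country1: Sequence[str] | None = None,
    country2: Sequence[str] | None = None,
) -> AncovaResult:
    """Baseline-adjusted GM ratio (group1 over group2) from an ANCOVA fit.

    Parameters
    ----------
    group1, group2:
        Complete (pre, post) concentration pairs; subjects missing either
        value must be dropped upstream.
    covariates:
        Any of ``"baseline"`` (log10 pre-vaccination concentration) and
        ``"country"`` (fixed-effect categorical; requires ``country1``/
        ``country2``).  An empty sequence reduces the estimate to the ratio
        of unadjusted geometric means.
    level:
        Two-sided confidence level for the ratio (0.975 in this trial).

    The adjusted geometric means are the model predictions for each group at
    the grand mean of the covariate columns; the ratio itself does not depend
    on where the covariates are evaluated.
    """
    g1 = np.asarray(list(group1), dtype=float)
    g2 = np.asarray(list(group2), dtype=float)
    covariates = tuple(covariates)
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("need at least 3 complete pairs per group")
    unknown = set(covariates) - {"baseline", "country"}
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    use_country = "country" in covariates
    if use_country and (country1 is None or country2 is None):
        raise ValueError("country covariate requested but country labels not supplied")

    pre = np.concatenate([g1[:, 0], g2[:, 0]])
    post = np.concatenate([g1[:, 1], g2[:, 1]])
    if np.any(pre <= 0) or np.any(post <= 0):
        if cutoff is None:
            raise ValueError("non-positive concentration without an assay cut-off to impute at")
    df = pd.DataFrame(
        {
            "log_post": np.log10(_impute(post, cutoff)),
            "log_pre": np.log10(_impute(pre, cutoff)),
            "group": np.r_[np.ones(len(g1)), np.zeros(len(g2))],
        }
    )
    formula = "log_post ~ group"
    if "baseline" in covariates:
        formula += " + log_pre"
    if use_country:
        df["country"] = list(country1) + list(country2)
        if df["country"].nunique() > 1:
            formula += " + C(country)"
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("singular ANCOVA design")
    beta = fit.params["group"]
    lo, hi = fit.conf_int(alpha=1.0 - level).loc["group"]

    exog = fit.model.exog.copy()
    names = fit.model.exog_names
    xbar = exog.mean(axis=0)
    gi = names.index("group")
    x1, x2 = xbar.copy(), xbar.copy()
    x1[gi], x2[gi] = 1.0, 0.0
    adj1 = 10.0 ** float(x1 @ fit.params.values)
    adj2 = 10.0 ** float(x2 @ fit.params.values)
    return AncovaResult(
        antigen=antigen,
        adjusted_gm_1=adj1,
        adjusted_gm_2=adj2,
        ratio=10.0**beta,
        lower=10.0**lo,
        upper=10.0**hi,
        level=level,
        covariates=covariates,
        n1=len(g1),
        n2=len(g2),
    )


def decide_ratio_noninferiority(res: AncovaResult, margin_ratio: float = 0.67) -> RatioNonInfDecision:
    """Non-inferiority holds iff the unrounded lower ratio bound >= margin."""
    if not 0.0 < margin_ratio < 1.0:
        raise ValueError("ratio margin must lie in (0, 1)")
    return RatioNonInfDecision(margin_ratio=margin_ratio, met=bool(res.lower >= margin_ratio))
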