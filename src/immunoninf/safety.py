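"""Descriptive reactogenicity and safety tabulation (total vaccinated cohort).

Counts are of subjects reporting at least one event in a category, not of
episodes, tabulated per sub-cohort and arm with exact two-sided 95%
confidence intervals.  Per-category denominators may be supplied (diary
return rates make the documented-dose N differ by category); otherwise the
group size is used.  No between-arm inference is performed - the trial's
safety analysis is descriptive only.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .proportion_stats import exact_ci, round_half_away
from .synth import AE_WINDOWS
from .trial_data import SubjectRecord

__all__ = ["KNOWN_CATEGORIES", "incidence_table"]

KNOWN_CATEGORIES = tuple(AE_WINDOWS)


def incidence_table(
    records: Sequence[SubjectRecord],
    categories: Sequence[str] | None = None,
    denominators: Mapping[tuple[int, str, str], int] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Long-format incidence table: one row per (sub_cohort, arm, category, grade).

    Parameters
    ----------
    records:
        Total vaccinated cohort, arms already pooled.
    categories:
        Categories to tabulate (default: all known).  Unknown names raise.
    denominators:
        Optional ``(sub_cohort, arm, category) -> N`` overrides.

    Returns columns: sub_cohort, arm, category, window, grade3_only, n, N,
    pct, lower_pct, upper_pct (percentages to full precision; a rendered
    1-dp column ``pct_1dp`` is included for display).
    """
    if categories is None:
        categories = KNOWN_CATEGORIES
    unknown = [c for c in categories if c not in AE_WINDOWS]
    if unknown:
        raise ValueError(f"unknown AE categories: {unknown}")

    groups: dict[tuple[int, str], list[SubjectRecord]] = {}
    for r in records:
        groups.setdefault((r.sub_cohort, r.arm.value), []).append(r)

    rows = []
    for (sc, arm), subs in sorted(groups.items()):
        for cat in categories:
            for grade3_only in (False, True):
                n = sum(
                    1
                    for r in subs
                    if any(
                        ae.category == cat and (ae.grade3 or not grade3_only)
                        for ae in r.ae_records
                    )
                )
                N = len(subs)
                if denominators is not None:
                    N = denominators.get((sc, arm, cat), N)
                ci = exact_ci(n, N, level=level)
                rows.append(
                    {
                        "sub_cohort": sc,
                        "arm": arm,
                        "category": cat,
                        "window": AE_WINDOWS[cat],
                        "grade3_only": grade3_only,
                        "n": n,
                        "N": N,
                        "pct": ci.rate_pct,
                        "lower_pct": ci.lower_pct,
                        "upper_pct": ci.upper_pct,
                        "pct_1dp": round_half_away(ci.rate_pct, 1),
                    }
                )
    return pd.DataFrame(rows)
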