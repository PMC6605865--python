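"""Per-subject antibody response classification.

Two families of rules are used:

*Seroresponse* — the Day-42 concentration meets a fixed absolute threshold,
ignoring the pre-vaccination value (the study population is almost entirely
seropositive at baseline, so fold-rise criteria would be uninformative for
the MMR and varicella components).

*Booster response* — a tiered rule whose criterion depends on where the
pre-vaccination concentration sits relative to the assay cut-off ``c``:

pertussis antigens (PT, FHA, PRN)
    pre < c          -> post >= 4c
    c <= pre < 4c    -> post >= 4 * pre
    pre >= 4c        -> post >= 2 * pre

diphtheria / tetanus toxoids (DT, TT), cut-off = 0.1 IU/mL seroprotection
    pre < 0.1        -> post >= 0.4 IU/mL
    pre >= 0.1       -> post >= 4 * pre

All comparisons are inclusive: equality at a boundary counts as a response.
A subject with a missing required concentration gets a null responder flag
and is excluded from the rate denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .proportion_stats import ProportionCI, exact_ci
from .trial_data import AntigenSpec, RuleKind, SubjectRecord

__all__ = [
    "ResponseKind",
    "Tier",
    "ResponseCall",
    "ResponseSummary",
    "DTT_SEROPROTECTION",
    "DTT_RESPONSE_FLOOR",
    "call_seroresponse",
    "call_booster_pertussis",
    "call_booster_dtt",
    "classify",
    "summarize_responses",
]

#: DT/TT seroprotection threshold (IU/mL) splitting the two booster tiers.
DTT_SEROPROTECTION = 0.1
#: Absolute post-vaccination response criterion (IU/mL) for baseline-seronegative DT/TT.
DTT_RESPONSE_FLOOR = 0.4


class ResponseKind(str, enum.Enum):
    SERORESPONSE = "seroresponse"
    BOOSTER = "booster"


class Tier(str, enum.Enum):
    """Which branch of the classification rule applied."""

    BELOW_CUTOFF = "below_cutoff"
    LOW_POSITIVE = "low_positive"
    HIGH_POSITIVE = "high_positive"
    SERONEG_DTT = "seroneg_dtt"
    SEROPOS_DTT = "seropos_dtt"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ResponseCall:
    antigen: str
    kind: ResponseKind
    responder: bool | None
    tier: Tier


@dataclass(frozen=True)
class ResponseSummary:
    """Responder count over evaluable subjects, with exact 95% CI."""

    antigen: str
    kind: ResponseKind
    x: int
    n: int
    rate_pct: float
    ci: ProportionCI


def call_seroresponse(post_conc: float | None, spec: AntigenSpec) -> ResponseCall:
    """Threshold rule on the post-vaccination concentration only."""
    if spec.rule_kind is not RuleKind.SERORESPONSE:
        raise ValueError(f"{spec.name} does not use the seroresponse rule")
    responder = None if post_conc is None else post_conc >= spec.seroresponse_threshold
    return ResponseCall(spec.name, ResponseKind.SERORESPONSE, responder, Tier.NOT_APPLICABLE)


def call_booster_pertussis(
    pre_conc: float | None, post_conc: float | None, spec: AntigenSpec
) -> ResponseCall:
    """Three-tier fold-rise rule anchored on the assay cut-off."""
    if spec.rule_kind is not RuleKind.BOOSTER_PERTUSSIS:
        raise ValueError(f"{spec.name} does not use the pertussis booster rule")
    c = spec.assay_cutoff
    if pre_conc is None:
        return ResponseCall(spec.name, ResponseKind.BOOSTER, None, Tier.NOT_APPLICABLE)
    if pre_conc < c:
        tier, criterion = Tier.BELOW_CUTOFF, 4.0 * c
    elif pre_conc < 4.0 * c:
        tier, criterion = Tier.LOW_POSITIVE, 4.0 * pre_conc
    else:
        tier, criterion = Tier.HIGH_POSITIVE, 2.0 * pre_conc
    responder = None if post_conc is None else post_conc >= criterion
    return ResponseCall(spec.name, ResponseKind.BOOSTER, responder, tier)


def call_booster_dtt(
    pre_conc: float | None, post_conc: float | None, spec: AntigenSpec
) -> ResponseCall:
    """Two-tier rule split at the 0.1 IU/mL seroprotection threshold."""
    if spec.rule_kind is not RuleKind.BOOSTER_DTT:
        raise ValueError(f"{spec.name} does not use the DT/TT booster rule")
    if pre_conc is None:
        return ResponseCall(spec.name, ResponseKind.BOOSTER, None, Tier.NOT_APPLICABLE)
    if pre_conc < DTT_SEROPROTECTION:
        tier, criterion = Tier.SERONEG_DTT, DTT_RESPONSE_FLOOR
    else:
        tier, criterion = Tier.SEROPOS_DTT, 4.0 * pre_conc
    responder = None if post_conc is None else post_conc >= criterion
    return ResponseCall(spec.name, ResponseKind.BOOSTER, responder, tier)


def classify(
    pre_conc: float | None, post_conc: float | None, spec: AntigenSpec
) -> ResponseCall:
    """Dispatch to the rule the antigen's assay defines."""
    if spec.rule_kind is RuleKind.SERORESPONSE:
        return call_seroresponse(post_conc, spec)
    if spec.rule_kind is RuleKind.BOOSTER_PERTUSSIS:
        return call_booster_pertussis(pre_conc, post_conc, spec)
    if spec.rule_kind is RuleKind.BOOSTER_DTT:
        return call_booster_dtt(pre_conc, post_conc, spec)
    raise ValueError(f"{spec.name} ({spec.rule_kind.value}) has no response rule")


def summarize_responses(
    records: Sequence[SubjectRecord],
    spec: AntigenSpec,
    kind: ResponseKind | None = None,
    level: float = 0.95,
) -> ResponseSummary:
    """Responder rate for one group of subjects with exact 95% CI.

    Subjects with a null responder call (missing required concentrations)
    are excluded from both numerator and denominator, giving per-endpoint
    complete-case denominators.
    """
    if kind is None:
        kind = (
            ResponseKind.SERORESPONSE
            if spec.rule_kind is RuleKind.SERORESPONSE
            else ResponseKind.BOOSTER
        )
    x = n = 0
    for r in records:
        pre, post = r.measurements.get(spec.name, (None, None))
        call = classify(pre, post, spec)
        if call.responder is None:
            continue
        n += 1
        x += int(call.responder)
    if n == 0:
        raise ValueError(f"{spec.name}: no evaluable subjects")
    return ResponseSummary(
        antigen=spec.name,
        kind=kind,
        x=x,
        n=n,
        rate_pct=100.0 * x / n,
        ci=exact_ci(x, n, level=level),
    )
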