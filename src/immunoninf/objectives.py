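"""Non-inferiority objectives, multiplicity gatekeeping, and power simulation.

The trial's confirmatory analysis is a family of non-inferiority objectives,
each a conjunction of per-antigen criteria of one of two shapes:

* rate difference - lower bound of the two-sided 97.5% score CI for
  (MMR-RIT rate minus MMR II rate) >= margin (-5 or -10 percentage points);
* geometric-mean ratio - lower bound of the two-sided 97.5% ANCOVA CI for
  (MMR-RIT GM over MMR II GM) >= 0.67.

Multiplicity is controlled by Bonferroni across the two immunogenicity
sub-cohorts - realized, as in the trial's tables, by fixed 97.5% two-sided
CIs rather than p-value splitting - plus hierarchical gatekeeping: the
secondary objectives are formally assessed only if every co-primary
objective succeeds.  The published objective list does not order the
secondaries relative to each other, so the default gate mode conditions
each secondary only on the primaries; a strict fixed-sequence mode is
available behind a flag.

``simulate_power`` estimates operating characteristics (global power, or
type-I error when the generative truth sits on a margin) by replicated
synthetic trials pushed through the full pipeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from . import response_rules, titer_stats
from .proportion_stats import decide_noninferiority, score_diff_ci
from .synth import SyntheticConfig, generate_trial
from .trial_data import (
    AntigenSpec,
    Arm,
    CohortLabel,
    SubjectRecord,
    default_antigen_panel,
    pool_arms,
    select_cohort,
)

__all__ = [
    "EndpointKind",
    "ObjectiveNode",
    "NodeOutcome",
    "GatekeepingResult",
    "PowerResult",
    "default_objective_tree",
    "objectives_from_yaml",
    "evaluate_objectives",
    "simulate_power",
    "planned_evaluable",
]


def planned_evaluable(n_planned: int, nonevaluable_rate: float = 0.20) -> int:
    """Planned evaluable count under an assumed non-evaluable rate.

    The sample-size plan assumed 20% of randomized subjects would not be
    evaluable in the according-to-protocol cohort, so e.g. planned arms of
    822 and 274 yield 657 and 219 evaluable (876 in total per sub-cohort).
    """
    if not 0.0 <= nonevaluable_rate < 1.0:
        raise ValueError("non-evaluable rate must lie in [0, 1)")
    return int(n_planned * (1.0 - nonevaluable_rate))


class EndpointKind(str, enum.Enum):
    SRR_DIFF = "srr_diff"
    BRR_DIFF = "brr_diff"
    GMC_RATIO = "gmc_ratio"
    GMT_RATIO = "gmt_ratio"


_DIFF_KINDS = (EndpointKind.SRR_DIFF, EndpointKind.BRR_DIFF)


@dataclass(frozen=True)
class ObjectiveNode:
    """One testable criterion in the gatekeeping tree.

    ``margin`` is in percentage points (negative) for difference endpoints
    and a ratio in (0, 1) for GM-ratio endpoints.  All antigens listed must
    individually clear the margin for the node to be met.
    """

    id: str
    sub_cohort: int
    endpoint_kind: EndpointKind
    antigens: tuple[str, ...]
    margin: float
    ci_level: float = 0.975
    tier: str = "primary"
    order_index: int = 0
    covariates: tuple[str, ...] = ("baseline",)

    def __post_init__(self) -> None:
        if self.tier not in ("primary", "secondary"):
            raise ValueError("tier must be 'primary' or 'secondary'")
        if self.endpoint_kind in _DIFF_KINDS and self.margin >= 0:
            raise ValueError(f"{self.id}: difference margin must be negative")
        if self.endpoint_kind not in _DIFF_KINDS and not 0 < self.margin < 1:
            raise ValueError(f"{self.id}: ratio margin must lie in (0, 1)")


@dataclass(frozen=True)
class NodeOutcome:
    node: ObjectiveNode
    evaluated: bool
    met: bool | None
    #: antigen -> {"ci"/"result": ..., "met": bool}
    details: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GatekeepingResult:
    nodes: tuple[NodeOutcome, ...]
    overall_success: bool


@dataclass(frozen=True)
class PowerResult:
    n_replicates: int
    success_rate: float
    seed: int
    assumptions: SyntheticConfig
    replicates: tuple[GatekeepingResult, ...] = ()


def default_objective_tree() -> list[ObjectiveNode]:
    """The four co-primary and four secondary non-inferiority objectives.

    The first secondary objective (varicella) jointly requires its SRR
    difference and its GMC ratio to clear their margins; it is represented
    as two consecutive nodes sharing the "S1" prefix, so the tree has nine
    nodes for the eight objectives.  Secondary ordering follows the listing
    sequence of the protocol objectives (varicella, DTaP booster rates,
    polio titers, pertussis concentrations) and is config-overridable.
    """
    mmr = ("measles", "mumps", "rubella")
    return [
        ObjectiveNode("P1-srr-coad", 1, EndpointKind.SRR_DIFF, mmr, -5.0, tier="primary", order_index=0),
        ObjectiveNode("P2-gmc-coad", 1, EndpointKind.GMC_RATIO, mmr, 0.67, tier="primary", order_index=1),
        ObjectiveNode("P3-srr-alone", 2, EndpointKind.SRR_DIFF, mmr, -5.0, tier="primary", order_index=2),
        ObjectiveNode(
            "P4-gmc-alone", 2, EndpointKind.GMC_RATIO, mmr, 0.67,
            tier="primary", order_index=3, covariates=("baseline", "country"),
        ),
        ObjectiveNode("S1-vzv-srr", 1, EndpointKind.SRR_DIFF, ("VZV",), -5.0, tier="secondary", order_index=4),
        ObjectiveNode("S1-vzv-gmc", 1, EndpointKind.GMC_RATIO, ("VZV",), 0.67, tier="secondary", order_index=5),
        ObjectiveNode(
            "S2-dtap-brr", 1, EndpointKind.BRR_DIFF, ("DT", "TT", "PT", "FHA", "PRN"), -10.0,
            tier="secondary", order_index=6,
        ),
        ObjectiveNode(
            "S3-pv-gmt", 1, EndpointKind.GMT_RATIO, ("PV1", "PV2", "PV3"), 0.67,
            tier="secondary", order_index=7,
        ),
        ObjectiveNode(
            "S4-pertussis-gmc", 1, EndpointKind.GMC_RATIO, ("PT", "FHA", "PRN"), 0.67,
            tier="secondary", order_index=8,
        ),
    ]


def objectives_from_yaml(path) -> list[ObjectiveNode]:
    """Load an objective tree from a YAML list of node mappings."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    nodes = []
    for entry in raw:
        nodes.append(
            ObjectiveNode(
                id=entry["id"],
                sub_cohort=int(entry["sub_cohort"]),
                endpoint_kind=EndpointKind(entry["endpoint_kind"]),
                antigens=tuple(entry["antigens"]),
                margin=float(entry["margin"]),
                ci_level=float(entry.get("ci_level", 0.975)),
                tier=entry.get("tier", "primary"),
                order_index=int(entry.get("order_index", 0)),
                covariates=tuple(entry.get("covariates", ["baseline"])),
            )
        )
    return nodes


def _evaluate_node(
    node: ObjectiveNode,
    atp: Sequence[SubjectRecord],
    spec_by_name: dict[str, AntigenSpec],
    score_corrected: bool,
) -> tuple[bool, dict]:
    sub = [r for r in atp if r.sub_cohort == node.sub_cohort]
    rit = [r for r in sub if r.arm is Arm.MMR_RIT]
    ref = [r for r in sub if r.arm is Arm.MMR_II]
    details: dict = {}
    met_all = True
    for antigen in node.antigens:
        if antigen not in spec_by_name:
            raise ValueError(f"{node.id}: antigen {antigen!r} not in schema")
        spec = spec_by_name[antigen]
        if not any(antigen in r.measurements for r in sub):
            raise ValueError(f"{node.id}: no {antigen!r} measurements in sub-cohort {node.sub_cohort}")
        if node.endpoint_kind in _DIFF_KINDS:
            s1 = response_rules.summarize_responses(rit, spec)
            s2 = response_rules.summarize_responses(ref, spec)
            ci = score_diff_ci(s1.x, s1.n, s2.x, s2.n, level=node.ci_level, corrected=score_corrected)
            decision = decide_noninferiority(ci, node.margin)
            details[antigen] = {"ci": ci, "met": decision.met}
        else:
            pairs1 = _complete_pairs(rit, antigen)
            pairs2 = _complete_pairs(ref, antigen)
            use_country = "country" in node.covariates
            res = titer_stats.ancova_ratio(
                [p for p, _ in pairs1],
                [p for p, _ in pairs2],
                covariates=node.covariates,
                level=node.ci_level,
                antigen=antigen,
                cutoff=spec.assay_cutoff,
                country1=[c for _, c in pairs1] if use_country else None,
                country2=[c for _, c in pairs2] if use_country else None,
            )
            decision = titer_stats.decide_ratio_noninferiority(res, node.margin)
            details[antigen] = {"result": res, "met": decision.met}
        met_all = met_all and decision.met
    return met_all, details


def _complete_pairs(records: Sequence[SubjectRecord], antigen: str):
    out = []
    for r in records:
        pre, post = r.measurements.get(antigen, (None, None))
        if pre is not None and post is not None:
            out.append(((pre, post), r.country))
    return out


def evaluate_objectives(
    trial: Sequence[SubjectRecord],
    tree: Sequence[ObjectiveNode] | None = None,
    schema: Sequence[AntigenSpec] | None = None,
    gate_mode: str = "primary",
    score_corrected: bool = True,
) -> GatekeepingResult:
    """Run the full gatekept confirmatory analysis on a trial.

    Lot arms are pooled, the according-to-protocol cohort is derived, every
    primary node is assessed in parallel, and secondary nodes are assessed
    (in ``order_index`` order) only if all primaries are met - and, with
    ``gate_mode="sequential"``, only while every earlier secondary is also
    met.  ``overall_success`` requires every node to be evaluated and met.
    """
    if tree is None:
        tree = default_objective_tree()
    if schema is None:
        schema = default_antigen_panel()
    if gate_mode not in ("primary", "sequential"):
        raise ValueError("gate_mode must be 'primary' or 'sequential'")
    spec_by_name = {s.name: s for s in schema}
    atp = select_cohort(pool_arms(trial), CohortLabel.ATP_IMMUNOGENICITY)

    ordered = sorted(tree, key=lambda nd: nd.order_index)
    primaries = [nd for nd in ordered if nd.tier == "primary"]
    secondaries = [nd for nd in ordered if nd.tier == "secondary"]

    outcomes: dict[str, NodeOutcome] = {}
    for node in primaries:
        met, details = _evaluate_node(node, atp, spec_by_name, score_corrected)
        outcomes[node.id] = NodeOutcome(node, evaluated=True, met=met, details=details)
    gate_open = all(o.met for o in outcomes.values())

    for node in secondaries:
        if not gate_open:
            outcomes[node.id] = NodeOutcome(node, evaluated=False, met=None)
            continue
        met, details = _evaluate_node(node, atp, spec_by_name, score_corrected)
        outcomes[node.id] = NodeOutcome(node, evaluated=True, met=met, details=details)
        if gate_mode == "sequential" and not met:
            gate_open = False

    ordered_outcomes = tuple(outcomes[nd.id] for nd in ordered)
    success = all(o.evaluated and o.met for o in ordered_outcomes)
    return GatekeepingResult(nodes=ordered_outcomes, overall_success=success)


def simulate_power(
    assumptions: SyntheticConfig,
    tree: Sequence[ObjectiveNode] | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    schema: Sequence[AntigenSpec] | None = None,
    gate_mode: str = "primary",
    keep_replicates: bool = True,
) -> PowerResult:
    """Monte Carlo operating characteristics of the gatekept analysis.

    Each replicate draws an independent synthetic trial from ``assumptions``
    (re-seeded from a spawned child of ``seed``) and runs
    :func:`evaluate_objectives`; the success rate is the fraction of
    replicates where every objective is met.  Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    results = []
    n_success = 0
    for child in children:
        rep_seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        trial = generate_trial(replace(assumptions, seed=rep_seed), schema=schema)
        res = evaluate_objectives(trial, tree=tree, schema=schema, gate_mode=gate_mode)
        n_success += int(res.overall_success)
        if keep_replicates:
            results.append(res)
    return PowerResult(
        n_replicates=n_replicates,
        success_rate=n_success / n_replicates,
        seed=seed,
        assumptions=assumptions,
        replicates=tuple(results),
    )
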