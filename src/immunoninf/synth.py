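"""Synthetic trial generator.

Emulates the statistical structure of a two-arm, three-sub-cohort MMR
second-dose trial: 6:1:1 blocked randomization (MMR-RIT and two MMR II lots,
pooled to 3:1 in analysis), correlated bivariate log-normal pre/post antibody
concentrations per antigen, near-ceiling seroresponse rates induced by the
log-normal tail, non-informative according-to-protocol attrition, and
Bernoulli adverse-event flags.  Sub-cohort 1 carries the full assay panel
(MMR + varicella + DTaP-IPV antigens), sub-cohort 2 the MMR components only,
and sub-cohort 3 none (safety follow-up only).

The default configuration is calibrated to the published summary statistics
of the trial (NCT01621802): arm sizes 802/298, 796/303 and 1319/489 per
sub-cohort, pre-vaccination geometric mean concentrations inside the printed
ranges, and post-vaccination GMs equal to the printed Day-42 values, with a
true between-arm ratio of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .trial_data import (
    MMR_COMPONENTS,
    AeRecord,
    AntigenSpec,
    Arm,
    RuleKind,
    SubjectRecord,
    default_antigen_panel,
)

__all__ = [
    "AntigenSim",
    "SyntheticConfig",
    "ANTIGENS_BY_SUBCOHORT",
    "AE_WINDOWS",
    "generate_trial",
    "default_config",
    "config_from_yaml",
]

#: Which antigens are assayed in each sub-cohort.
ANTIGENS_BY_SUBCOHORT: dict[int, tuple[str, ...]] = {
    1: ("measles", "mumps", "rubella", "VZV", "DT", "TT", "PT", "FHA", "PRN", "PV1", "PV2", "PV3"),
    2: MMR_COMPONENTS,
    3: (),
}

#: Solicited/unsolicited AE collection windows per category.
AE_WINDOWS: dict[str, str] = {
    "pain": "d0_3",
    "redness": "d0_3",
    "swelling": "d0_3",
    "fever": "d0_42",
    "fever_d5_12": "d5_12",
    "any_rash": "d0_42",
    "measles_rubella_like_rash": "d0_42",
    "varicella_like_rash": "d0_42",
    "parotid_swelling": "d0_42",
    "febrile_convulsion_headache": "d0_42",
    "drowsiness": "d0_3",
    "loss_of_appetite": "d0_3",
    "unsolicited": "d0_42",
    "SAE": "d0_180",
    "NOCD": "d0_180",
}

#: Categories solicited only in the co-administration sub-cohort.
_SUBCOHORT1_ONLY = {"varicella_like_rash", "drowsiness", "loss_of_appetite"}


@dataclass(frozen=True)
class AntigenSim:
    """Generative parameters for one antigen's pre/post concentrations.

    ``(log10 pre, log10 post)`` is bivariate normal with geometric means
    ``pre_gm`` / ``post_gm``, log10 standard deviations and correlation as
    given.  ``response_rate_override`` (scalar, or (MMR-RIT, MMR II) pair)
    spikes a fraction of subjects to a rule-failing post value so that the
    responder rate equals the target in expectation - used to force gate
    failures.  ``rit_post_gm_ratio`` multiplies the MMR-RIT arm's post GM,
    for simulations at a non-unit true ratio.
    """

    pre_gm: float
    pre_log10_sd: float
    post_gm: float
    post_log10_sd: float
    pre_post_correlation: float = 0.5
    response_rate_override: float | tuple[float, float] | None = None
    rit_post_gm_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.pre_post_correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        if min(self.pre_gm, self.post_gm, self.rit_post_gm_ratio) <= 0:
            raise ValueError("geometric means and ratio multipliers must be positive")
        if min(self.pre_log10_sd, self.post_log10_sd) < 0:
            raise ValueError("log10 SDs must be nonnegative")


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    sub_cohort_sizes: dict[int, int] = field(
        default_factory=lambda: {1: 1100, 2: 1099, 3: 1808}
    )
    randomization_weights: tuple[int, int, int] = (6, 1, 1)
    antigens: dict[str, AntigenSim] = field(default_factory=dict)
    atp_attrition: float = 0.10
    countries: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            1: {"USA": 1.0},
            2: {"USA": 0.52, "KOR": 0.20, "TWN": 0.28},
            3: {"USA": 0.56, "KOR": 0.08, "TWN": 0.36},
        }
    )
    #: category -> (P(event | MMR-RIT), P(event | MMR II))
    ae_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "pain": (0.406, 0.408),
            "redness": (0.15, 0.15),
            "swelling": (0.10, 0.10),
            "fever": (0.22, 0.22),
            "fever_d5_12": (0.048, 0.034),
            "any_rash": (0.083, 0.104),
            "measles_rubella_like_rash": (0.019, 0.019),
            "varicella_like_rash": (0.005, 0.011),
            "parotid_swelling": (0.001, 0.002),
            "febrile_convulsion_headache": (0.001, 0.003),
            "drowsiness": (0.27, 0.27),
            "loss_of_appetite": (0.22, 0.22),
            "unsolicited": (0.344, 0.302),
            "SAE": (0.005, 0.003),
            "NOCD": (0.010, 0.013),
        }
    )
    ae_grade3_frac: float = 0.04
    pre_missing_rate: float = 0.01
    post_missing_rate: float = 0.005

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.randomization_weights):
            raise ValueError("randomization weights must be positive")
        if not 0.0 <= self.atp_attrition < 1.0:
            raise ValueError("attrition must lie in [0, 1)")
        for cat, (p1, p2) in self.ae_rates.items():
            if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
                raise ValueError(f"AE probabilities for {cat} outside [0, 1]")


def default_config(seed: int = 0) -> SyntheticConfig:
    """Configuration calibrated to the trial's published summary statistics.

    Pre-vaccination GMs sit inside the printed between-group ranges
    (anti-measles 2729.6-3644.1 mIU/mL, anti-mumps 49.6-60.7 EU/mL,
    anti-rubella 45.1-61.5 IU/mL); post-vaccination GMs equal the printed
    sub-cohort-1 Day-42 values; the true between-arm ratio is 1 and the true
    response probabilities sit near the ceiling, as observed.  Log10 SDs and
    the pre/post correlation of 0.5 are serology conventions - the trial
    published only geometric means.
    """
    a = {
        "measles": AntigenSim(3000.0, 0.30, 4285.0, 0.25),
        "mumps": AntigenSim(55.0, 0.30, 171.3, 0.25),
        "rubella": AntigenSim(52.0, 0.30, 97.1, 0.25),
        "VZV": AntigenSim(150.0, 0.30, 879.7, 0.30),
        "DT": AntigenSim(0.35, 0.25, 6.0, 0.25),
        "TT": AntigenSim(0.80, 0.25, 8.0, 0.25),
        "PT": AntigenSim(8.0, 0.25, 76.1, 0.25),
        "FHA": AntigenSim(25.0, 0.25, 313.7, 0.25),
        "PRN": AntigenSim(30.0, 0.25, 399.9, 0.25),
        "PV1": AntigenSim(150.0, 0.35, 1636.5, 0.35),
        "PV2": AntigenSim(200.0, 0.35, 2032.7, 0.35),
        "PV3": AntigenSim(250.0, 0.35, 2794.4, 0.35),
    }
    return SyntheticConfig(seed=seed, antigens=a)


def config_from_yaml(path, seed: int | None = None) -> SyntheticConfig:
    """Load a generator configuration from YAML, starting from the defaults.

    Top-level keys override :func:`default_config` fields; ``antigens``
    entries override or extend the default panel parameters.  ``seed``
    (argument) takes precedence over the file.
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    base = default_config(seed=raw.get("seed", 0))
    antigens = dict(base.antigens)
    for name, params in (raw.get("antigens") or {}).items():
        defaults = antigens.get(name)
        merged = {
            "pre_gm": defaults.pre_gm if defaults else None,
            "pre_log10_sd": defaults.pre_log10_sd if defaults else None,
            "post_gm": defaults.post_gm if defaults else None,
            "post_log10_sd": defaults.post_log10_sd if defaults else None,
            "pre_post_correlation": defaults.pre_post_correlation if defaults else 0.5,
            "response_rate_override": defaults.response_rate_override if defaults else None,
            "rit_post_gm_ratio": defaults.rit_post_gm_ratio if defaults else 1.0,
        }
        merged.update(params)
        ov = merged["response_rate_override"]
        if isinstance(ov, list):
            merged["response_rate_override"] = tuple(ov)
        antigens[name] = AntigenSim(**merged)
    kwargs = dict(
        seed=base.seed,
        antigens=antigens,
        sub_cohort_sizes={int(k): int(v) for k, v in raw.get("sub_cohort_sizes", base.sub_cohort_sizes).items()},
        randomization_weights=tuple(raw.get("randomization_weights", base.randomization_weights)),
        atp_attrition=float(raw.get("atp_attrition", base.atp_attrition)),
        ae_grade3_frac=float(raw.get("ae_grade3_frac", base.ae_grade3_frac)),
        pre_missing_rate=float(raw.get("pre_missing_rate", base.pre_missing_rate)),
        post_missing_rate=float(raw.get("post_missing_rate", base.post_missing_rate)),
    )
    if "countries" in raw:
        kwargs["countries"] = {int(k): dict(v) for k, v in raw["countries"].items()}
    if "ae_rates" in raw:
        kwargs["ae_rates"] = {k: tuple(v) for k, v in raw["ae_rates"].items()}
    cfg = SyntheticConfig(**kwargs)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg


def _blocked_arms(n: int, weights: tuple[int, int, int], rng: np.random.Generator) -> list[Arm]:
    """Permuted-block assignment (block size = sum of weights)."""
    block = (
        [Arm.MMR_RIT] * weights[0]
        + [Arm.MMR_II_LOT1] * weights[1]
        + [Arm.MMR_II_LOT2] * weights[2]
    )
    arms: list[Arm] = []
    while len(arms) < n:
        b = list(block)
        rng.shuffle(b)
        arms.extend(b)
    return arms[:n]


def _failing_post(pre: float, spec: AntigenSpec) -> float:
    """A positive post-vaccination value guaranteed to fail the response rule."""
    if spec.rule_kind is RuleKind.SERORESPONSE:
        return spec.seroresponse_threshold / 2.0
    # every booster tier requires post >= 2*pre or an absolute floor > pre
    return max(min(0.9 * pre, 0.05), 1e-6)


def generate_trial(
    config: SyntheticConfig, schema: Sequence[AntigenSpec] | None = None
) -> list[SubjectRecord]:
    """Draw one complete synthetic trial, fully reproducible from the seed."""
    if schema is None:
        schema = default_antigen_panel()
    spec_by_name = {s.name: s for s in schema}
    for sc, names in ANTIGENS_BY_SUBCOHORT.items():
        for name in names:
            if name not in spec_by_name:
                raise ValueError(f"sub-cohort {sc} antigen {name!r} missing from schema")
            if name not in config.antigens:
                raise ValueError(f"antigen {name!r} in schema but not in config.antigens")

    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    sid = 0
    for sc in sorted(config.sub_cohort_sizes):
        n = config.sub_cohort_sizes[sc]
        arms = _blocked_arms(n, config.randomization_weights, rng)
        cdict = config.countries.get(sc, {"USA": 1.0})
        cnames = list(cdict)
        cw = np.array([cdict[c] for c in cnames], dtype=float)
        countries = rng.choice(cnames, size=n, p=cw / cw.sum())
        age_mu, age_sd = (4.1, 0.3) if sc == 1 else (4.4, 0.6)
        ages = np.clip(rng.normal(age_mu, age_sd, size=n), 4.0, 6.9)
        compliant = rng.random(n) >= config.atp_attrition
        is_rit = np.array([a is Arm.MMR_RIT for a in arms])

        meas: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for name in ANTIGENS_BY_SUBCOHORT[sc]:
            sim = config.antigens[name]
            s1, s2, rho = sim.pre_log10_sd, sim.post_log10_sd, sim.pre_post_correlation
            z1 = rng.standard_normal(n)
            z2 = rng.standard_normal(n)
            # explicit Cholesky factorization; exact at rho = +/-1
            log_pre = np.log10(sim.pre_gm) + s1 * z1
            log_post = np.log10(sim.post_gm) + s2 * (rho * z1 + np.sqrt(1.0 - rho * rho) * z2)
            pre = 10.0**log_pre
            post = 10.0**log_post
            if sim.rit_post_gm_ratio != 1.0:
                post = np.where(is_rit, post * sim.rit_post_gm_ratio, post)
            if sim.response_rate_override is not None:
                ov = sim.response_rate_override
                target = np.where(is_rit, ov[0], ov[1]) if isinstance(ov, tuple) else np.full(n, ov)
                spike = rng.random(n) >= target
                fail = np.array([_failing_post(p, spec_by_name[name]) for p in pre])
                post = np.where(spike, fail, post)
            pre_miss = rng.random(n) < config.pre_missing_rate
            post_miss = rng.random(n) < config.post_missing_rate
            meas[name] = (pre, post, pre_miss, post_miss)

        ae_cats = [
            c for c in config.ae_rates if sc == 1 or c not in _SUBCOHORT1_ONLY
        ]
        ae_draws = {}
        for cat in ae_cats:
            p1, p2 = config.ae_rates[cat]
            p = np.where(is_rit, p1, p2)
            event = rng.random(n) < p
            g3 = event & (rng.random(n) < config.ae_grade3_frac)
            ae_draws[cat] = (event, g3)

        for i in range(n):
            m: dict[str, tuple[float | None, float | None]] = {}
            for name in ANTIGENS_BY_SUBCOHORT[sc]:
                pre, post, pre_miss, post_miss = meas[name]
                pv = None if pre_miss[i] else float(pre[i])
                qv = None if post_miss[i] else float(post[i])
                if pv is not None or qv is not None:
                    m[name] = (pv, qv)
            aes = [
                AeRecord(category=cat, grade3=bool(ae_draws[cat][1][i]), window=AE_WINDOWS[cat])
                for cat in ae_cats
                if ae_draws[cat][0][i]
            ]
            records.append(
                SubjectRecord(
                    subject_id=f"S{sc}-{sid:05d}",
                    sub_cohort=sc,
                    arm=arms[i],
                    country=str(countries[i]),
                    age_years=round(float(ages[i]), 2),
                    vaccinated=True,
                    eligible=True,
                    protocol_compliant=bool(compliant[i]),
                    measurements=m,
                    ae_records=aes,
                )
            )
            sid += 1
    return records
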