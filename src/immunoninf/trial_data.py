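"""Domain types, delimited-file I/O and analysis-cohort construction.

A trial is held as a list of :class:`SubjectRecord`.  Subjects carry the
randomized arm (MMR-RIT, or one of two MMR II lots that are pooled for
analysis), the sub-cohort (1 = MMR + DTaP-IPV + varicella co-administration,
2 = MMR alone with immunogenicity sampling, 3 = MMR alone, safety follow-up
only), eligibility/compliance flags, per-antigen pre- and post-vaccination
antibody concentrations, and adverse-event records.

The on-disk dialect is a UTF-8 CSV, one row per subject, wide format with
``<antigen>_pre`` / ``<antigen>_post`` concentration columns and
``ae_<category>`` / ``ae_<category>_g3`` 0/1 adverse-event flags.  Empty
concentration cells are missing values, not zeros.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Arm",
    "RuleKind",
    "CohortLabel",
    "AntigenSpec",
    "AeRecord",
    "SubjectRecord",
    "MMR_COMPONENTS",
    "default_antigen_panel",
    "schema_from_yaml",
    "read_subjects",
    "write_subjects",
    "select_cohort",
    "pool_arms",
]

#: The three MMR vaccine components; ATP-cohort membership requires a
#: post-vaccination result for at least one of them.
MMR_COMPONENTS = ("measles", "mumps", "rubella")


class Arm(str, enum.Enum):
    """Randomized vaccine group. Lots are pooled to MMR_II for analysis."""

    MMR_RIT = "MMR_RIT"
    MMR_II_LOT1 = "MMR_II_lot1"
    MMR_II_LOT2 = "MMR_II_lot2"
    MMR_II = "MMR_II"


class RuleKind(str, enum.Enum):
    """Which response-classification rule applies to an antigen."""

    SERORESPONSE = "seroresponse"
    BOOSTER_PERTUSSIS = "booster_pertussis"
    BOOSTER_DTT = "booster_dtt"
    TITER_ONLY = "titer_only"


class CohortLabel(str, enum.Enum):
    """Analysis cohort: total vaccinated, or according-to-protocol."""

    TVC = "TVC"
    ATP_IMMUNOGENICITY = "ATP_immunogenicity"


@dataclass(frozen=True)
class AntigenSpec:
    """Assay metadata and classification thresholds for one antigen.

    Parameters
    ----------
    name:
        Antigen label, e.g. ``"measles"`` or ``"PT"`` (pertussis toxoid).
    unit:
        Concentration/titer unit as reported by the assay.
    seroresponse_threshold:
        Absolute post-vaccination concentration defining seroresponse
        (required when ``rule_kind`` is seroresponse).
    assay_cutoff:
        Lower limit of quantitation anchoring the tiered booster rule
        (required when ``rule_kind`` is booster_pertussis).
    rule_kind:
        Which classification rule applies.
    """

    name: str
    unit: str
    rule_kind: RuleKind
    seroresponse_threshold: float | None = None
    assay_cutoff: float | None = None

    def __post_init__(self) -> None:
        for label, v in (
            ("seroresponse_threshold", self.seroresponse_threshold),
            ("assay_cutoff", self.assay_cutoff),
        ):
            if v is not None and v <= 0:
                raise ValueError(f"{self.name}: {label} must be positive, got {v}")
        if self.rule_kind is RuleKind.SERORESPONSE and self.seroresponse_threshold is None:
            raise ValueError(f"{self.name}: seroresponse rule requires a threshold")
        if self.rule_kind is RuleKind.BOOSTER_PERTUSSIS and self.assay_cutoff is None:
            raise ValueError(f"{self.name}: pertussis booster rule requires an assay cut-off")


@dataclass(frozen=True)
class AeRecord:
    """One adverse-event report: solicited/unsolicited category, intensity."""

    category: str
    grade3: bool = False
    window: str = "d0_42"


@dataclass
class SubjectRecord:
    """One enrolled child."""

    subject_id: str
    sub_cohort: int
    arm: Arm
    country: str
    age_years: float
    vaccinated: bool
    eligible: bool
    protocol_compliant: bool
    #: antigen name -> (pre-vaccination conc, post-vaccination conc); None = missing
    measurements: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    ae_records: list[AeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sub_cohort not in (1, 2, 3):
            raise ValueError(f"{self.subject_id}: sub_cohort must be 1, 2 or 3")
        for antigen, (pre, post) in self.measurements.items():
            for label, v in (("pre", pre), ("post", post)):
                if v is not None and v < 0:
                    raise ValueError(
                        f"{self.subject_id}: negative {antigen} {label} concentration {v}"
                    )


def default_antigen_panel() -> list[AntigenSpec]:
    """The full assay panel of the second-dose MMR co-administration trial.

    Seroresponse thresholds: anti-measles >=200 mIU/mL, anti-mumps >=10 EU/mL,
    anti-rubella >=10 IU/mL, anti-VZV >=75 mIU/mL.  Pertussis booster tiers
    anchor on assay cut-offs 2.693 (PT), 2.046 (FHA) and 2.187 (PRN) IU/mL.
    DT/TT boosters use the 0.1 IU/mL seroprotection threshold and the
    0.4 IU/mL response floor, which live in :mod:`immunoninf.response_rules`.
    Polio antibodies (micro-neutralization ED50 titers) enter only the
    geometric-mean-titer endpoints.
    """
    S, BP, BD, T = (
        RuleKind.SERORESPONSE,
        RuleKind.BOOSTER_PERTUSSIS,
        RuleKind.BOOSTER_DTT,
        RuleKind.TITER_ONLY,
    )
    return [
        AntigenSpec("measles", "mIU/mL", S, seroresponse_threshold=200.0),
        AntigenSpec("mumps", "EU/mL", S, seroresponse_threshold=10.0),
        AntigenSpec("rubella", "IU/mL", S, seroresponse_threshold=10.0),
        AntigenSpec("VZV", "mIU/mL", S, seroresponse_threshold=75.0),
        AntigenSpec("DT", "IU/mL", BD),
        AntigenSpec("TT", "IU/mL", BD),
        AntigenSpec("PT", "IU/mL", BP, assay_cutoff=2.693),
        AntigenSpec("FHA", "IU/mL", BP, assay_cutoff=2.046),
        AntigenSpec("PRN", "IU/mL", BP, assay_cutoff=2.187),
        AntigenSpec("PV1", "ED50", T),
        AntigenSpec("PV2", "ED50", T),
        AntigenSpec("PV3", "ED50", T),
    ]


def schema_from_yaml(path: str | Path) -> list[AntigenSpec]:
    """Load an antigen panel from a YAML file (list of spec mappings)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for entry in raw:
        specs.append(
            AntigenSpec(
                name=entry["name"],
                unit=entry["unit"],
                rule_kind=RuleKind(entry["rule_kind"]),
                seroresponse_threshold=entry.get("seroresponse_threshold"),
                assay_cutoff=entry.get("assay_cutoff"),
            )
        )
    return specs


_BASE_COLUMNS = [
    "subject_id",
    "sub_cohort",
    "arm",
    "country",
    "age_years",
    "vaccinated",
    "eligible",
    "protocol_compliant",
]


def _ae_columns(categories: Sequence[str]) -> list[str]:
    cols = []
    for c in categories:
        cols.append(f"ae_{c}")
        cols.append(f"ae_{c}_g3")
    return cols


def read_subjects(path: str | Path, schema: Sequence[AntigenSpec]) -> list[SubjectRecord]:
    """Read a subjects CSV into validated :class:`SubjectRecord` objects.

    Blank concentration cells become ``None``.  Lot-level arms are preserved;
    pooling is a separate, explicit step (:func:`pool_arms`).

    Raises
    ------
    ValueError
        On an unknown antigen column, or a malformed/invalid row (the error
        message names the row and field).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subjects file {path} lacks required columns: {missing}")
    known = {s.name for s in schema}
    for col in df.columns:
        if col.endswith("_pre") or col.endswith("_post"):
            antigen = col.rsplit("_", 1)[0]
            if antigen not in known:
                raise ValueError(f"unknown antigen column {col!r} (not in schema)")

    records: list[SubjectRecord] = []
    for idx, row in df.iterrows():
        try:
            measurements: dict[str, tuple[float | None, float | None]] = {}
            for spec in schema:
                pre_col, post_col = f"{spec.name}_pre", f"{spec.name}_post"
                if pre_col not in df.columns and post_col not in df.columns:
                    continue
                pre = _cell_to_conc(row.get(pre_col), idx, pre_col)
                post = _cell_to_conc(row.get(post_col), idx, post_col)
                if pre is not None or post is not None:
                    measurements[spec.name] = (pre, post)
            aes = []
            for col in df.columns:
                if col.startswith("ae_") and not col.endswith("_g3"):
                    if _truthy(row[col]):
                        cat = col[3:]
                        g3col = f"{col}_g3"
                        g3 = g3col in df.columns and _truthy(row[g3col])
                        aes.append(AeRecord(category=cat, grade3=g3))
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    sub_cohort=int(row["sub_cohort"]),
                    arm=Arm(row["arm"]),
                    country=str(row["country"]),
                    age_years=float(row["age_years"]),
                    vaccinated=_truthy(row["vaccinated"]),
                    eligible=_truthy(row["eligible"]),
                    protocol_compliant=_truthy(row["protocol_compliant"]),
                    measurements=measurements,
                    ae_records=aes,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
    return records


def _truthy(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(int(v))


def _cell_to_conc(v, row_idx, col) -> float | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or (isinstance(v, str) and not v.strip()):
        return None
    x = float(v)
    if x < 0:
        raise ValueError(f"negative concentration in column {col!r}: {x}")
    return x


def write_subjects(
    records: Iterable[SubjectRecord],
    path: str | Path,
    schema: Sequence[AntigenSpec],
    header_comment: str | None = None,
) -> None:
    """Write subjects to the CSV dialect read by :func:`read_subjects`."""
    records = list(records)
    antigen_names = [s.name for s in schema]
    ae_cats = sorted({ae.category for r in records for ae in r.ae_records})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subject_id": r.subject_id,
            "sub_cohort": r.sub_cohort,
            "arm": r.arm.value,
            "country": r.country,
            "age_years": r.age_years,
            "vaccinated": int(r.vaccinated),
            "eligible": int(r.eligible),
            "protocol_compliant": int(r.protocol_compliant),
        }
        for name in antigen_names:
            pre, post = r.measurements.get(name, (None, None))
            row[f"{name}_pre"] = pre
            row[f"{name}_post"] = post
        got = {ae.category: ae for ae in r.ae_records}
        for c in ae_cats:
            row[f"ae_{c}"] = int(c in got)
            row[f"ae_{c}_g3"] = int(c in got and got[c].grade3)
        rows.append(row)
    cols = _BASE_COLUMNS + [f"{n}_{s}" for n in antigen_names for s in ("pre", "post")]
    cols += _ae_columns(ae_cats)
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def select_cohort(records: Sequence[SubjectRecord], label: CohortLabel) -> list[SubjectRecord]:
    """Filter subjects into an analysis cohort, preserving input order.

    TVC (total vaccinated cohort): every subject with a documented vaccine
    administration.  ATP (according-to-protocol for immunogenicity): also
    eligible, protocol-compliant, and with a post-vaccination result for at
    least one of the three MMR components.
    """
    if label is CohortLabel.TVC:
        return [r for r in records if r.vaccinated]
    out = []
    for r in records:
        if not (r.vaccinated and r.eligible and r.protocol_compliant):
            continue
        has_mmr_post = any(
            r.measurements.get(a, (None, None))[1] is not None for a in MMR_COMPONENTS
        )
        if has_mmr_post:
            out.append(r)
    return out


def pool_arms(records: Sequence[SubjectRecord]) -> list[SubjectRecord]:
    """Map the two MMR II lot arms to the pooled MMR_II analysis group."""
    pooled = []
    for r in records:
        if r.arm in (Arm.MMR_II_LOT1, Arm.MMR_II_LOT2):
            pooled.append(replace(r, arm=Arm.MMR_II))
        else:
            pooled.append(r)
    return pooled
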