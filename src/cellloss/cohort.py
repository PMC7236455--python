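"""Cohort data model and CSV input/output.

A cohort is a wide, one-row-per-patient table: serum thymidine kinase 1
(sTK1, ng/ml) at up to three timepoints, tumour size (largest diameter in
cm and/or sphere-equivalent volume in cm^3) at baseline and between the
2nd and 3rd treatment cycle, the pathologic outcome at surgery, and a set
of baseline covariates.  All downstream stages consume this table.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "Timepoint",
    "Outcome",
    "Covariates",
    "PatientRecord",
    "CohortTable",
    "Finding",
    "CohortSchemaError",
    "CohortValidationError",
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]


class Timepoint(enum.IntEnum):
    """Sampling timepoints, in chronological order."""

    BASELINE = 0
    PRE_CYCLE2 = 1
    POST_CYCLE2_48H = 2
    SURGERY = 3


class Outcome(str, enum.Enum):
    """Pathologic status of the breast at surgery.

    pCR is absence of invasive cancer (residual DCIS permitted); residual
    tumours are classed by size into pT1-pT3.  Nodal status is not part of
    this definition.
    """

    PCR = "pCR"
    PT1 = "pT1"
    PT2 = "pT2"
    PT3 = "pT3"


@dataclass
class Covariates:
    age: float | None = None
    menopause: str | None = None  # "pre" | "post"
    stage: int | None = None  # 1 | 2 | 3
    histology: str | None = None  # ductal | lobular | other | not_done
    subtype: str | None = None  # basal | lumA | lumB
    er_positive: bool | None = None
    pr_positive: bool | None = None
    ki67_percent: float | None = None
    node_positive: bool | None = None


@dataclass
class PatientRecord:
    """One patient's timepointed measurements, outcome and covariates.

    ``stk1`` maps timepoints to serum TK1 concentrations (ng/ml).
    ``tumour_diameter`` / ``tumour_volume`` hold the largest diameter (cm)
    and sphere-equivalent volume (cm^3); the measurement taken between the
    2nd and 3rd cycle is stored under ``POST_CYCLE2_48H``.  ``residual_volume``
    is the pathologic tumour volume at surgery (0 iff pCR).
    """

    patient_id: str
    stk1: dict[Timepoint, float] = field(default_factory=dict)
    tumour_diameter: dict[Timepoint, float] = field(default_factory=dict)
    tumour_volume: dict[Timepoint, float] = field(default_factory=dict)
    outcome: Outcome | None = None
    residual_volume: float | None = None
    covariates: Covariates = field(default_factory=Covariates)

    def has_pre_cycle2(self) -> bool:
        return Timepoint.PRE_CYCLE2 in self.stk1


@dataclass
class CohortTable:
    """Ordered collection of patient records with a provenance tag."""

    records: list[PatientRecord]
    provenance: str = ""
    seed: int | None = None
    # latent quartile labels, present only on generator output
    latent_quartiles: dict[str, int] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.patient_id for r in self.records]


@dataclass
class Finding:
    """One validation finding; serialized as a JSON line."""

    patient_id: str
    field: str
    message: str
    severity: str = "error"  # "error" | "warning"

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient_id": self.patient_id,
                "field": self.field,
                "message": self.message,
                "severity": self.severity,
            }
        )


class CohortSchemaError(ValueError):
    """Raised when the CSV header does not match the documented schema."""


class CohortValidationError(ValueError):
    """Raised in strict mode when a record violates a hard invariant."""


# Documented wide CSV schema, in column order.
COHORT_COLUMNS = [
    "patient_id",
    "stk1_baseline",
    "stk1_pre_cycle2",
    "stk1_post_cycle2_48h",
    "diam_baseline_cm",
    "diam_intercycle_cm",
    "vol_baseline_cm3",
    "vol_intercycle_cm3",
    "outcome",
    "residual_volume_cm3",
    "age",
    "menopause",
    "stage",
    "histology",
    "subtype",
    "er_positive",
    "pr_positive",
    "ki67_percent",
    "node_positive",
]

_REQUIRED_COLUMNS = ["patient_id", "stk1_baseline", "outcome"]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
    return float(value)


def _opt_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if not s:
        return None
    try:
        return _BOOL_MAP[s]
    except KeyError:
        raise CohortValidationError(f"cannot parse boolean value {value!r}")


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_cohort(path: str | Path, strict: bool = True) -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    Row order is preserved; empty fields become absent values.  With
    ``strict=True`` (default) hard invariant violations raise
    :class:`CohortValidationError`; warnings never raise.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(
            f"cohort CSV {path} is missing required column(s): {', '.join(missing)}"
        )

    records: list[PatientRecord] = []
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        stk1 = {}
        for tp, col in [
            (Timepoint.BASELINE, "stk1_baseline"),
            (Timepoint.PRE_CYCLE2, "stk1_pre_cycle2"),
            (Timepoint.POST_CYCLE2_48H, "stk1_post_cycle2_48h"),
        ]:
            v = _opt_float(getattr(row, col))
            if v is not None:
                stk1[tp] = v
        diam = {}
        for tp, col in [
            (Timepoint.BASELINE, "diam_baseline_cm"),
            (Timepoint.POST_CYCLE2_48H, "diam_intercycle_cm"),
        ]:
            v = _opt_float(getattr(row, col))
            if v is not None:
                diam[tp] = v
        vol = {}
        for tp, col in [
            (Timepoint.BASELINE, "vol_baseline_cm3"),
            (Timepoint.POST_CYCLE2_48H, "vol_intercycle_cm3"),
        ]:
            v = _opt_float(getattr(row, col))
            if v is not None:
                vol[tp] = v
        outcome_s = _opt_str(row.outcome)
        outcome = Outcome(outcome_s) if outcome_s is not None else None
        stage = _opt_float(row.stage)
        records.append(
            PatientRecord(
                patient_id=pid,
                stk1=stk1,
                tumour_diameter=diam,
                tumour_volume=vol,
                outcome=outcome,
                residual_volume=_opt_float(row.residual_volume_cm3),
                covariates=Covariates(
                    age=_opt_float(row.age),
                    menopause=_opt_str(row.menopause),
                    stage=int(stage) if stage is not None else None,
                    histology=_opt_str(row.histology),
                    subtype=_opt_str(row.subtype),
                    er_positive=_opt_bool(row.er_positive),
                    pr_positive=_opt_bool(row.pr_positive),
                    ki67_percent=_opt_float(row.ki67_percent),
                    node_positive=_opt_bool(row.node_positive),
                ),
            )
        )

    cohort = CohortTable(records=records, provenance=str(path))
    if strict:
        errors = [f for f in validate_cohort(cohort) if f.severity == "error"]
        if errors:
            raise CohortValidationError(
                "; ".join(f"{f.patient_id}/{f.field}: {f.message}" for f in errors[:10])
            )
    return cohort


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the cohort as CSV with the documented column order.

    Missing values are written as empty fields; floats use ``repr`` so that
    a write/read/write cycle is byte-identical.
    """
    rows = []
    for r in cohort:
        c = r.covariates
        rows.append(
            {
                "patient_id": r.patient_id,
                "stk1_baseline": _fmt(r.stk1.get(Timepoint.BASELINE)),
                "stk1_pre_cycle2": _fmt(r.stk1.get(Timepoint.PRE_CYCLE2)),
                "stk1_post_cycle2_48h": _fmt(r.stk1.get(Timepoint.POST_CYCLE2_48H)),
                "diam_baseline_cm": _fmt(r.tumour_diameter.get(Timepoint.BASELINE)),
                "diam_intercycle_cm": _fmt(r.tumour_diameter.get(Timepoint.POST_CYCLE2_48H)),
                "vol_baseline_cm3": _fmt(r.tumour_volume.get(Timepoint.BASELINE)),
                "vol_intercycle_cm3": _fmt(r.tumour_volume.get(Timepoint.POST_CYCLE2_48H)),
                "outcome": r.outcome.value if r.outcome is not None else "",
                "residual_volume_cm3": _fmt(r.residual_volume),
                "age": _fmt(c.age),
                "menopause": _fmt(c.menopause),
                "stage": _fmt(c.stage),
                "histology": _fmt(c.histology),
                "subtype": _fmt(c.subtype),
                "er_positive": _fmt(c.er_positive),
                "pr_positive": _fmt(c.pr_positive),
                "ki67_percent": _fmt(c.ki67_percent),
                "node_positive": _fmt(c.node_positive),
            }
        )
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def validate_cohort(cohort: CohortTable) -> list[Finding]:
    """Check every record against the cohort invariants.

    Returns a (possibly empty) list of findings and never raises: hard
    violations get severity ``error``, soft inconsistencies (diameter vs
    volume off by more than 1% under the sphere formula) get ``warning``.
    """
    from .metric import sphere_volume  # local import to avoid cycle

    findings: list[Finding] = []
    seen: set[str] = set()
    for r in cohort:
        pid = r.patient_id
        if pid in seen:
            findings.append(Finding(pid, "patient_id", "duplicate patient_id"))
        seen.add(pid)

        if Timepoint.BASELINE not in r.stk1:
            findings.append(Finding(pid, "stk1_baseline", "baseline sTK1 is required"))
        if (
            Timepoint.BASELINE not in r.tumour_volume
            and Timepoint.BASELINE not in r.tumour_diameter
        ):
            findings.append(
                Finding(pid, "vol_baseline_cm3", "baseline volume or diameter is required")
            )
        for tp, v in r.stk1.items():
            if v < 0:
                findings.append(
                    Finding(pid, f"stk1_{tp.name.lower()}", f"negative concentration {v}")
                )
        for label, mapping in [("vol", r.tumour_volume), ("diam", r.tumour_diameter)]:
            for tp, v in mapping.items():
                if v <= 0:
                    findings.append(
                        Finding(pid, f"{label}_{tp.name.lower()}", f"non-positive value {v}")
                    )
        if r.residual_volume is not None and r.residual_volume < 0:
            findings.append(
                Finding(pid, "residual_volume_cm3", f"negative volume {r.residual_volume}")
            )
        if r.outcome is not None and r.residual_volume is not None:
            if r.outcome is Outcome.PCR and r.residual_volume != 0:
                findings.append(
                    Finding(
                        pid,
                        "residual_volume_cm3",
                        f"pCR requires residual volume 0, got {r.residual_volume}",
                    )
                )
            if r.outcome is not Outcome.PCR and r.residual_volume == 0:
                findings.append(
                    Finding(pid, "residual_volume_cm3", "residual volume 0 requires pCR")
                )
        ki = r.covariates.ki67_percent
        if ki is not None and not (0 <= ki <= 100):
            findings.append(Finding(pid, "ki67_percent", f"out of range value {ki}"))
        # diameter/volume cross-check under the sphere formula
        for tp in (Timepoint.BASELINE, Timepoint.POST_CYCLE2_48H):
            d = r.tumour_diameter.get(tp)
            v = r.tumour_volume.get(tp)
            if d is not None and v is not None and d > 0 and v > 0:
                expected = sphere_volume(d)
                if abs(v - expected) > 0.01 * expected:
                    findings.append(
                        Finding(
                            pid,
                            f"vol_{tp.name.lower()}",
                            f"volume {v} inconsistent with diameter {d} "
                            f"(sphere formula gives {expected:.4g})",
                            severity="warning",
                        )
                    )
    return findings


def findings_to_jsonl(findings: Iterable[Finding]) -> str:
    return "\n".join(f.to_json() for f in findings)
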