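"""Patient-record domain types and bundle readers/writers.

The record schema is a minimal sufficient model of a primary-care patient
management system: demographics, a coded problem list with onset/abatement
dates, dated medication orders with dose and supply, dated laboratory
results, immunizations, and a small set of stored risk fields (cardiovascular
risk, creatinine clearance, weight). It is intentionally narrower than any
deployed PMS schema — it carries exactly the data elements the clinical rule
catalog reads.

Two on-disk representations are supported:

* ``csv_set`` — five UTF-8 CSV tables (``patients.csv``, ``conditions.csv``,
  ``medications.csv``, ``labs.csv``, ``immunizations.csv``) joined on
  ``patient_id``;
* ``json_bundle`` — a single JSON file with one nested object per patient.

All dates are ISO-8601 calendar dates. A medication order is *active* on the
half-open interval ``[start_date, end_date)`` where ``end_date`` defaults to
``start_date + days_supply``: active on the first day of supply, no longer
active on the day the supply runs out.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CONDITION_CODES",
    "ANALYTE_CODES",
    "INDICATION_CODES",
    "ConditionRecord",
    "MedicationOrder",
    "LabResult",
    "Immunization",
    "RiskFields",
    "PatientRecord",
    "Violation",
    "SchemaError",
    "ReferentialIntegrityError",
    "RowParseError",
    "validate_record",
    "validate_bundle",
    "load_bundle",
    "write_bundle",
]


# Registered clinical-concept vocabulary for the problem list. The set is an
# open enumeration: rules only ever test membership of specific codes, and
# loaders accept unregistered codes with a validation warning rather than a
# hard failure is NOT the convention here — unknown codes are violations so
# that typos in condition codes cannot silently disarm a rule.
CONDITION_CODES = frozenset(
    {
        "heart_failure",
        "parkinsons_disease",
        "dementia",
        "schizophrenia",
        "gout",
        "chronic_constipation",
        "peptic_ulcer_uncomplicated",
        "erosive_esophagitis",
        "dvt_first",
        "pe_first",
        "osteoarthritis",
        "osteoporosis",
        "diabetes",
        "copd",
        "asthma_on_preventer",
        "ischemic_heart_disease",
        "rheumatic_heart_disease",
        "tia_stroke",
        "cancer_invasive",
        "hiv",
        "transplant_recipient",
        "splenectomy",
        "pregnancy",
        "seizure_disorder",
        "rem_sleep_disorder",
        "alcohol_withdrawal",
        "severe_gad",
        "end_of_life",
        "nonmalignant_pain",
        "insomnia",
        "agitation",
        "delirium",
        "continuing_vte_risk",
        "hypokalemia_cause_resolved",
        "bmd_stabilized",
        # documented exception to the antipsychotics-in-dementia rule:
        # non-pharmacological options failed and the patient is a risk
        "behavioral_risk_exception",
    }
)

ANALYTE_CODES = frozenset(
    {
        "serum_potassium",
        "serum_sodium",
        "serum_calcium",
        "uric_acid",
        "serum_creatinine",
        "creatinine_clearance",
        "lithium_level",
        "tsh",
        "fasting_glucose",
        "lipid_profile",
        "full_blood_count",
        "liver_function",
        "prolactin",
        "weight",
        "ecg",
        "cv_assessment",
        "bmd_scan",
    }
)

# Electrolyte/urate analytes carry numeric values in mmol/L and must be > 0.
_POSITIVE_ANALYTES = frozenset(
    {"serum_potassium", "serum_sodium", "serum_calcium", "uric_acid", "serum_creatinine"}
)

INDICATION_CODES = frozenset(
    {
        "gastroprotection",
        "insomnia",
        "agitation",
        "delirium",
        "gout_flare",
        "primary_cv_prevention",
        "behavioral_dementia",
        "nonmalignant_pain",
        "osteoarthritis",
        "gravitational_edema",
        "osteoporosis",
    }
)

SEXES = frozenset({"female", "male", "other"})

INFLUENZA_VACCINE_CODE = "influenza"


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(value)


@dataclass(frozen=True)
class ConditionRecord:
    """One coded problem-list entry with onset and optional abatement."""

    condition_code: str
    onset_date: dt.date
    abatement_date: dt.date | None = None

    def active_at(self, as_of: dt.date) -> bool:
        """True when the condition has onset on/before ``as_of`` and has not abated."""
        if self.onset_date > as_of:
            return False
        return self.abatement_date is None or self.abatement_date > as_of

    @property
    def element_id(self) -> str:
        return f"cond:{self.condition_code}:{self.onset_date.isoformat()}"


@dataclass(frozen=True)
class MedicationOrder:
    """A dated drug order.

    ``dose_amount`` is per administration in ``dose_unit`` (mg unless stated);
    daily dose is ``dose_amount * doses_per_day``. Exactly one of
    ``days_supply`` / ``end_date`` determines the supply window.
    """

    drug_code: str
    dose_amount: float
    doses_per_day: float
    start_date: dt.date
    days_supply: int | None = None
    end_date: dt.date | None = None
    dose_unit: str = "mg"
    indication_code: str | None = None
    long_acting: bool = False

    @property
    def effective_end(self) -> dt.date:
        """Exclusive end of the active interval."""
        if self.end_date is not None:
            return self.end_date
        if self.days_supply is None:
            raise ValueError(
                f"order for {self.drug_code} has neither days_supply nor end_date"
            )
        return self.start_date + dt.timedelta(days=self.days_supply)

    def active_at(self, as_of: dt.date) -> bool:
        """Membership of the half-open interval [start, end)."""
        return self.start_date <= as_of < self.effective_end

    @property
    def element_id(self) -> str:
        return f"med:{self.drug_code}:{self.start_date.isoformat()}"


@dataclass(frozen=True)
class LabResult:
    """A dated laboratory result or procedure marker.

    Panel/procedure entries (ECG, CV assessment, BMD scan, full blood count,
    liver function, lipid profile) may carry ``value=None`` with a qualitative
    ``marker`` such as ``"done"``.
    """

    analyte_code: str
    result_date: dt.date
    value: float | None = None
    unit: str | None = None
    marker: str | None = None

    @property
    def element_id(self) -> str:
        return f"lab:{self.analyte_code}:{self.result_date.isoformat()}"


@dataclass(frozen=True)
class Immunization:
    vaccine_code: str
    date: dt.date

    @property
    def element_id(self) -> str:
        return f"imm:{self.vaccine_code}:{self.date.isoformat()}"


@dataclass(frozen=True)
class RiskFields:
    """Stored risk fields consumed (never computed) by the rules."""

    cv_risk_pct: float | None = None
    crcl_ml_min: float | None = None
    weight_kg: float | None = None


@dataclass
class PatientRecord:
    patient_id: str
    birth_date: dt.date
    sex: str
    conditions: list[ConditionRecord] = field(default_factory=list)
    medications: list[MedicationOrder] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    immunizations: list[Immunization] = field(default_factory=list)
    risk_fields: RiskFields = field(default_factory=RiskFields)

    def conditions_active(self, as_of: dt.date) -> list[ConditionRecord]:
        return [c for c in self.conditions if c.active_at(as_of)]

    def has_condition(self, code: str, as_of: dt.date) -> bool:
        return any(c.condition_code == code and c.active_at(as_of) for c in self.conditions)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_record`."""

    patient_id: str
    field_name: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"[{self.patient_id}] {self.field_name}: {self.message}"


class SchemaError(ValueError):
    """A required table or column is missing from a bundle."""


class ReferentialIntegrityError(ValueError):
    """A child row references a patient_id absent from the patients table."""


class RowParseError(ValueError):
    """A row-level parse failure; carries the table and row index."""

    def __init__(self, table: str, row_index: int, message: str):
        super().__init__(f"{table} row {row_index}: {message}")
        self.table = table
        self.row_index = row_index


def validate_record(record: PatientRecord) -> list[Violation]:
    """Check every type invariant; returns violations as data, never raises.

    An empty list means the record is internally consistent: known codes,
    ordered dates, positive electrolytes, and every event dated strictly
    after birth.
    """
    v: list[Violation] = []
    pid = record.patient_id

    if record.sex not in SEXES:
        v.append(Violation(pid, "sex", f"unknown sex {record.sex!r}"))

    for c in record.conditions:
        if c.condition_code not in CONDITION_CODES:
            v.append(Violation(pid, "conditions", f"unknown condition_code {c.condition_code!r}"))
        if c.onset_date <= record.birth_date:
            v.append(
                Violation(pid, "birth_date", f"condition {c.condition_code} onset not after birth")
            )
        if c.abatement_date is not None and c.abatement_date < c.onset_date:
            v.append(
                Violation(
                    pid, "conditions", f"condition {c.condition_code} abatement before onset"
                )
            )

    for m in record.medications:
        if m.dose_amount < 0:
            v.append(Violation(pid, "medications", f"{m.drug_code} negative dose_amount"))
        if m.doses_per_day <= 0:
            v.append(Violation(pid, "medications", f"{m.drug_code} non-positive doses_per_day"))
        if m.days_supply is None and m.end_date is None:
            v.append(
                Violation(pid, "medications", f"{m.drug_code} has neither days_supply nor end_date")
            )
            continue
        if m.days_supply is not None and m.days_supply <= 0:
            v.append(Violation(pid, "medications", f"{m.drug_code} non-positive days_supply"))
        elif m.effective_end < m.start_date:
            v.append(Violation(pid, "medications", f"{m.drug_code} ends before it starts"))
        if m.indication_code is not None and m.indication_code not in INDICATION_CODES:
            v.append(
                Violation(pid, "medications", f"unknown indication_code {m.indication_code!r}")
            )
        if m.start_date <= record.birth_date:
            v.append(Violation(pid, "birth_date", f"order {m.drug_code} starts not after birth"))

    for lab in record.labs:
        if lab.analyte_code not in ANALYTE_CODES:
            v.append(Violation(pid, "labs", f"unknown analyte_code {lab.analyte_code!r}"))
        if lab.result_date < record.birth_date:
            v.append(Violation(pid, "birth_date", f"lab {lab.analyte_code} dated before birth"))
        if lab.analyte_code in _POSITIVE_ANALYTES and lab.value is not None and lab.value <= 0:
            v.append(Violation(pid, "labs", f"{lab.analyte_code} non-positive value {lab.value}"))

    for imm in record.immunizations:
        if imm.date <= record.birth_date:
            v.append(Violation(pid, "immunizations", f"{imm.vaccine_code} dated not after birth"))

    rf = record.risk_fields
    if rf.cv_risk_pct is not None and not (0.0 <= rf.cv_risk_pct <= 100.0):
        v.append(Violation(pid, "risk_fields", f"cv_risk_pct {rf.cv_risk_pct} outside [0, 100]"))
    if rf.crcl_ml_min is not None and rf.crcl_ml_min < 0:
        v.append(Violation(pid, "risk_fields", "negative crcl_ml_min"))
    if rf.weight_kg is not None and rf.weight_kg <= 0:
        v.append(Violation(pid, "risk_fields", "non-positive weight_kg"))

    return v


def validate_bundle(records: Sequence[PatientRecord]) -> list[Violation]:
    """Per-record invariants plus bundle-level patient_id uniqueness."""
    violations: list[Violation] = []
    seen: set[str] = set()
    for r in records:
        if r.patient_id in seen:
            violations.append(Violation(r.patient_id, "patient_id", "duplicate patient_id"))
        seen.add(r.patient_id)
        violations.extend(validate_record(r))
    return violations


# --------------------------------------------------------------------------
# bundle I/O

_PATIENT_COLS = ["patient_id", "birth_date", "sex", "cv_risk_pct", "crcl_ml_min", "weight_kg"]
_CONDITION_COLS = ["patient_id", "condition_code", "onset_date", "abatement_date"]
_MEDICATION_COLS = [
    "patient_id",
    "drug_code",
    "dose_amount",
    "dose_unit",
    "doses_per_day",
    "start_date",
    "days_supply",
    "end_date",
    "indication_code",
    "long_acting",
]
_LAB_COLS = ["patient_id", "analyte_code", "result_date", "value", "unit", "marker"]
_IMMUNIZATION_COLS = ["patient_id", "vaccine_code", "date"]

_TABLES = {
    "patients": _PATIENT_COLS,
    "conditions": _CONDITION_COLS,
    "medications": _MEDICATION_COLS,
    "labs": _LAB_COLS,
    "immunizations": _IMMUNIZATION_COLS,
}


def _read_table(path: Path, table: str) -> list[dict[str, str]]:
    file = path / f"{table}.csv"
    if not file.exists():
        raise SchemaError(f"missing table {table}.csv in {path}")
    with open(file, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _TABLES[table] if c not in header]
        if missing:
            raise SchemaError(f"{table}.csv missing required column(s): {', '.join(missing)}")
        return list(reader)


def _opt_float(raw: str | None) -> float | None:
    if raw is None or raw == "":
        return None
    return float(raw)


def _opt_str(raw: str | None) -> str | None:
    return raw if raw else None


def _row_date(raw: str, table: str, idx: int, col: str) -> dt.date:
    try:
        return _parse_date(raw)
    except ValueError as exc:
        raise RowParseError(table, idx, f"unparseable date in {col}: {raw!r}") from exc


def _load_csv_set(path: Path) -> list[PatientRecord]:
    rows = {name: _read_table(path, name) for name in _TABLES}

    records: dict[str, PatientRecord] = {}
    for i, row in enumerate(rows["patients"]):
        records[row["patient_id"]] = PatientRecord(
            patient_id=row["patient_id"],
            birth_date=_row_date(row["birth_date"], "patients", i, "birth_date"),
            sex=row["sex"],
            risk_fields=RiskFields(
                cv_risk_pct=_opt_float(row.get("cv_risk_pct")),
                crcl_ml_min=_opt_float(row.get("crcl_ml_min")),
                weight_kg=_opt_float(row.get("weight_kg")),
            ),
        )

    def owner(row: dict[str, str], table: str, idx: int) -> PatientRecord:
        pid = row["patient_id"]
        if pid not in records:
            raise ReferentialIntegrityError(
                f"{table}.csv row {idx} references unknown patient_id {pid!r}"
            )
        return records[pid]

    for i, row in enumerate(rows["conditions"]):
        rec = owner(row, "conditions", i)
        abate = _opt_str(row.get("abatement_date"))
        rec.conditions.append(
            ConditionRecord(
                condition_code=row["condition_code"],
                onset_date=_row_date(row["onset_date"], "conditions", i, "onset_date"),
                abatement_date=(
                    _row_date(abate, "conditions", i, "abatement_date") if abate else None
                ),
            )
        )

    for i, row in enumerate(rows["medications"]):
        rec = owner(row, "medications", i)
        supply = _opt_str(row.get("days_supply"))
        end = _opt_str(row.get("end_date"))
        try:
            dose = float(row["dose_amount"])
            per_day = float(row["doses_per_day"])
        except ValueError as exc:
            raise RowParseError("medications", i, str(exc)) from exc
        rec.medications.append(
            MedicationOrder(
                drug_code=row["drug_code"],
                dose_amount=dose,
                doses_per_day=per_day,
                start_date=_row_date(row["start_date"], "medications", i, "start_date"),
                days_supply=int(supply) if supply else None,
                end_date=_row_date(end, "medications", i, "end_date") if end else None,
                dose_unit=row.get("dose_unit") or "mg",
                indication_code=_opt_str(row.get("indication_code")),
                long_acting=(row.get("long_acting") or "").lower() in {"1", "true", "yes"},
            )
        )

    for i, row in enumerate(rows["labs"]):
        rec = owner(row, "labs", i)
        rec.labs.append(
            LabResult(
                analyte_code=row["analyte_code"],
                result_date=_row_date(row["result_date"], "labs", i, "result_date"),
                value=_opt_float(row.get("value")),
                unit=_opt_str(row.get("unit")),
                marker=_opt_str(row.get("marker")),
            )
        )

    for i, row in enumerate(rows["immunizations"]):
        rec = owner(row, "immunizations", i)
        rec.immunizations.append(
            Immunization(
                vaccine_code=row["vaccine_code"],
                date=_row_date(row["date"], "immunizations", i, "date"),
            )
        )

    return list(records.values())


def _record_to_obj(r: PatientRecord) -> dict:
    return {
        "patient_id": r.patient_id,
        "birth_date": r.birth_date.isoformat(),
        "sex": r.sex,
        "risk_fields": {
            "cv_risk_pct": r.risk_fields.cv_risk_pct,
            "crcl_ml_min": r.risk_fields.crcl_ml_min,
            "weight_kg": r.risk_fields.weight_kg,
        },
        "conditions": [
            {
                "condition_code": c.condition_code,
                "onset_date": c.onset_date.isoformat(),
                "abatement_date": c.abatement_date.isoformat() if c.abatement_date else None,
            }
            for c in r.conditions
        ],
        "medications": [
            {
                "drug_code": m.drug_code,
                "dose_amount": m.dose_amount,
                "dose_unit": m.dose_unit,
                "doses_per_day": m.doses_per_day,
                "start_date": m.start_date.isoformat(),
                "days_supply": m.days_supply,
                "end_date": m.end_date.isoformat() if m.end_date else None,
                "indication_code": m.indication_code,
                "long_acting": m.long_acting,
            }
            for m in r.medications
        ],
        "labs": [
            {
                "analyte_code": lab.analyte_code,
                "result_date": lab.result_date.isoformat(),
                "value": lab.value,
                "unit": lab.unit,
                "marker": lab.marker,
            }
            for lab in r.labs
        ],
        "immunizations": [
            {"vaccine_code": im.vaccine_code, "date": im.date.isoformat()}
            for im in r.immunizations
        ],
    }


def _record_from_obj(obj: dict) -> PatientRecord:
    rf = obj.get("risk_fields") or {}
    return PatientRecord(
        patient_id=obj["patient_id"],
        birth_date=_parse_date(obj["birth_date"]),
        sex=obj["sex"],
        risk_fields=RiskFields(
            cv_risk_pct=rf.get("cv_risk_pct"),
            crcl_ml_min=rf.get("crcl_ml_min"),
            weight_kg=rf.get("weight_kg"),
        ),
        conditions=[
            ConditionRecord(
                condition_code=c["condition_code"],
                onset_date=_parse_date(c["onset_date"]),
                abatement_date=(
                    _parse_date(c["abatement_date"]) if c.get("abatement_date") else None
                ),
            )
            for c in obj.get("conditions", [])
        ],
        medications=[
            MedicationOrder(
                drug_code=m["drug_code"],
                dose_amount=m["dose_amount"],
                doses_per_day=m["doses_per_day"],
                start_date=_parse_date(m["start_date"]),
                days_supply=m.get("days_supply"),
                end_date=_parse_date(m["end_date"]) if m.get("end_date") else None,
                dose_unit=m.get("dose_unit", "mg"),
                indication_code=m.get("indication_code"),
                long_acting=bool(m.get("long_acting", False)),
            )
            for m in obj.get("medications", [])
        ],
        labs=[
            LabResult(
                analyte_code=lab["analyte_code"],
                result_date=_parse_date(lab["result_date"]),
                value=lab.get("value"),
                unit=lab.get("unit"),
                marker=lab.get("marker"),
            )
            for lab in obj.get("labs", [])
        ],
        immunizations=[
            Immunization(vaccine_code=im["vaccine_code"], date=_parse_date(im["date"]))
            for im in obj.get("immunizations", [])
        ],
    )


def load_bundle(path: str | Path, format: str = "csv_set") -> list[PatientRecord]:
    """Load a patient bundle from disk.

    Parameters
    ----------
    path
        Directory of the five CSV tables (``csv_set``) or the JSON file
        (``json_bundle``).
    format
        ``"csv_set"`` or ``"json_bundle"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"bundle path does not exist: {path}")
    if format == "csv_set":
        return _load_csv_set(path)
    if format == "json_bundle":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return [_record_from_obj(obj) for obj in payload["patients"]]
    raise ValueError(f"unknown bundle format {format!r}")


def write_bundle(
    records: Iterable[PatientRecord], path: str | Path, format: str = "csv_set"
) -> None:
    """Write a bundle; inverse of :func:`load_bundle` (field-level round trip)."""
    records = list(records)
    path = Path(path)
    if format == "json_bundle":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"patients": [_record_to_obj(r) for r in records]}, fh, indent=1)
        return
    if format != "csv_set":
        raise ValueError(f"unknown bundle format {format!r}")

    path.mkdir(parents=True, exist_ok=True)

    def _write(table: str, cols: list[str], rows: list[dict]) -> None:
        with open(path / f"{table}.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})

    _write(
        "patients",
        _PATIENT_COLS,
        [
            {
                "patient_id": r.patient_id,
                "birth_date": r.birth_date.isoformat(),
                "sex": r.sex,
                "cv_risk_pct": r.risk_fields.cv_risk_pct,
                "crcl_ml_min": r.risk_fields.crcl_ml_min,
                "weight_kg": r.risk_fields.weight_kg,
            }
            for r in records
        ],
    )
    _write(
        "conditions",
        _CONDITION_COLS,
        [
            {
                "patient_id": r.patient_id,
                "condition_code": c.condition_code,
                "onset_date": c.onset_date.isoformat(),
                "abatement_date": c.abatement_date.isoformat() if c.abatement_date else None,
            }
            for r in records
            for c in r.conditions
        ],
    )
    _write(
        "medications",
        _MEDICATION_COLS,
        [
            {
                "patient_id": r.patient_id,
                "drug_code": m.drug_code,
                "dose_amount": m.dose_amount,
                "dose_unit": m.dose_unit,
                "doses_per_day": m.doses_per_day,
                "start_date": m.start_date.isoformat(),
                "days_supply": m.days_supply,
                "end_date": m.end_date.isoformat() if m.end_date else None,
                "indication_code": m.indication_code,
                "long_acting": "true" if m.long_acting else "false",
            }
            for r in records
            for m in r.medications
        ],
    )
    _write(
        "labs",
        _LAB_COLS,
        [
            {
                "patient_id": r.patient_id,
                "analyte_code": lab.analyte_code,
                "result_date": lab.result_date.isoformat(),
                "value": lab.value,
                "unit": lab.unit,
                "marker": lab.marker,
            }
            for r in records
            for lab in r.labs
        ],
    )
    _write(
        "immunizations",
        _IMMUNIZATION_COLS,
        [
            {
                "patient_id": r.patient_id,
                "vaccine_code": im.vaccine_code,
                "date": im.date.isoformat(),
            }
            for r in records
            for im in r.immunizations
        ],
    )
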