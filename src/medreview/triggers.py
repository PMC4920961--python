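"""Minimal rule-trigger patients: one constructed record per catalog rule.

Each builder returns a patient engineered to fire *exactly* its rule and no
other when the full default catalog is evaluated at ``as_of``. This is the
package's validation-by-challenge fixture: a 46-patient bundle that must
yield 46 alerts, one per rule. The builders are also reused by the
synthetic-population generator to plant guaranteed rule triggers.

Isolation is deliberate and sometimes non-obvious: every patient aged 65+
or carrying an influenza-cohort condition receives a recent influenza
vaccination (else FLU-1 would co-fire), patients on ACE inhibitors or
lithium get fresh monitoring labs, and hypnotic courses are kept under four
weeks unless the rule under test needs longer.
"""

from __future__ import annotations

import datetime as dt

from dateutil.relativedelta import relativedelta

from .records import (
    ConditionRecord,
    Immunization,
    LabResult,
    MedicationOrder,
    PatientRecord,
    RiskFields,
    INFLUENZA_VACCINE_CODE,
)

__all__ = ["TRIGGER_BUILDERS", "build_trigger_patient", "build_trigger_bundle"]


def _base(
    rule_id: str,
    as_of: dt.date,
    age: int,
    sex: str = "female",
    patient_id: str | None = None,
    flu_vaccinated: bool = True,
) -> PatientRecord:
    birth = as_of - relativedelta(years=age, days=200)
    rec = PatientRecord(
        patient_id=patient_id or f"trigger-{rule_id}",
        birth_date=birth,
        sex=sex,
    )
    if flu_vaccinated:
        rec.immunizations.append(
            Immunization(INFLUENZA_VACCINE_CODE, as_of - relativedelta(months=3))
        )
    return rec


def _order(as_of, drug, *, days_ago, supply, dose=10.0, per_day=1.0, indication=None,
           long_acting=False, unit="mg"):
    return MedicationOrder(
        drug_code=drug,
        dose_amount=dose,
        doses_per_day=per_day,
        start_date=as_of - dt.timedelta(days=days_ago),
        days_supply=supply,
        dose_unit=unit,
        indication_code=indication,
        long_acting=long_acting,
    )


def _cond(as_of, code, *, months_ago=12):
    return ConditionRecord(code, as_of - relativedelta(months=months_ago))


def _lab(as_of, analyte, *, months_ago=0, days_ago=0, value=None, unit=None, marker=None):
    date = as_of - relativedelta(months=months_ago) - dt.timedelta(days=days_ago)
    return LabResult(analyte_code=analyte, result_date=date, value=value, unit=unit,
                     marker=marker)


def _fresh_renal_potassium(rec, as_of):
    rec.labs += [
        _lab(as_of, "serum_creatinine", months_ago=2, value=0.09, unit="mmol/L"),
        _lab(as_of, "serum_potassium", months_ago=2, value=4.1, unit="mmol/L"),
    ]


# -- duplicate therapy ------------------------------------------------------


def _t_dup_1(as_of):
    rec = _base("DUP-1", as_of, 52, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "famotidine", days_ago=10, supply=30, dose=20),
        _order(as_of, "omeprazole", days_ago=10, supply=30, dose=20),
    ]
    return rec


def _t_dup_2(as_of):
    rec = _base("DUP-2", as_of, 40, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "diazepam", days_ago=10, supply=14, dose=5),
        _order(as_of, "temazepam", days_ago=10, supply=14, dose=10),
    ]
    return rec


def _t_dup_3(as_of):
    rec = _base("DUP-3", as_of, 40, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "haloperidol", days_ago=10, supply=30, dose=1),
        _order(as_of, "risperidone", days_ago=10, supply=30, dose=1),
    ]
    return rec


def _t_dup_4(as_of):
    rec = _base("DUP-4", as_of, 40, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "fluoxetine", days_ago=10, supply=30, dose=20),
        _order(as_of, "sertraline", days_ago=10, supply=30, dose=50),
    ]
    return rec


# -- gastroprotectants ------------------------------------------------------


def _t_gas_1(as_of):
    rec = _base("GAS-1", as_of, 58, flu_vaccinated=False)
    rec.medications += [
        # the irritant course ended a month ago; the protective PPI lingers
        _order(as_of, "naproxen", days_ago=120, supply=90, dose=250, per_day=2),
        _order(as_of, "omeprazole", days_ago=60, supply=90, dose=20,
               indication="gastroprotection"),
    ]
    return rec


def _t_gas_2(as_of):
    rec = _base("GAS-2", as_of, 55, flu_vaccinated=False)
    rec.conditions.append(_cond(as_of, "peptic_ulcer_uncomplicated", months_ago=4))
    rec.medications.append(_order(as_of, "pantoprazole", days_ago=70, supply=90, dose=40))
    return rec


# -- constipation -----------------------------------------------------------


def _t_con_1(as_of):
    rec = _base("CON-1", as_of, 60, flu_vaccinated=False)
    rec.conditions.append(_cond(as_of, "chronic_constipation", months_ago=24))
    rec.medications.append(_order(as_of, "verapamil", days_ago=30, supply=90, dose=120))
    return rec


# -- antithrombotics --------------------------------------------------------


def _t_ant_1(as_of):
    rec = _base("ANT-1", as_of, 56, flu_vaccinated=False)
    rec.conditions.append(_cond(as_of, "dvt_first", months_ago=8))
    rec.medications.append(_order(as_of, "warfarin", days_ago=240, supply=270, dose=3))
    return rec


def _t_ant_2(as_of):
    rec = _base("ANT-2", as_of, 56, flu_vaccinated=False)
    rec.conditions.append(_cond(as_of, "pe_first", months_ago=14))
    rec.medications.append(_order(as_of, "rivaroxaban", days_ago=420, supply=450, dose=20))
    return rec


def _t_ant_3(as_of):
    rec = _base("ANT-3", as_of, 55, flu_vaccinated=False)
    rec.risk_fields = RiskFields(cv_risk_pct=12.0)
    rec.medications.append(
        _order(as_of, "aspirin", days_ago=100, supply=180, dose=100,
               indication="primary_cv_prevention")
    )
    return rec


# -- medicines in the elderly ----------------------------------------------


def _t_eld_1(as_of):
    rec = _base("ELD-1", as_of, 72)
    rec.medications.append(
        _order(as_of, "furosemide", days_ago=150, supply=180, dose=40,
               indication="gravitational_edema")
    )
    return rec


def _t_eld_2(as_of):
    rec = _base("ELD-2", as_of, 74)
    rec.conditions.append(_cond(as_of, "heart_failure", months_ago=36))
    rec.medications.append(_order(as_of, "spironolactone", days_ago=60, supply=90, dose=50))
    return rec


def _t_eld_3(as_of):
    rec = _base("ELD-3", as_of, 87)
    rec.medications.append(
        _order(as_of, "atorvastatin", days_ago=2200, supply=2400, dose=20,
               indication="primary_cv_prevention")
    )
    return rec


def _t_eld_4(as_of):
    rec = _base("ELD-4", as_of, 70)
    rec.medications.append(
        _order(as_of, "zopiclone", days_ago=10, supply=14, dose=7.5, indication="insomnia")
    )
    return rec


def _t_eld_5(as_of):
    rec = _base("ELD-5", as_of, 80)
    rec.conditions.append(_cond(as_of, "dementia", months_ago=30))
    rec.medications.append(
        _order(as_of, "risperidone", days_ago=20, supply=90, dose=0.5,
               indication="behavioral_dementia")
    )
    return rec


def _t_eld_6(as_of):
    rec = _base("ELD-6", as_of, 78)
    rec.medications.append(_order(as_of, "chlorpheniramine", days_ago=5, supply=30, dose=4))
    return rec


def _t_eld_7(as_of):
    rec = _base("ELD-7", as_of, 78)
    rec.medications.append(_order(as_of, "orphenadrine", days_ago=5, supply=30, dose=100))
    return rec


# -- psychotropics ----------------------------------------------------------


def _t_psy_1(as_of):
    rec = _base("PSY-1", as_of, 70)
    rec.conditions.append(_cond(as_of, "parkinsons_disease", months_ago=48))
    rec.medications.append(_order(as_of, "metoclopramide", days_ago=5, supply=14, dose=10))
    return rec


def _t_psy_2(as_of):
    rec = _base("PSY-2", as_of, 45, flu_vaccinated=False)
    rec.medications.append(
        _order(as_of, "citalopram", days_ago=20, supply=60, dose=30, per_day=2)
    )
    return rec


def _t_psy_3(as_of):
    rec = _base("PSY-3", as_of, 50, flu_vaccinated=False)
    rec.medications.append(_order(as_of, "diazepam", days_ago=40, supply=60, dose=5))
    return rec


# -- analgesics -------------------------------------------------------------


def _t_ana_1(as_of):
    rec = _base("ANA-1", as_of, 50, flu_vaccinated=False)
    rec.medications.append(
        _order(as_of, "morphine", days_ago=120, supply=150, dose=10, per_day=2,
               indication="nonmalignant_pain")
    )
    return rec


def _t_ana_2(as_of):
    rec = _base("ANA-2", as_of, 55, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "fentanyl_patch", days_ago=30, supply=60, dose=12, unit="mcg/h",
               long_acting=True),
        _order(as_of, "oxycodone_cr", days_ago=30, supply=60, dose=10, per_day=2,
               long_acting=True),
    ]
    return rec


def _t_ana_3(as_of):
    rec = _base("ANA-3", as_of, 48, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "codeine", days_ago=7, supply=14, dose=30, per_day=3),
        _order(as_of, "morphine", days_ago=7, supply=14, dose=10, per_day=2),
    ]
    return rec


def _t_ana_4(as_of):
    rec = _base("ANA-4", as_of, 45, flu_vaccinated=False)
    rec.medications.append(
        _order(as_of, "paracetamol_codeine", days_ago=7, supply=30, dose=500, per_day=4)
    )
    return rec


# -- NSAIDs -----------------------------------------------------------------


def _t_nsd_1(as_of):
    rec = _base("NSD-1", as_of, 78)
    rec.medications += [
        _order(as_of, "naproxen", days_ago=120, supply=150, dose=250, per_day=2,
               indication="osteoarthritis"),
        # paracetamol was tried first (keeps the paracetamol-trial rule quiet)
        _order(as_of, "paracetamol", days_ago=300, supply=60, dose=1000, per_day=3),
    ]
    return rec


def _t_nsd_2(as_of):
    rec = _base("NSD-2", as_of, 60, flu_vaccinated=False)
    rec.medications.append(
        _order(as_of, "ibuprofen", days_ago=120, supply=150, dose=400, per_day=3,
               indication="osteoarthritis")
    )
    return rec


def _t_nsd_3(as_of):
    rec = _base("NSD-3", as_of, 50, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "ibuprofen", days_ago=10, supply=30, dose=400, per_day=3),
        _order(as_of, "clopidogrel", days_ago=60, supply=90, dose=75),
    ]
    return rec


def _t_nsd_4(as_of):
    rec = _base("NSD-4", as_of, 62)
    rec.conditions.append(_cond(as_of, "heart_failure", months_ago=24))
    rec.medications.append(_order(as_of, "ibuprofen", days_ago=10, supply=30, dose=400))
    return rec


def _t_nsd_5(as_of):
    rec = _base("NSD-5", as_of, 58, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "ibuprofen", days_ago=10, supply=30, dose=400, per_day=3),
        _order(as_of, "lisinopril", days_ago=200, supply=365, dose=10),
    ]
    _fresh_renal_potassium(rec, as_of)  # keeps ACE monitoring quiet
    return rec


def _t_nsd_6(as_of):
    rec = _base("NSD-6", as_of, 50, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "ibuprofen", days_ago=10, supply=30, dose=400, per_day=3),
        _order(as_of, "diclofenac", days_ago=10, supply=30, dose=50, per_day=2),
    ]
    return rec


# -- gout -------------------------------------------------------------------


def _t_gou_1(as_of):
    rec = _base("GOU-1", as_of, 55, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "colchicine", days_ago=240, supply=7, dose=0.5, per_day=2,
               indication="gout_flare"),
        _order(as_of, "colchicine", days_ago=60, supply=7, dose=0.5, per_day=2,
               indication="gout_flare"),
    ]
    return rec


def _t_gou_2(as_of):
    rec = _base("GOU-2", as_of, 58, flu_vaccinated=False)
    rec.medications.append(_order(as_of, "allopurinol", days_ago=700, supply=800, dose=300))
    return rec


def _t_gou_3(as_of):
    rec = _base("GOU-3", as_of, 58, flu_vaccinated=False)
    rec.medications.append(_order(as_of, "allopurinol", days_ago=700, supply=800, dose=100))
    rec.labs += [
        _lab(as_of, "uric_acid", months_ago=2, value=0.45, unit="mmol/L"),
        _lab(as_of, "serum_creatinine", months_ago=2, value=0.09, unit="mmol/L"),
    ]
    return rec


# -- bisphosphonates --------------------------------------------------------


def _t_bis_1(as_of):
    rec = _base("BIS-1", as_of, 62, flu_vaccinated=False)
    rec.conditions += [
        _cond(as_of, "osteoporosis", months_ago=80),
        _cond(as_of, "bmd_stabilized", months_ago=6),
    ]
    rec.medications.append(_order(as_of, "alendronate", days_ago=2200, supply=2400, dose=70))
    return rec


def _t_bis_2(as_of):
    rec = _base("BIS-2", as_of, 58, flu_vaccinated=False)
    rec.medications.append(_order(as_of, "prednisone", days_ago=150, supply=180, dose=7.5))
    return rec


# -- metformin --------------------------------------------------------------


def _t_met_1(as_of):
    rec = _base("MET-1", as_of, 55)
    rec.conditions.append(_cond(as_of, "diabetes", months_ago=60))
    rec.risk_fields = RiskFields(crcl_ml_min=25.0)
    rec.medications.append(
        _order(as_of, "metformin", days_ago=200, supply=365, dose=500, per_day=2)
    )
    return rec


# -- influenza --------------------------------------------------------------


def _t_flu_1(as_of):
    return _base("FLU-1", as_of, 70, flu_vaccinated=False)


# -- interactions -----------------------------------------------------------


def _t_int_1(as_of):
    rec = _base("INT-1", as_of, 48, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "amitriptyline", days_ago=10, supply=30, dose=25),
        _order(as_of, "sertraline", days_ago=10, supply=30, dose=50),
    ]
    return rec


def _t_int_2(as_of):
    rec = _base("INT-2", as_of, 60, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "metoprolol", days_ago=30, supply=90, dose=47.5),
        _order(as_of, "diltiazem", days_ago=30, supply=90, dose=120),
    ]
    return rec


def _t_int_3(as_of):
    rec = _base("INT-3", as_of, 60, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "oxybutynin", days_ago=10, supply=30, dose=5, per_day=2),
        _order(as_of, "solifenacin", days_ago=10, supply=30, dose=5),
    ]
    return rec


def _t_int_4(as_of):
    rec = _base("INT-4", as_of, 62, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "amiodarone", days_ago=60, supply=90, dose=200),
        _order(as_of, "domperidone", days_ago=5, supply=14, dose=10, per_day=3),
    ]
    return rec


# -- monitoring -------------------------------------------------------------


def _t_mon_1(as_of):
    rec = _base("MON-1", as_of, 58, flu_vaccinated=False)
    rec.medications += [
        _order(as_of, "spironolactone", days_ago=100, supply=180, dose=25),
        _order(as_of, "amiloride", days_ago=100, supply=180, dose=5),
    ]
    rec.labs.append(_lab(as_of, "serum_potassium", months_ago=7, value=4.3, unit="mmol/L"))
    return rec


def _t_mon_2(as_of):
    rec = _base("MON-2", as_of, 55, flu_vaccinated=False)
    rec.conditions.append(_cond(as_of, "hypokalemia_cause_resolved", months_ago=2))
    rec.medications.append(
        _order(as_of, "potassium_chloride", days_ago=60, supply=90, dose=600, per_day=2)
    )
    rec.labs.append(_lab(as_of, "serum_potassium", months_ago=1, value=4.5, unit="mmol/L"))
    return rec


def _t_mon_3(as_of):
    rec = _base("MON-3", as_of, 45, flu_vaccinated=False)
    rec.medications.append(_order(as_of, "lithium", days_ago=365, supply=400, dose=400))
    rec.labs += [
        _lab(as_of, "lithium_level", months_ago=8, value=0.7, unit="mmol/L"),
        _lab(as_of, "tsh", months_ago=2, value=2.1),
        _lab(as_of, "serum_creatinine", months_ago=2, value=0.08, unit="mmol/L"),
        _lab(as_of, "serum_sodium", months_ago=2, value=140, unit="mmol/L"),
        _lab(as_of, "serum_calcium", months_ago=6, value=2.4, unit="mmol/L"),
        _lab(as_of, "ecg", months_ago=6, marker="done"),
    ]
    return rec


def _t_mon_4(as_of):
    rec = _base("MON-4", as_of, 60, flu_vaccinated=False)
    rec.medications.append(_order(as_of, "lisinopril", days_ago=500, supply=700, dose=10))
    rec.labs += [
        _lab(as_of, "serum_creatinine", months_ago=14, value=0.09, unit="mmol/L"),
        _lab(as_of, "serum_potassium", months_ago=14, value=4.2, unit="mmol/L"),
    ]
    return rec


def _t_mon_5(as_of):
    rec = _base("MON-5", as_of, 40, flu_vaccinated=False)
    rec.conditions.append(_cond(as_of, "schizophrenia", months_ago=120))
    rec.medications.append(_order(as_of, "olanzapine", days_ago=200, supply=365, dose=10))
    return rec


TRIGGER_BUILDERS = {
    "DUP-1": _t_dup_1, "DUP-2": _t_dup_2, "DUP-3": _t_dup_3, "DUP-4": _t_dup_4,
    "GAS-1": _t_gas_1, "GAS-2": _t_gas_2,
    "CON-1": _t_con_1,
    "ANT-1": _t_ant_1, "ANT-2": _t_ant_2, "ANT-3": _t_ant_3,
    "ELD-1": _t_eld_1, "ELD-2": _t_eld_2, "ELD-3": _t_eld_3, "ELD-4": _t_eld_4,
    "ELD-5": _t_eld_5, "ELD-6": _t_eld_6, "ELD-7": _t_eld_7,
    "PSY-1": _t_psy_1, "PSY-2": _t_psy_2, "PSY-3": _t_psy_3,
    "ANA-1": _t_ana_1, "ANA-2": _t_ana_2, "ANA-3": _t_ana_3, "ANA-4": _t_ana_4,
    "NSD-1": _t_nsd_1, "NSD-2": _t_nsd_2, "NSD-3": _t_nsd_3, "NSD-4": _t_nsd_4,
    "NSD-5": _t_nsd_5, "NSD-6": _t_nsd_6,
    "GOU-1": _t_gou_1, "GOU-2": _t_gou_2, "GOU-3": _t_gou_3,
    "BIS-1": _t_bis_1, "BIS-2": _t_bis_2,
    "MET-1": _t_met_1,
    "FLU-1": _t_flu_1,
    "INT-1": _t_int_1, "INT-2": _t_int_2, "INT-3": _t_int_3, "INT-4": _t_int_4,
    "MON-1": _t_mon_1, "MON-2": _t_mon_2, "MON-3": _t_mon_3, "MON-4": _t_mon_4,
    "MON-5": _t_mon_5,
}


def build_trigger_patient(
    rule_id: str, as_of: dt.date, patient_id: str | None = None
) -> "PatientRecord":
    """The minimal patient that fires ``rule_id`` (and only it) at ``as_of``."""
    try:
        builder = TRIGGER_BUILDERS[rule_id]
    except KeyError:
        raise KeyError(f"unknown rule_id {rule_id!r}") from None
    rec = builder(as_of)
    if patient_id is not None:
        rec.patient_id = patient_id
    return rec


def build_trigger_bundle(as_of: dt.date) -> list["PatientRecord"]:
    """One trigger patient per catalog rule, in catalog order."""
    return [build_trigger_patient(rule_id, as_of) for rule_id in TRIGGER_BUILDERS]
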