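"""Engine vs straight-line reference predicates on random synthetic patients.

Each reference predicate below re-derives its rule's decision directly from
the record with explicit, flat logic: day-set episode construction instead
of interval merging, inline Cockcroft-Gault, inline comparator boundaries.
They share nothing with the engine's generic evaluator, so agreement on a
large random population is a genuine cross-check. The default data-gap
policy (optional values absent => rule does not fire) is part of the
specification and is encoded here too.
"""

import datetime as dt

from dateutil.relativedelta import relativedelta

from medreview.formulary import default_formulary
from medreview.rule_catalog import default_ruleset
from medreview.rules_engine import evaluate_patient
from medreview.synthpop import SynthParams, generate_population

AS_OF = dt.date(2016, 6, 1)
FM = default_formulary()
GAP = 7


def _tags(m):
    return FM.classify_drug(m.drug_code)


def _active(rec, as_of=AS_OF):
    return [m for m in rec.medications if m.start_date <= as_of < m.effective_end]


def _active_tag(rec, *tags, as_of=AS_OF):
    return [m for m in _active(rec, as_of) if set(tags) & _tags(m)]


def _has_cond(rec, *codes, as_of=AS_OF):
    for c in rec.conditions:
        if c.condition_code in codes and c.onset_date <= as_of and (
            c.abatement_date is None or c.abatement_date > as_of
        ):
            return True
    return False


def _age(rec, as_of=AS_OF):
    years = as_of.year - rec.birth_date.year
    if (as_of.month, as_of.day) < (rec.birth_date.month, rec.birth_date.day):
        years -= 1
    return years


def _episode_days(rec, selectors, as_of=AS_OF):
    """Day-set reconstruction of the current continuous-use episode length."""
    if isinstance(selectors, str):
        selectors = (selectors,)
    days = set()
    for m in rec.medications:
        if set(selectors) & _tags(m):
            for i in range((m.effective_end - m.start_date).days):
                days.add(m.start_date + dt.timedelta(days=i))
    ordered = sorted(days)
    episodes = []
    for day in ordered:
        if episodes and (day - episodes[-1][-1]).days - 1 <= GAP:
            episodes[-1].append(day)
        else:
            episodes.append([day])
    for ep in episodes:
        if ep[0] <= as_of <= ep[-1] + dt.timedelta(days=GAP):
            return (as_of - ep[0]).days + 1, ep[0]
    return 0, None


def _episode_longer_than(rec, selectors, *, months=0, years=0, days=0):
    _, start = _episode_days(rec, selectors)
    if start is None:
        return False
    return start + relativedelta(years=years, months=months, days=days) < AS_OF


def _last_lab(rec, analyte, as_of=AS_OF):
    labs = [l for l in rec.labs if l.analyte_code == analyte and l.result_date <= as_of]
    return max(labs, key=lambda l: l.result_date) if labs else None


def _stale(rec, analytes, *, months=0, years=0):
    if isinstance(analytes, str):
        analytes = (analytes,)
    latest = None
    for a in analytes:
        lab = _last_lab(rec, a)
        if lab and (latest is None or lab.result_date > latest):
            latest = lab.result_date
    if latest is None:
        return True
    return latest + relativedelta(years=years, months=months) < AS_OF


def _crcl(rec):
    if rec.risk_fields.crcl_ml_min is not None:
        return rec.risk_fields.crcl_ml_min
    scr = _last_lab(rec, "serum_creatinine")
    if scr is None or scr.value is None:
        return None
    weight = rec.risk_fields.weight_kg
    if weight is None:
        wlab = _last_lab(rec, "weight")
        weight = wlab.value if wlab else None
    if weight is None or weight <= 0:
        return None
    value = (140 - _age(rec)) * weight / (0.815 * scr.value * 1000)
    return value if rec.sex == "male" else value * 0.85


# ---- one flat reference predicate per rule --------------------------------


def ref_dup_1(r):
    return bool(_active_tag(r, "h2ra")) and bool(_active_tag(r, "ppi"))


def ref_dup_2(r):
    return len({m.drug_code for m in _active_tag(r, "benzodiazepine")}) >= 2


def ref_dup_3(r):
    return len({m.drug_code for m in _active_tag(r, "antipsychotic")}) >= 2


def ref_dup_4(r):
    return len({m.drug_code for m in _active_tag(r, "ssri")}) >= 2


def ref_gas_1(r):
    ppis = _active_tag(r, "ppi")
    if not ppis or _active_tag(r, "nsaid", "aspirin_antiplatelet", "systemic_corticosteroid"):
        return False
    return any(m.indication_code == "gastroprotection" for m in ppis)


def ref_gas_2(r):
    if not _has_cond(r, "peptic_ulcer_uncomplicated", "erosive_esophagitis"):
        return False
    if not _active_tag(r, "ppi"):
        return False
    duration, _ = _episode_days(r, "ppi")
    return duration > 56


def ref_con_1(r):
    return _has_cond(r, "chronic_constipation") and bool(_active_tag(r, "constipating"))


def _ref_ant(r, cond, months):
    if not _active_tag(r, "vka", "dti", "xa_inhibitor"):
        return False
    if not _has_cond(r, cond) or _has_cond(r, "continuing_vte_risk"):
        return False
    return _episode_longer_than(r, ("vka", "dti", "xa_inhibitor"), months=months)


def ref_ant_1(r):
    return _ref_ant(r, "dvt_first", 6)


def ref_ant_2(r):
    return _ref_ant(r, "pe_first", 12)


def ref_ant_3(r):
    aspirin = _active_tag(r, "aspirin_antiplatelet")
    if not any(m.indication_code == "primary_cv_prevention" for m in aspirin):
        return False
    if _has_cond(r, "ischemic_heart_disease", "tia_stroke"):
        return False
    risk = r.risk_fields.cv_risk_pct
    return risk is not None and risk < 20


def ref_eld_1(r):
    if _age(r) < 65 or _has_cond(r, "heart_failure"):
        return False
    loops = _active_tag(r, "loop_diuretic")
    if not any(m.indication_code == "gravitational_edema" for m in loops):
        return False
    return _episode_longer_than(r, "loop_diuretic", days=90)


def ref_eld_2(r):
    if _age(r) < 65:
        return False
    spiro = _active_tag(r, "spironolactone")
    dose = sum(m.dose_amount * m.doses_per_day for m in spiro)
    if not spiro or dose <= 25:
        return False
    if _has_cond(r, "heart_failure"):
        return True
    crcl = _crcl(r)
    return crcl is not None and crcl < 30


def ref_eld_3(r):
    if _age(r) <= 85:
        return False
    statins = _active_tag(r, "statin")
    if not any(m.indication_code == "primary_cv_prevention" for m in statins):
        return False
    return _episode_longer_than(r, "statin", years=5)


def ref_eld_4(r):
    if _age(r) <= 65:
        return False
    return any(
        m.indication_code in ("insomnia", "agitation", "delirium")
        for m in _active_tag(r, "benzodiazepine", "zopiclone")
    )


def ref_eld_5(r):
    if _has_cond(r, "behavioral_risk_exception"):
        return False
    return any(
        m.indication_code == "behavioral_dementia" for m in _active_tag(r, "antipsychotic")
    )


def ref_eld_6(r):
    return _age(r) > 75 and bool(_active_tag(r, "first_gen_antihistamine"))


def ref_eld_7(r):
    return _age(r) > 75 and bool(_active_tag(r, "orphenadrine"))


def ref_psy_1(r):
    if not _has_cond(r, "parkinsons_disease"):
        return False
    for m in _active(r):
        t = _tags(m)
        if "antipsychotic" in t and "quetiapine_or_clozapine" not in t:
            return True
        if t & {"metoclopramide", "prochlorperazine", "promethazine"}:
            return True
    return False


def ref_psy_2(r):
    total = sum(
        m.dose_amount * m.doses_per_day for m in _active_tag(r, "citalopram")
    )
    return total > 40


def ref_psy_3(r):
    duration, _ = _episode_days(r, ("benzodiazepine", "zopiclone"))
    if duration < 28:
        return False
    return not _has_cond(
        r, "seizure_disorder", "rem_sleep_disorder", "alcohol_withdrawal",
        "severe_gad", "end_of_life",
    )


_OPIOIDS = ("opioid_strong", "opioid_weak_codeine", "opioid_weak_tramadol")


def ref_ana_1(r):
    if not _active_tag(r, *_OPIOIDS):
        return False
    if not _episode_longer_than(r, _OPIOIDS, months=3):
        return False
    if _has_cond(r, "nonmalignant_pain"):
        return True
    _, start = _episode_days(r, _OPIOIDS)
    for m in r.medications:
        if set(_OPIOIDS) & _tags(m) and m.start_date <= AS_OF and m.effective_end > start:
            if m.indication_code == "nonmalignant_pain":
                return True
    return False


def ref_ana_2(r):
    codes = set()
    for m in _active(r):
        t = _tags(m)
        if "opioid_long_acting" in t or (m.long_acting and t & set(_OPIOIDS)):
            codes.add(m.drug_code)
    return len(codes) >= 2


def ref_ana_3(r):
    return bool(_active_tag(r, "opioid_weak_codeine", "opioid_weak_tramadol")) and bool(
        _active_tag(r, "opioid_strong")
    )


def ref_ana_4(r):
    return bool(_active_tag(r, "paracetamol_codeine_combo"))


def ref_nsd_1(r):
    return (
        _age(r) > 75
        and bool(_active_tag(r, "nsaid"))
        and _episode_longer_than(r, "nsaid", months=3)
    )


def ref_nsd_2(r):
    nsaids = _active_tag(r, "nsaid")
    if not any(m.indication_code == "osteoarthritis" for m in nsaids):
        return False
    if not _episode_longer_than(r, "nsaid", months=3):
        return False
    for m in r.medications:
        if "paracetamol" in _tags(m) and m.start_date <= AS_OF:
            return False
    return True


def ref_nsd_3(r):
    return (
        bool(_active_tag(r, "nsaid"))
        and bool(_active_tag(r, "antiplatelet"))
        and not _active_tag(r, "ppi")
    )


def ref_nsd_4(r):
    return bool(_active_tag(r, "nsaid")) and _has_cond(r, "heart_failure")


def ref_nsd_5(r):
    return bool(_active_tag(r, "nsaid")) and bool(
        _active_tag(r, "diuretic", "ace_inhibitor", "arb")
    )


def ref_nsd_6(r):
    return len({m.drug_code for m in _active_tag(r, "nsaid")}) >= 2


def ref_gou_1(r):
    if _active_tag(r, "allopurinol"):
        return False
    window = AS_OF - relativedelta(months=12)
    flares = [
        m
        for m in r.medications
        if window < m.start_date <= AS_OF
        and _tags(m) & {"nsaid", "colchicine"}
        and m.indication_code == "gout_flare"
    ]
    return len(flares) >= 2


def ref_gou_2(r):
    if not _active_tag(r, "allopurinol"):
        return False
    return _stale(r, "uric_acid", years=1) and _stale(
        r, ("serum_creatinine", "creatinine_clearance"), years=1
    )


def ref_gou_3(r):
    if not _active_tag(r, "allopurinol"):
        return False
    urate = _last_lab(r, "uric_acid")
    return urate is not None and urate.value is not None and urate.value >= 0.36


def ref_bis_1(r):
    return (
        bool(_active_tag(r, "bisphosphonate"))
        and _episode_longer_than(r, "bisphosphonate", years=5)
        and _has_cond(r, "bmd_stabilized")
    )


def ref_bis_2(r):
    return (
        bool(_active_tag(r, "systemic_corticosteroid"))
        and not _active_tag(r, "bisphosphonate")
        and _episode_longer_than(r, "systemic_corticosteroid", days=90)
    )


def ref_met_1(r):
    if not _active_tag(r, "metformin"):
        return False
    crcl = _crcl(r)
    return crcl is not None and crcl < 30


def ref_flu_1(r):
    eligible = _age(r) >= 65 or _has_cond(
        r, "ischemic_heart_disease", "heart_failure", "rheumatic_heart_disease",
        "tia_stroke", "asthma_on_preventer", "copd", "diabetes", "cancer_invasive",
        "hiv", "transplant_recipient", "splenectomy", "pregnancy",
    )
    if not eligible:
        return False
    window = AS_OF - relativedelta(months=12)
    return not any(
        im.vaccine_code == "influenza" and window < im.date <= AS_OF
        for im in r.immunizations
    )


def ref_int_1(r):
    return bool(_active_tag(r, "tca")) and bool(_active_tag(r, "ssri"))


def ref_int_2(r):
    return bool(_active_tag(r, "beta_blocker")) and bool(_active_tag(r, "verapamil_diltiazem"))


def ref_int_3(r):
    return len({m.drug_code for m in _active_tag(r, "antimuscarinic")}) >= 2


def ref_int_4(r):
    return len({m.drug_code for m in _active_tag(r, "qt_prolonging")}) >= 2


def ref_mon_1(r):
    spiro = {m.drug_code for m in _active_tag(r, "spironolactone")}
    if not spiro:
        return False
    others = {m.drug_code for m in _active_tag(r, "potassium_sparing")} - spiro
    if not others:
        return False
    return _stale(r, "serum_potassium", months=6)


def ref_mon_2(r):
    if not _active_tag(r, "potassium_supplement"):
        return False
    k = _last_lab(r, "serum_potassium")
    if k is None or k.value is None or k.value <= 4.0:
        return False
    return _has_cond(r, "hypokalemia_cause_resolved")


def ref_mon_3(r):
    if not _active_tag(r, "lithium"):
        return False
    for analyte in ("tsh", "serum_creatinine", "lithium_level", "serum_sodium"):
        if _stale(r, analyte, months=6):
            return True
    for analyte in ("serum_calcium", "ecg"):
        if _stale(r, analyte, years=1):
            return True
    return False


def ref_mon_4(r):
    if not _active_tag(r, "ace_inhibitor"):
        return False
    return _stale(r, ("serum_creatinine", "creatinine_clearance"), years=1) or _stale(
        r, "serum_potassium", years=1
    )


def ref_mon_5(r):
    if not _active_tag(r, "atypical_antipsychotic") or not _has_cond(r, "schizophrenia"):
        return False
    panel = (
        "cv_assessment", "full_blood_count", "serum_creatinine", "liver_function",
        "lipid_profile", "weight", "fasting_glucose", "prolactin",
    )
    return any(_stale(r, a, years=1) for a in panel)


REFERENCES = {
    "DUP-1": ref_dup_1, "DUP-2": ref_dup_2, "DUP-3": ref_dup_3, "DUP-4": ref_dup_4,
    "GAS-1": ref_gas_1, "GAS-2": ref_gas_2,
    "CON-1": ref_con_1,
    "ANT-1": ref_ant_1, "ANT-2": ref_ant_2, "ANT-3": ref_ant_3,
    "ELD-1": ref_eld_1, "ELD-2": ref_eld_2, "ELD-3": ref_eld_3, "ELD-4": ref_eld_4,
    "ELD-5": ref_eld_5, "ELD-6": ref_eld_6, "ELD-7": ref_eld_7,
    "PSY-1": ref_psy_1, "PSY-2": ref_psy_2, "PSY-3": ref_psy_3,
    "ANA-1": ref_ana_1, "ANA-2": ref_ana_2, "ANA-3": ref_ana_3, "ANA-4": ref_ana_4,
    "NSD-1": ref_nsd_1, "NSD-2": ref_nsd_2, "NSD-3": ref_nsd_3, "NSD-4": ref_nsd_4,
    "NSD-5": ref_nsd_5, "NSD-6": ref_nsd_6,
    "GOU-1": ref_gou_1, "GOU-2": ref_gou_2, "GOU-3": ref_gou_3,
    "BIS-1": ref_bis_1, "BIS-2": ref_bis_2,
    "MET-1": ref_met_1,
    "FLU-1": ref_flu_1,
    "INT-1": ref_int_1, "INT-2": ref_int_2, "INT-3": ref_int_3, "INT-4": ref_int_4,
    "MON-1": ref_mon_1, "MON-2": ref_mon_2, "MON-3": ref_mon_3, "MON-4": ref_mon_4,
    "MON-5": ref_mon_5,
}


def test_reference_covers_whole_catalog(ruleset):
    assert set(REFERENCES) == {r.rule_id for r in ruleset}


def test_engine_agrees_with_references_on_1000_random_patients(ruleset, formulary):
    """Zero discrepancies between the generic evaluator and flat re-derivations."""
    population = generate_population(
        SynthParams(n_patients=1000, seed=20160601, index_date=AS_OF)
    )
    mismatches = []
    for rec in population:
        engine_fired = {
            a.rule_id for a in evaluate_patient(rec, ruleset, AS_OF, "silent", formulary)
        }
        for rule_id, reference in REFERENCES.items():
            expected = reference(rec)
            if expected != (rule_id in engine_fired):
                mismatches.append((rec.patient_id, rule_id, expected))
    assert mismatches == []


def test_engine_agrees_with_references_on_trigger_patients(trigger_bundle, ruleset, formulary):
    for rec in trigger_bundle:
        engine_fired = {
            a.rule_id for a in evaluate_patient(rec, ruleset, AS_OF, "silent", formulary)
        }
        reference_fired = {rid for rid, ref in REFERENCES.items() if ref(rec)}
        assert engine_fired == reference_fired == {rec.patient_id.replace("trigger-", "")}
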