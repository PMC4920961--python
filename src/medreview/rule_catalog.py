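"""The deprescribing / monitoring rule catalog.

Forty-six rules across fourteen categories: duplicate therapy,
gastroprotectants, constipation, antithrombotics, medicines in the elderly,
psychotropics, analgesics, NSAIDs, gout, bisphosphonates, metformin,
seasonal influenza vaccination, drug-drug interactions, and laboratory
monitoring. Each rule is a pure predicate over one patient record at an
evaluation date; every numeric threshold lives in the rule's parameter map
(overridable per deployment), never in the predicate body.

Comparator strictness follows the clinical phrasing exactly: "aged >65" is
strict, "taken for >=4 weeks" is inclusive, "doses >40 mg daily" is strict,
"uric acid not <0.36 mmol/L" fires at 0.36, "serum potassium >4.0 mmol/L"
does not fire at 4.0.
"""

from __future__ import annotations

from dateutil.relativedelta import relativedelta

from . import medhist as _mh
from .records import INFLUENZA_VACCINE_CODE
from .rules_engine import RuleContext, RuleDefinition

__all__ = [
    "default_ruleset",
    "rule_by_id",
    "RULE_IDS",
    "ANTICOAGULANT_TAGS",
    "OPIOID_TAGS",
    "BENZO_OR_Z",
    "GASTRO_IRRITANT_TAGS",
    "CVD_HISTORY_CONDITIONS",
    "BENZO_EXCEPTION_CONDITIONS",
    "FLU_COHORT_CONDITIONS",
    "MON3_SIX_MONTHLY",
    "MON3_ANNUAL",
    "MON5_PANEL",
    "RENAL_ANALYTES",
]

ANTICOAGULANT_TAGS = ("vka", "dti", "xa_inhibitor")
OPIOID_TAGS = ("opioid_strong", "opioid_weak_codeine", "opioid_weak_tramadol")
BENZO_OR_Z = ("benzodiazepine", "zopiclone")
GASTRO_IRRITANT_TAGS = ("nsaid", "aspirin_antiplatelet", "systemic_corticosteroid")
CVD_HISTORY_CONDITIONS = ("ischemic_heart_disease", "tia_stroke")
BENZO_EXCEPTION_CONDITIONS = (
    "seizure_disorder",
    "rem_sleep_disorder",
    "alcohol_withdrawal",
    "severe_gad",
    "end_of_life",
)
FLU_COHORT_CONDITIONS = (
    "ischemic_heart_disease",
    "heart_failure",
    "rheumatic_heart_disease",
    "tia_stroke",
    "asthma_on_preventer",
    "copd",
    "diabetes",
    "cancer_invasive",
    "hiv",
    "transplant_recipient",
    "splenectomy",
    "pregnancy",
)
RENAL_ANALYTES = ("serum_creatinine", "creatinine_clearance")
MON3_SIX_MONTHLY = ("tsh", "serum_creatinine", "lithium_level", "serum_sodium")
MON3_ANNUAL = ("serum_calcium", "ecg")
# Annual metabolic-safety panel for atypical antipsychotics in schizophrenia;
# serum creatinine stands in for the urea-and-electrolytes panel.
MON5_PANEL = (
    "cv_assessment",
    "full_blood_count",
    "serum_creatinine",
    "liver_function",
    "lipid_profile",
    "weight",
    "fasting_glucose",
    "prolactin",
)


# ---------------------------------------------------------------- duplicates


def _dup_pair(ctx: RuleContext, tag_a: str, tag_b: str):
    a = ctx.active_with_tag(tag_a)
    b = ctx.active_with_tag(tag_b)
    if a and b:
        return ctx.ev(a, b)
    return None


def _dup_class(ctx: RuleContext, tag: str):
    orders = ctx.active_with_tag(tag)
    if len(ctx.distinct_codes(orders)) >= ctx.params["min_distinct"]:
        return ctx.ev(orders)
    return None


def _dup_1(ctx):  # H2RA with PPI
    return _dup_pair(ctx, "h2ra", "ppi")


def _dup_2(ctx):
    return _dup_class(ctx, "benzodiazepine")


def _dup_3(ctx):
    return _dup_class(ctx, "antipsychotic")


def _dup_4(ctx):
    return _dup_class(ctx, "ssri")


# ----------------------------------------------------------- gastroprotectants


def _gas_1(ctx):
    ppis = ctx.active_with_tag("ppi")
    if not ppis:
        return None
    if ctx.active_with_tag(*GASTRO_IRRITANT_TAGS):
        return None  # the irritant is still on board; gastroprotection stands
    protective = [m for m in ppis if m.indication_code == "gastroprotection"]
    if not protective:
        if all(m.indication_code is None for m in ppis):
            if ctx.gap("indication_code", "PPI active with no recorded indication"):
                protective = [m for m in ppis if m.indication_code is None]
        if not protective:
            return None
    return ctx.ev(protective)


def _gas_2(ctx):
    cond = ctx.condition("peptic_ulcer_uncomplicated", "erosive_esophagitis")
    if cond is None:
        return None
    ppis = ctx.active_with_tag("ppi")
    if not ppis:
        return None
    duration = _mh.continuous_use_duration(
        ctx.record, "ppi", ctx.as_of, ctx.config.max_gap_days, ctx.fm
    )
    if duration > ctx.params["weeks"] * 7:
        return ctx.ev(cond, ctx.episode_orders("ppi"))
    return None


# -------------------------------------------------------------- constipation


def _con_1(ctx):
    cond = ctx.condition("chronic_constipation")
    if cond is None:
        return None
    culprits = ctx.active_with_tag("constipating")
    if culprits:
        return ctx.ev(cond, culprits)
    return None


# ------------------------------------------------------------ antithrombotic


def _ant_duration(ctx, condition_code: str):
    anticoag = ctx.active_with_tag(*ANTICOAGULANT_TAGS)
    if not anticoag:
        return None
    cond = ctx.condition(condition_code)
    if cond is None:
        return None
    if ctx.condition("continuing_vte_risk") is not None:
        return None
    if ctx.used_longer_than(frozenset(ANTICOAGULANT_TAGS), months=ctx.params["months"]):
        return ctx.ev(anticoag, cond)
    return None


def _ant_1(ctx):
    return _ant_duration(ctx, "dvt_first")


def _ant_2(ctx):
    return _ant_duration(ctx, "pe_first")


def _ant_3(ctx):
    aspirin = ctx.active_with_tag("aspirin_antiplatelet")
    if not aspirin:
        return None
    primary = [m for m in aspirin if m.indication_code == "primary_cv_prevention"]
    if not primary:
        if all(m.indication_code is None for m in aspirin) and ctx.gap(
            "indication_code", "aspirin active with no recorded indication"
        ):
            primary = aspirin
        if not primary:
            return None
    if ctx.condition(*CVD_HISTORY_CONDITIONS) is not None:
        return None
    risk = ctx.record.risk_fields.cv_risk_pct
    if risk is None:
        if not ctx.gap("cv_risk_pct", "no stored cardiovascular risk estimate"):
            return None
        return ctx.ev(primary)
    if risk < ctx.params["risk_threshold_pct"]:
        return ctx.ev(primary, "risk:cv_risk_pct")
    return None


# -------------------------------------------------------------------- elderly


def _eld_1(ctx):
    if ctx.age() < ctx.params["min_age"]:
        return None
    loops = ctx.active_with_tag("loop_diuretic")
    if not loops:
        return None
    if ctx.condition("heart_failure") is not None:
        return None
    if not ctx.used_longer_than("loop_diuretic", days=ctx.params["long_term_days"]):
        return None
    edema = [m for m in loops if m.indication_code == "gravitational_edema"]
    if not edema:
        if all(m.indication_code is None for m in loops) and ctx.gap(
            "indication_code", "long-term loop diuretic with no recorded indication"
        ):
            edema = loops
        if not edema:
            return None
    return ctx.ev(edema)


def _eld_2(ctx):
    if ctx.age() < ctx.params["min_age"]:
        return None
    spiro = ctx.active_with_tag("spironolactone")
    if not spiro:
        return None
    dose = _mh.class_daily_dose(ctx.record, "spironolactone", ctx.as_of, ctx.fm)
    if dose <= ctx.params["max_daily_mg"]:
        return None
    hf = ctx.condition("heart_failure")
    if hf is not None:
        return ctx.ev(spiro, hf)
    crcl = _mh.estimate_crcl(ctx.record, ctx.as_of)
    if crcl is None:
        if ctx.gap("crcl_ml_min", "renal function unknown; cannot assess spironolactone dose"):
            return ctx.ev(spiro)
        return None
    if crcl < ctx.params["crcl_threshold"]:
        source = (
            "risk:crcl_ml_min"
            if ctx.record.risk_fields.crcl_ml_min is not None
            else ctx.last_result("serum_creatinine")
        )
        return ctx.ev(spiro, source)
    return None


def _eld_3(ctx):
    if ctx.age() <= ctx.params["age_over"]:
        return None
    statins = ctx.active_with_tag("statin")
    if not statins:
        return None
    if not ctx.used_longer_than("statin", years=ctx.params["years"]):
        return None
    primary = [m for m in statins if m.indication_code == "primary_cv_prevention"]
    if not primary:
        if all(m.indication_code is None for m in statins) and ctx.gap(
            "indication_code", "long-term statin with no recorded indication"
        ):
            primary = statins
        if not primary:
            return None
    return ctx.ev(primary)


def _eld_4(ctx):
    if ctx.age() <= ctx.params["age_over"]:
        return None
    hypnotics = ctx.active_with_tag(*BENZO_OR_Z)
    if not hypnotics:
        return None
    indicated = [
        m for m in hypnotics if m.indication_code in {"insomnia", "agitation", "delirium"}
    ]
    if not indicated:
        if all(m.indication_code is None for m in hypnotics) and ctx.gap(
            "indication_code", "hypnotic active in an older adult with no recorded indication"
        ):
            indicated = hypnotics
        if not indicated:
            return None
    return ctx.ev(indicated)


def _eld_5(ctx):
    antipsych = ctx.active_with_tag("antipsychotic")
    if not antipsych:
        return None
    dementia_use = [m for m in antipsych if m.indication_code == "behavioral_dementia"]
    if not dementia_use:
        if (
            ctx.condition("dementia") is not None
            and all(m.indication_code is None for m in antipsych)
            and ctx.gap(
                "indication_code", "antipsychotic in dementia with no recorded indication"
            )
        ):
            dementia_use = antipsych
        if not dementia_use:
            return None
    if ctx.condition("behavioral_risk_exception") is not None:
        return None
    return ctx.ev(dementia_use)


def _eld_6(ctx):
    if ctx.age() <= ctx.params["age_over"]:
        return None
    orders = ctx.active_with_tag("first_gen_antihistamine")
    return ctx.ev(orders) if orders else None


def _eld_7(ctx):
    if ctx.age() <= ctx.params["age_over"]:
        return None
    orders = ctx.active_with_tag("orphenadrine")
    return ctx.ev(orders) if orders else None


# ---------------------------------------------------------------- psychotropic


def _psy_1(ctx):
    cond = ctx.condition("parkinsons_disease")
    if cond is None:
        return None
    offenders = [
        m
        for m in ctx.active
        if (
            ("antipsychotic" in ctx.tags(m) and "quetiapine_or_clozapine" not in ctx.tags(m))
            or ctx.tags(m) & {"metoclopramide", "prochlorperazine", "promethazine"}
        )
    ]
    if offenders:
        return ctx.ev(cond, offenders)
    return None


def _psy_2(ctx):
    dose = _mh.class_daily_dose(ctx.record, "citalopram", ctx.as_of, ctx.fm)
    if dose > ctx.params["max_daily_mg"]:
        return ctx.ev(ctx.active_with_tag("citalopram"))
    return None


def _psy_3(ctx):
    duration = _mh.continuous_use_duration(
        ctx.record, frozenset(BENZO_OR_Z), ctx.as_of, ctx.config.max_gap_days, ctx.fm
    )
    if duration < ctx.params["min_days"]:
        return None
    if ctx.condition(*BENZO_EXCEPTION_CONDITIONS) is not None:
        return None
    return ctx.ev(ctx.episode_orders(frozenset(BENZO_OR_Z)))


# ------------------------------------------------------------------ analgesic


def _ana_1(ctx):
    opioids = ctx.active_with_tag(*OPIOID_TAGS)
    if not opioids:
        return None
    if not ctx.used_longer_than(frozenset(OPIOID_TAGS), months=ctx.params["months"]):
        return None
    episode = ctx.episode_orders(frozenset(OPIOID_TAGS))
    indicated = [m for m in episode if m.indication_code == "nonmalignant_pain"]
    cond = ctx.condition("nonmalignant_pain")
    if not indicated and cond is None:
        if all(m.indication_code is None for m in episode) and ctx.gap(
            "indication_code", "long-term opioid with no recorded indication"
        ):
            indicated = episode
        if not indicated:
            return None
    return ctx.ev(indicated or episode, cond)


def _ana_2(ctx):
    long_acting = [
        m
        for m in ctx.active
        if ("opioid_long_acting" in ctx.tags(m))
        or (m.long_acting and ctx.tags(m) & set(OPIOID_TAGS))
    ]
    if len(ctx.distinct_codes(long_acting)) >= ctx.params["min_distinct"]:
        return ctx.ev(long_acting)
    return None


def _ana_3(ctx):
    weak = ctx.active_with_tag("opioid_weak_codeine", "opioid_weak_tramadol")
    strong = ctx.active_with_tag("opioid_strong")
    if weak and strong:
        return ctx.ev(weak, strong)
    return None


def _ana_4(ctx):
    combos = ctx.active_with_tag("paracetamol_codeine_combo")
    return ctx.ev(combos) if combos else None


# ---------------------------------------------------------------------- NSAID


def _nsd_1(ctx):
    if ctx.age() <= ctx.params["age_over"]:
        return None
    if not ctx.active_with_tag("nsaid"):
        return None
    if ctx.used_longer_than("nsaid", months=ctx.params["months"]):
        return ctx.ev(ctx.episode_orders("nsaid"))
    return None


def _nsd_2(ctx):
    nsaids = ctx.active_with_tag("nsaid")
    if not nsaids:
        return None
    if not ctx.used_longer_than("nsaid", months=ctx.params["months"]):
        return None
    tried_paracetamol = any(
        "paracetamol" in ctx.tags(m)
        for m in ctx.record.medications
        if m.start_date <= ctx.as_of
    )
    if tried_paracetamol:
        return None
    oa = [m for m in nsaids if m.indication_code == "osteoarthritis"]
    if not oa:
        if all(m.indication_code is None for m in nsaids) and ctx.gap(
            "indication_code", "long-term NSAID with no recorded indication"
        ):
            oa = nsaids
        if not oa:
            return None
    return ctx.ev(oa)


def _nsd_3(ctx):
    nsaids = ctx.active_with_tag("nsaid")
    antiplatelets = ctx.active_with_tag("antiplatelet")
    if not (nsaids and antiplatelets):
        return None
    if ctx.active_with_tag("ppi"):
        return None
    return ctx.ev(nsaids, antiplatelets)


def _nsd_4(ctx):
    nsaids = ctx.active_with_tag("nsaid")
    cond = ctx.condition("heart_failure")
    if nsaids and cond is not None:
        return ctx.ev(nsaids, cond)
    return None


def _nsd_5(ctx):
    nsaids = ctx.active_with_tag("nsaid")
    if not nsaids:
        return None
    interacting = ctx.active_with_tag("diuretic", "ace_inhibitor", "arb")
    if interacting:
        return ctx.ev(nsaids, interacting)
    return None


def _nsd_6(ctx):
    return _dup_class(ctx, "nsaid")


# ----------------------------------------------------------------------- gout


def _gou_1(ctx):
    if ctx.active_with_tag("allopurinol"):
        return None
    window_start = ctx.as_of - relativedelta(months=ctx.params["months"])
    flare_orders = [
        m
        for m in ctx.record.medications
        if window_start < m.start_date <= ctx.as_of
        and ctx.tags(m) & {"nsaid", "colchicine"}
        and m.indication_code == "gout_flare"
    ]
    if len(flare_orders) >= ctx.params["min_courses"]:
        return ctx.ev(flare_orders)
    return None


def _gou_2(ctx):
    allo = ctx.active_with_tag("allopurinol")
    if not allo:
        return None
    years = ctx.params["years"]
    if ctx.stale("uric_acid", years=years) and ctx.stale(RENAL_ANALYTES, years=years):
        return ctx.ev(allo)
    return None


def _gou_3(ctx):
    allo = ctx.active_with_tag("allopurinol")
    if not allo:
        return None
    urate = ctx.last_result("uric_acid")
    if urate is None or urate.value is None:
        return None  # GOU-2 covers the untested case
    if urate.value >= ctx.params["target_mmol_l"]:  # "not <0.36" fires at 0.36
        return ctx.ev(allo, urate)
    return None


# -------------------------------------------------------------- bisphosphonate


def _bis_1(ctx):
    bis = ctx.active_with_tag("bisphosphonate")
    if not bis:
        return None
    if not ctx.used_longer_than("bisphosphonate", years=ctx.params["years"]):
        return None
    stabilized = ctx.condition("bmd_stabilized")
    if stabilized is None:
        if ctx.gap("bmd_stabilized", "long-term bisphosphonate; BMD stability not recorded"):
            return ctx.ev(bis)
        return None
    return ctx.ev(bis, stabilized)


def _bis_2(ctx):
    steroids = ctx.active_with_tag("systemic_corticosteroid")
    if not steroids:
        return None
    if ctx.active_with_tag("bisphosphonate"):
        return None
    if ctx.used_longer_than("systemic_corticosteroid", days=ctx.params["long_term_days"]):
        return ctx.ev(ctx.episode_orders("systemic_corticosteroid"))
    return None


# ------------------------------------------------------------------- metformin


def _met_1(ctx):
    metformin = ctx.active_with_tag("metformin")
    if not metformin:
        return None
    crcl = _mh.estimate_crcl(ctx.record, ctx.as_of)
    if crcl is None:
        if ctx.gap("crcl_ml_min", "renal function unknown; cannot assess metformin dose"):
            return ctx.ev(metformin)
        return None
    if crcl < ctx.params["crcl_threshold"]:
        source = (
            "risk:crcl_ml_min"
            if ctx.record.risk_fields.crcl_ml_min is not None
            else ctx.last_result("serum_creatinine")
        )
        return ctx.ev(metformin, source)
    return None


# ------------------------------------------------------------------- influenza


def _flu_1(ctx):
    cohort_evidence: list = []
    if ctx.age() >= ctx.params["min_age"]:
        cohort_evidence.append(f"demo:age:{ctx.age()}")
    for code in FLU_COHORT_CONDITIONS:
        cond = ctx.condition(code)
        if cond is not None:
            cohort_evidence.append(cond)
    if not cohort_evidence:
        return None
    window_start = ctx.as_of - relativedelta(months=ctx.params["months"])
    vaccinated = any(
        im.vaccine_code == INFLUENZA_VACCINE_CODE and window_start < im.date <= ctx.as_of
        for im in ctx.record.immunizations
    )
    if vaccinated:
        return None
    return ctx.ev(cohort_evidence)


# ---------------------------------------------------------------- interactions


def _int_1(ctx):
    return _dup_pair(ctx, "tca", "ssri")


def _int_2(ctx):
    return _dup_pair(ctx, "beta_blocker", "verapamil_diltiazem")


def _int_3(ctx):
    return _dup_class(ctx, "antimuscarinic")


def _int_4(ctx):
    return _dup_class(ctx, "qt_prolonging")


# ------------------------------------------------------------------ monitoring


def _mon_1(ctx):
    spiro = ctx.active_with_tag("spironolactone")
    if not spiro:
        return None
    spiro_codes = ctx.distinct_codes(spiro)
    other_sparing = [
        m
        for m in ctx.active_with_tag("potassium_sparing")
        if m.drug_code not in spiro_codes
    ]
    if not other_sparing:
        return None
    if ctx.stale("serum_potassium", months=ctx.params["months"]):
        return ctx.ev(spiro, other_sparing, ctx.last_result("serum_potassium"))
    return None


def _mon_2(ctx):
    supplements = ctx.active_with_tag("potassium_supplement")
    if not supplements:
        return None
    k = ctx.last_result("serum_potassium")
    if k is None or k.value is None:
        return None
    if k.value <= ctx.params["threshold_mmol_l"]:  # ">4.0" strict: 4.0 does not fire
        return None
    resolved = ctx.condition("hypokalemia_cause_resolved")
    if resolved is None:
        if ctx.gap(
            "hypokalemia_cause_resolved",
            "potassium above target; hypokalemia cause resolution not recorded",
        ):
            return ctx.ev(supplements, k)
        return None
    return ctx.ev(supplements, k, resolved)


def _mon_3(ctx):
    lithium = ctx.active_with_tag("lithium")
    if not lithium:
        return None
    months = ctx.params["months"]
    years = ctx.params["years"]
    stale_any = any(ctx.stale(a, months=months) for a in MON3_SIX_MONTHLY) or any(
        ctx.stale(a, years=years) for a in MON3_ANNUAL
    )
    if stale_any:
        return ctx.ev(lithium)
    return None


def _mon_4(ctx):
    ace = ctx.active_with_tag("ace_inhibitor")
    if not ace:
        return None
    years = ctx.params["years"]
    if ctx.stale(RENAL_ANALYTES, years=years) or ctx.stale("serum_potassium", years=years):
        return ctx.ev(ace)
    return None


def _mon_5(ctx):
    atypicals = ctx.active_with_tag("atypical_antipsychotic")
    if not atypicals:
        return None
    cond = ctx.condition("schizophrenia")
    if cond is None:
        return None
    years = ctx.params["years"]
    if any(ctx.stale(a, years=years) for a in MON5_PANEL):
        return ctx.ev(atypicals, cond)
    return None


# --------------------------------------------------------------------- catalog

_MEDS = frozenset({"medications"})
_MEDS_COND = frozenset({"medications", "conditions"})
_MEDS_LABS = frozenset({"medications", "labs"})
_MEDS_DEMO = frozenset({"medications", "demographics"})


def _rule(rule_id, category, action, message, required, params, predicate):
    return RuleDefinition(
        rule_id=rule_id,
        category=category,
        action_kind=action,
        message=message,
        required_elements=frozenset(required),
        parameters=params,
        info_link=f"guide:{rule_id.lower()}",
        predicate=predicate,
    )


_CATALOG: list[RuleDefinition] = [
    _rule("DUP-1", "duplicate_therapy", "stop",
          "H2-receptor antagonist and proton pump inhibitor are both active; stop one.",
          _MEDS, {}, _dup_1),
    _rule("DUP-2", "duplicate_therapy", "stop",
          "More than one benzodiazepine is active; stop the duplicate.",
          _MEDS, {"min_distinct": 2}, _dup_2),
    _rule("DUP-3", "duplicate_therapy", "stop",
          "More than one antipsychotic is active; stop the duplicate.",
          _MEDS, {"min_distinct": 2}, _dup_3),
    _rule("DUP-4", "duplicate_therapy", "stop",
          "More than one SSRI is active; stop the duplicate.",
          _MEDS, {"min_distinct": 2}, _dup_4),
    _rule("GAS-1", "gastroprotectant", "stop",
          "PPI prescribed for gastroprotection but the gastro-irritant therapy has stopped; "
          "stop the PPI.",
          _MEDS, {}, _gas_1),
    _rule("GAS-2", "gastroprotectant", "reduce_dose",
          "PPI for uncomplicated peptic ulcer or erosive esophagitis beyond 8 weeks; "
          "stop or step down.",
          _MEDS_COND, {"weeks": 8}, _gas_2),
    _rule("CON-1", "constipation", "review",
          "Chronic constipation with a constipating medicine active; switch to a "
          "non-constipating alternative if appropriate.",
          _MEDS_COND, {}, _con_1),
    _rule("ANT-1", "antithrombotic", "stop",
          "Anticoagulation beyond 6 months after a first DVT without continuing provoking "
          "risk factors; stop.",
          _MEDS_COND, {"months": 6}, _ant_1),
    _rule("ANT-2", "antithrombotic", "stop",
          "Anticoagulation beyond 12 months after a first pulmonary embolus without "
          "continuing provoking risk factors; stop.",
          _MEDS_COND, {"months": 12}, _ant_2),
    _rule("ANT-3", "antithrombotic", "stop",
          "Aspirin for primary prevention with 5-year cardiovascular risk below 20% and no "
          "cardiovascular history; stop.",
          frozenset({"medications", "conditions", "risk_fields"}),
          {"risk_threshold_pct": 20}, _ant_3),
    _rule("ELD-1", "elderly", "stop",
          "Long-term loop diuretic for gravitational edema without heart failure in an "
          "older adult; stop, use as-required if needed.",
          frozenset({"medications", "conditions", "demographics"}),
          {"min_age": 65, "long_term_days": 90}, _eld_1),
    _rule("ELD-2", "elderly", "reduce_dose",
          "Spironolactone above 25 mg daily with heart failure or creatinine clearance "
          "below 30 mL/min in an older adult; reduce.",
          frozenset({"medications", "conditions", "labs", "demographics"}),
          {"min_age": 65, "max_daily_mg": 25, "crcl_threshold": 30}, _eld_2),
    _rule("ELD-3", "elderly", "review",
          "Statin continued beyond 5 years for primary prevention after age 85; review.",
          _MEDS_DEMO, {"age_over": 85, "years": 5}, _eld_3),
    _rule("ELD-4", "elderly", "stop",
          "Benzodiazepine or zopiclone for insomnia, agitation or delirium after age 65; stop.",
          _MEDS_DEMO, {"age_over": 65}, _eld_4),
    _rule("ELD-5", "elderly", "stop",
          "Antipsychotic for behavioral problems of dementia without a documented exception; "
          "stop.",
          _MEDS_COND, {}, _eld_5),
    _rule("ELD-6", "elderly", "stop",
          "First-generation antihistamine after age 75; stop.",
          _MEDS_DEMO, {"age_over": 75}, _eld_6),
    _rule("ELD-7", "elderly", "stop",
          "Orphenadrine after age 75; stop.",
          _MEDS_DEMO, {"age_over": 75}, _eld_7),
    _rule("PSY-1", "psychotropic", "stop",
          "Dopamine-blocking antipsychotic or antiemetic in Parkinson's disease "
          "(quetiapine/clozapine excepted); stop.",
          _MEDS_COND, {}, _psy_1),
    _rule("PSY-2", "psychotropic", "reduce_dose",
          "Citalopram above 40 mg daily; reduce the dose.",
          _MEDS, {"max_daily_mg": 40}, _psy_2),
    _rule("PSY-3", "psychotropic", "stop",
          "Benzodiazepine or zopiclone taken continuously for 4 weeks or more without an "
          "excepted indication; taper and stop.",
          _MEDS_COND, {"min_days": 28}, _psy_3),
    _rule("ANA-1", "analgesic", "review",
          "Opioid beyond 3 months for nonmalignant pain; review continued need.",
          _MEDS_COND, {"months": 3}, _ana_1),
    _rule("ANA-2", "analgesic", "stop",
          "Two different long-acting opioids are active; stop one.",
          _MEDS, {"min_distinct": 2}, _ana_2),
    _rule("ANA-3", "analgesic", "stop",
          "Codeine or tramadol co-prescribed with a strong opioid; stop the weak opioid.",
          _MEDS, {}, _ana_3),
    _rule("ANA-4", "analgesic", "stop",
          "Fixed-dose paracetamol-codeine combination; stop and prescribe the components "
          "separately.",
          _MEDS, {}, _ana_4),
    _rule("NSD-1", "nsaid", "review",
          "NSAID beyond 3 months after age 75; review stopping.",
          _MEDS_DEMO, {"months": 3, "age_over": 75}, _nsd_1),
    _rule("NSD-2", "nsaid", "review",
          "NSAID beyond 3 months for osteoarthritis without a paracetamol trial; review.",
          _MEDS, {"months": 3}, _nsd_2),
    _rule("NSD-3", "nsaid", "stop",
          "NSAID with an antiplatelet and no PPI cover; stop the NSAID or add a PPI.",
          _MEDS, {}, _nsd_3),
    _rule("NSD-4", "nsaid", "stop",
          "NSAID active in heart failure; stop.",
          _MEDS_COND, {}, _nsd_4),
    _rule("NSD-5", "nsaid", "stop",
          "NSAID with a diuretic, ACE inhibitor or ARB; stop the NSAID.",
          _MEDS, {}, _nsd_5),
    _rule("NSD-6", "nsaid", "stop",
          "More than one NSAID is active; stop the duplicate.",
          _MEDS, {"min_distinct": 2}, _nsd_6),
    _rule("GOU-1", "gout", "initiate",
          "Recurrent gout flares treated acutely without urate-lowering therapy; start "
          "allopurinol (or an alternative if contraindicated).",
          _MEDS, {"min_courses": 2, "months": 12}, _gou_1),
    _rule("GOU-2", "gout", "monitor",
          "On allopurinol with neither uric acid nor renal function checked in over a year; "
          "order monitoring.",
          _MEDS_LABS, {"years": 1}, _gou_2),
    _rule("GOU-3", "gout", "review",
          "On allopurinol with uric acid not below 0.36 mmol/L; maximize the dose or add "
          "therapy.",
          _MEDS_LABS, {"target_mmol_l": 0.36}, _gou_3),
    _rule("BIS-1", "bisphosphonate", "review",
          "Bisphosphonate beyond 5 years of continuous use with stabilized bone density; "
          "consider a drug holiday.",
          _MEDS_COND, {"years": 5}, _bis_1),
    _rule("BIS-2", "bisphosphonate", "initiate",
          "Long-term systemic corticosteroid without bone protection; consider starting a "
          "bisphosphonate.",
          _MEDS, {"long_term_days": 90}, _bis_2),
    _rule("MET-1", "metformin", "reduce_dose",
          "Metformin with creatinine clearance below 30 mL/min; adjust the dose.",
          _MEDS_LABS, {"crcl_threshold": 30}, _met_1),
    _rule("FLU-1", "influenza", "recommend",
          "Eligible for annual influenza vaccination and none recorded in the past 12 "
          "months; recommend vaccination.",
          frozenset({"conditions", "immunizations", "demographics"}),
          {"min_age": 65, "months": 12}, _flu_1),
    _rule("INT-1", "interaction", "alert",
          "Tricyclic antidepressant with an SSRI.",
          _MEDS, {}, _int_1),
    _rule("INT-2", "interaction", "alert",
          "Beta-blocker with verapamil or diltiazem.",
          _MEDS, {}, _int_2),
    _rule("INT-3", "interaction", "alert",
          "Two or more antimuscarinic medicines are active.",
          _MEDS, {"min_distinct": 2}, _int_3),
    _rule("INT-4", "interaction", "alert",
          "Two or more QT-prolonging medicines are active.",
          _MEDS, {"min_distinct": 2}, _int_4),
    _rule("MON-1", "monitoring", "monitor",
          "Spironolactone with another potassium-sparing drug and no potassium level in 6 "
          "months; order one.",
          _MEDS_LABS, {"months": 6}, _mon_1),
    _rule("MON-2", "monitoring", "stop",
          "Potassium supplement with serum potassium above 4.0 mmol/L and the cause of "
          "hypokalemia resolved; stop and follow up.",
          frozenset({"medications", "labs", "conditions"}),
          {"threshold_mmol_l": 4.0}, _mon_2),
    _rule("MON-3", "monitoring", "monitor",
          "On lithium with overdue safety monitoring (TFT/renal/lithium/sodium 6-monthly; "
          "calcium/ECG yearly); order the overdue tests.",
          _MEDS_LABS, {"months": 6, "years": 1}, _mon_3),
    _rule("MON-4", "monitoring", "monitor",
          "On an ACE inhibitor with no renal function or potassium in over a year; order "
          "monitoring.",
          _MEDS_LABS, {"years": 1}, _mon_4),
    _rule("MON-5", "monitoring", "monitor",
          "On an atypical antipsychotic for schizophrenia with the annual metabolic panel "
          "overdue; order the overdue tests.",
          frozenset({"medications", "labs", "conditions"}),
          {"years": 1}, _mon_5),
]

RULE_IDS = tuple(r.rule_id for r in _CATALOG)


def default_ruleset() -> list[RuleDefinition]:
    """The full 46-rule catalog, in catalog order."""
    return list(_CATALOG)


def rule_by_id(rule_id: str) -> RuleDefinition:
    for rule in _CATALOG:
        if rule.rule_id == rule_id:
            return rule
    raise KeyError(f"unknown rule_id {rule_id!r}")
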