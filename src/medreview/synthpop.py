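"""Seeded synthetic primary-care populations.

The generator stands in for a de-identified historical database when
validating the rule catalog: it produces patient bundles with a
controllable concurrent-medication-count distribution, condition
prevalences high enough to exercise every rule, dated laboratory panels
with a tunable overdue fraction, and optional *planted* patients guaranteed
to fire chosen rules.

Medication-count calibration
----------------------------
National dispensing data summarise concurrent medicine use by two tail
probabilities: the fraction of the population on five or more medicines
(8.5% in the 2013-2014 figures the defaults target) and on eleven or more
(2.6%). The generator fits a two-component mixture with closed-form tails:

* a *low-use* component supported on 0-4 medicines (truncated geometric
  shape), carrying probability ``1 - P(>=5)``;
* a *heavy-use* component ``5 + Geometric(q)`` supported on 5, 6, ...,
  carrying probability ``P(>=5)``, with the continuation probability ``q``
  solved from ``P(>=11) = P(>=5) * q**6``.

Both stated tails are therefore matched exactly. Every order generated for
a patient is active at the single index date, so the concurrent count at
the index date equals the drawn count by construction.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from dateutil.relativedelta import relativedelta

from .formulary import Formulary, default_formulary
from .records import (
    ConditionRecord,
    Immunization,
    LabResult,
    MedicationOrder,
    PatientRecord,
    RiskFields,
    INFLUENZA_VACCINE_CODE,
)
from .triggers import build_trigger_patient

__all__ = [
    "DEFAULT_TARGET_GE5",
    "DEFAULT_TARGET_GE11",
    "DEFAULT_INDEX_DATE",
    "DEFAULT_CONDITION_PREVALENCES",
    "MedCountDistribution",
    "SynthParams",
    "calibrate_med_count",
    "generate_population",
]

DEFAULT_TARGET_GE5 = 0.085
DEFAULT_TARGET_GE11 = 0.026
DEFAULT_INDEX_DATE = dt.date(2016, 6, 1)

# Shape of the low-use component over 0-4 medicines: decreasing truncated
# geometric with ratio 0.6 (most low-use patients take nothing or one drug).
_LOW_SHAPE_RATIO = 0.6

DEFAULT_CONDITION_PREVALENCES: dict[str, float] = {
    "diabetes": 0.08,
    "heart_failure": 0.02,
    "copd": 0.04,
    "asthma_on_preventer": 0.05,
    "ischemic_heart_disease": 0.05,
    "rheumatic_heart_disease": 0.003,
    "tia_stroke": 0.02,
    "cancer_invasive": 0.01,
    "hiv": 0.001,
    "transplant_recipient": 0.001,
    "splenectomy": 0.001,
    "pregnancy": 0.01,
    "osteoarthritis": 0.10,
    "osteoporosis": 0.04,
    "chronic_constipation": 0.03,
    "parkinsons_disease": 0.005,
    "dementia": 0.015,
    "schizophrenia": 0.005,
    "gout": 0.03,
    "dvt_first": 0.005,
    "pe_first": 0.003,
    "continuing_vte_risk": 0.002,
    "peptic_ulcer_uncomplicated": 0.01,
    "erosive_esophagitis": 0.005,
    "insomnia": 0.05,
    "nonmalignant_pain": 0.06,
    "seizure_disorder": 0.005,
    "rem_sleep_disorder": 0.001,
    "alcohol_withdrawal": 0.002,
    "severe_gad": 0.01,
    "end_of_life": 0.003,
    "hypokalemia_cause_resolved": 0.002,
    "bmd_stabilized": 0.005,
    "behavioral_risk_exception": 0.001,
}

# Plausible indication assignments by class tag, used with probability
# ``indication_prob`` when an order's drug carries the tag.
_INDICATION_BY_TAG: list[tuple[str, str]] = [
    ("ppi", "gastroprotection"),
    ("benzodiazepine", "insomnia"),
    ("zopiclone", "insomnia"),
    ("aspirin_antiplatelet", "primary_cv_prevention"),
    ("statin", "primary_cv_prevention"),
    ("loop_diuretic", "gravitational_edema"),
    ("nsaid", "osteoarthritis"),
    ("colchicine", "gout_flare"),
    ("opioid_strong", "nonmalignant_pain"),
    ("opioid_weak_codeine", "nonmalignant_pain"),
    ("opioid_weak_tramadol", "nonmalignant_pain"),
    ("antipsychotic", "behavioral_dementia"),
    ("bisphosphonate", "osteoporosis"),
]

_LAB_VALUE_SPECS: dict[str, tuple[float, float, float, float, str | None]] = {
    # analyte: (mean, sd, lo, hi, unit)
    "serum_potassium": (4.2, 0.4, 3.0, 6.0, "mmol/L"),
    "serum_sodium": (140.0, 3.0, 125.0, 150.0, "mmol/L"),
    "serum_creatinine": (0.09, 0.025, 0.04, 0.40, "mmol/L"),
    "serum_calcium": (2.4, 0.1, 2.0, 2.9, "mmol/L"),
    "uric_acid": (0.38, 0.08, 0.15, 0.70, "mmol/L"),
    "lithium_level": (0.7, 0.15, 0.2, 1.4, "mmol/L"),
    "tsh": (2.0, 0.8, 0.3, 6.0, None),
    "fasting_glucose": (5.5, 0.8, 3.5, 12.0, "mmol/L"),
    "weight": (78.0, 16.0, 40.0, 160.0, "kg"),
    "prolactin": (300.0, 120.0, 50.0, 1200.0, None),
}
_MARKER_ANALYTES = (
    "lipid_profile",
    "full_blood_count",
    "liver_function",
    "ecg",
    "cv_assessment",
    "bmd_scan",
)

_DOSE_CHOICES = (2.5, 5.0, 10.0, 20.0, 25.0, 40.0, 50.0, 100.0)


@dataclass(frozen=True)
class MedCountDistribution:
    """Fitted two-component medication-count mixture with closed-form tails."""

    p_high: float  # mixture weight of the heavy-use (5+) component
    continue_prob: float  # geometric continuation probability q of the 5+ tail
    low_pmf: tuple[float, ...]  # pmf over counts 0..4 within the low component

    def pmf(self, k: int) -> float:
        if k < 0:
            return 0.0
        if k < 5:
            return (1.0 - self.p_high) * self.low_pmf[k]
        q = self.continue_prob
        return self.p_high * (1.0 - q) * q ** (k - 5)

    def tail(self, k: int) -> float:
        """P(count >= k), exact."""
        if k <= 0:
            return 1.0
        if k <= 5:
            return (1.0 - self.p_high) * sum(self.low_pmf[k:]) + self.p_high
        return self.p_high * self.continue_prob ** (k - 5)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        high = rng.random(n) < self.p_high
        low_draws = rng.choice(5, size=n, p=np.asarray(self.low_pmf))
        # numpy geometric counts trials to first success (>=1); shift to 0-based
        high_draws = 5 + rng.geometric(1.0 - self.continue_prob, size=n) - 1
        return np.where(high, high_draws, low_draws)


def calibrate_med_count(
    target_ge5: float = DEFAULT_TARGET_GE5, target_ge11: float = DEFAULT_TARGET_GE11
) -> MedCountDistribution:
    """Fit the count mixture so that P(>=5) and P(>=11) match the targets.

    The mixture has closed-form tails, so both targets are met exactly
    (well within 1e-4). Infeasible orderings raise ``ValueError``.
    """
    if not (0.0 < target_ge11 < target_ge5 < 1.0):
        raise ValueError(
            f"need 0 < target_ge11 < target_ge5 < 1, got ({target_ge5}, {target_ge11})"
        )
    continue_prob = float((target_ge11 / target_ge5) ** (1.0 / 6.0))
    weights = np.array([_LOW_SHAPE_RATIO**k for k in range(5)])
    low_pmf = tuple(float(w) for w in weights / weights.sum())
    return MedCountDistribution(
        p_high=float(target_ge5), continue_prob=continue_prob, low_pmf=low_pmf
    )


@dataclass
class SynthParams:
    n_patients: int
    seed: int
    target_ge5: float = DEFAULT_TARGET_GE5
    target_ge11: float = DEFAULT_TARGET_GE11
    index_date: dt.date = DEFAULT_INDEX_DATE
    condition_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PREVALENCES)
    )
    lab_overdue_prob: float = 0.2
    indication_prob: float = 0.4
    flu_vaccine_prob: float = 0.55
    planted_rules: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("lab_overdue_prob", "indication_prob", "flu_vaccine_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for code, p in self.condition_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {code} outside [0, 1]")


def _draw_lab(
    rng: np.random.Generator,
    analyte: str,
    index: dt.date,
    overdue: bool,
    window_days: int = 180,
) -> LabResult:
    if overdue:
        days_ago = int(rng.integers(window_days + 30, window_days * 4))
    else:
        days_ago = int(rng.integers(0, window_days))
    date = index - dt.timedelta(days=days_ago)
    if analyte in _LAB_VALUE_SPECS:
        mean, sd, lo, hi, unit = _LAB_VALUE_SPECS[analyte]
        value = float(np.clip(rng.normal(mean, sd), lo, hi))
        return LabResult(analyte, date, value=round(value, 3), unit=unit)
    return LabResult(analyte, date, marker="done")


def _patient_labs(
    rng: np.random.Generator,
    tags: set[str],
    index: dt.date,
    overdue_prob: float,
) -> list[LabResult]:
    wanted: list[str] = []
    if rng.random() < 0.7:
        wanted += ["serum_creatinine"]
    if tags & {"diuretic", "ace_inhibitor", "arb", "potassium_supplement", "potassium_sparing"}:
        wanted += ["serum_potassium"]
    if "allopurinol" in tags:
        wanted += ["uric_acid"]
    if "lithium" in tags:
        wanted += ["lithium_level", "tsh", "serum_sodium", "serum_calcium", "ecg"]
    if "atypical_antipsychotic" in tags:
        wanted += ["full_blood_count", "lipid_profile", "weight", "fasting_glucose"]
    if "statin" in tags:
        wanted += ["lipid_profile"]
    labs = []
    for analyte in dict.fromkeys(wanted):  # preserve order, dedupe
        if rng.random() < 0.85:  # a sliver of never-tested patients
            labs.append(_draw_lab(rng, analyte, index, rng.random() < overdue_prob))
    return labs


def _indication_for(
    rng: np.random.Generator, tags: frozenset[str], prob: float
) -> str | None:
    if rng.random() >= prob:
        return None
    for tag, indication in _INDICATION_BY_TAG:
        if tag in tags:
            return indication
    return None


def generate_population(params: SynthParams, formulary: Formulary | None = None) -> list[PatientRecord]:
    """Generate a reproducible synthetic population.

    The output is a pure function of ``params``: identical parameters
    (including the seed) give an identical bundle. Planted rule-trigger
    patients, when requested, are appended after the ``n_patients`` random
    records with ids ``planted-<RULE-ID>``.
    """
    fm = formulary if formulary is not None else default_formulary()
    rng = np.random.default_rng(params.seed)
    dist = calibrate_med_count(params.target_ge5, params.target_ge11)
    index = params.index_date
    counts = dist.sample(rng, params.n_patients)
    drug_codes = sorted(fm.entries)
    prevalences = sorted(params.condition_prevalences.items())

    records: list[PatientRecord] = []
    for i in range(params.n_patients):
        age = int(np.clip(rng.normal(52.0, 19.0), 18, 95))
        birth = index - relativedelta(years=age, days=int(rng.integers(0, 365)))
        sex = str(rng.choice(["female", "male", "other"], p=[0.5, 0.49, 0.01]))
        rec = PatientRecord(patient_id=f"synth-{i:05d}", birth_date=birth, sex=sex)

        for code, prev in prevalences:
            if rng.random() < prev:
                onset_days = int(rng.integers(30, 4000))
                onset = max(index - dt.timedelta(days=onset_days), birth + dt.timedelta(days=365))
                rec.conditions.append(ConditionRecord(code, onset))

        n_meds = int(counts[i])
        if n_meds > 0:
            chosen = rng.choice(len(drug_codes), size=min(n_meds, len(drug_codes)), replace=False)
            for j in sorted(chosen):
                code = drug_codes[j]
                start_ago = int(rng.integers(5, 300))
                start = index - dt.timedelta(days=start_ago)
                supply = start_ago + int(rng.integers(10, 120))  # active at index by design
                rec.medications.append(
                    MedicationOrder(
                        drug_code=code,
                        dose_amount=float(rng.choice(_DOSE_CHOICES)),
                        doses_per_day=float(rng.choice([1, 1, 1, 2, 3])),
                        start_date=start,
                        days_supply=supply,
                        indication_code=_indication_for(
                            rng, fm.classify_drug(code), params.indication_prob
                        ),
                    )
                )

        tag_union: set[str] = set()
        for m in rec.medications:
            tag_union |= fm.classify_drug(m.drug_code)
        rec.labs = _patient_labs(rng, tag_union, index, params.lab_overdue_prob)

        if rng.random() < params.flu_vaccine_prob:
            rec.immunizations.append(
                Immunization(INFLUENZA_VACCINE_CODE, index - dt.timedelta(days=int(rng.integers(0, 400))))
            )

        rec.risk_fields = RiskFields(
            cv_risk_pct=round(float(rng.uniform(2, 35)), 1) if rng.random() < 0.5 else None,
            crcl_ml_min=round(float(rng.uniform(15, 90)), 1) if rng.random() < 0.1 else None,
            weight_kg=round(float(rng.uniform(45, 120)), 1) if rng.random() < 0.8 else None,
        )
        records.append(rec)

    if params.planted_rules:
        for rule_id in params.planted_rules:
            records.append(
                build_trigger_patient(rule_id, index, patient_id=f"planted-{rule_id}")
            )
    return records
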