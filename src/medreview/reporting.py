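"""Polypharmacy metrics, practice audit reports, queries, and trial measures.

Definitions
-----------
*Polypharmacy* is the concurrent use of five or more medicines;
*hyperpolypharmacy* (excessive polypharmacy) the concurrent use of ten or
more. Counts are distinct drug codes active on the evaluation date.

*Inappropriately prescribed medicine* is operationalized as any active
medicine cited in the evidence of a fired stop / reduce-dose / review rule
— inappropriateness is defined by the clinical rule catalog, not by an
external list.

Monthly practice reports recount raw practice-log events for the calendar
month (no cached state) and compute prevalences from the record bundle at
month end; the rule ranking covers exactly the enabled ruleset, most-fired
first.
"""

from __future__ import annotations

import calendar
import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import norm

from . import medhist
from .formulary import Formulary, default_formulary
from .practicelog import PracticeLog
from .records import PatientRecord
from .rule_catalog import default_ruleset, rule_by_id
from .rules_engine import Alert, EngineConfig, RuleDefinition, evaluate_patient

__all__ = [
    "PrevalenceSummary",
    "MonthlyReport",
    "polypharmacy_status",
    "practice_prevalence",
    "flagged_medicines",
    "build_monthly_report",
    "report_to_csv",
    "report_to_html",
    "query_patients",
    "trial_measures",
    "inappropriate_initiation_rate",
    "sample_size_two_proportions",
]

POLYPHARMACY_THRESHOLD = 5
HYPERPOLYPHARMACY_THRESHOLD = 10

_FLAG_ACTIONS = frozenset({"stop", "reduce_dose", "review"})


def polypharmacy_status(record: PatientRecord, as_of: dt.date) -> str:
    """Classify one patient: none (<5), polypharmacy (5-9), hyperpolypharmacy (>=10)."""
    count = medhist.concurrent_count(record, as_of)
    if count >= HYPERPOLYPHARMACY_THRESHOLD:
        return "hyperpolypharmacy"
    if count >= POLYPHARMACY_THRESHOLD:
        return "polypharmacy"
    return "none"


@dataclass(frozen=True)
class PrevalenceSummary:
    prop_ge5: float
    prop_ge10: float
    prop_ge11: float
    mean_meds: float
    n_patients: int


def practice_prevalence(
    records: Sequence[PatientRecord], as_of: dt.date
) -> PrevalenceSummary:
    """Tail proportions and mean concurrent medicine count at ``as_of``."""
    if not records:
        raise ValueError("practice_prevalence requires a non-empty collection")
    counts = [medhist.concurrent_count(r, as_of) for r in records]
    n = len(counts)
    return PrevalenceSummary(
        prop_ge5=sum(c >= 5 for c in counts) / n,
        prop_ge10=sum(c >= 10 for c in counts) / n,
        prop_ge11=sum(c >= 11 for c in counts) / n,
        mean_meds=sum(counts) / n,
        n_patients=n,
    )


def _evidence_drugs(alert: Alert) -> set[str]:
    return {e.split(":")[1] for e in alert.evidence if e.startswith("med:")}


def flagged_medicines(
    records: Sequence[PatientRecord],
    as_of: dt.date,
    ruleset: Sequence[RuleDefinition] | None = None,
    formulary: Formulary | None = None,
    config: EngineConfig | None = None,
) -> set[tuple[str, str]]:
    """Distinct (patient_id, drug_code) pairs cited by stop/reduce/review alerts."""
    rules = list(ruleset) if ruleset is not None else default_ruleset()
    flagged: set[tuple[str, str]] = set()
    for rec in records:
        for alert in evaluate_patient(rec, rules, as_of, "silent", formulary, config):
            if alert.action_kind in _FLAG_ACTIONS:
                for drug in _evidence_drugs(alert):
                    flagged.add((rec.patient_id, drug))
    return flagged


@dataclass(frozen=True)
class MonthlyReport:
    practice_id: str
    month: str  # "YYYY-MM"
    n_patients: int
    prop_polypharmacy: float
    prop_hyperpolypharmacy: float
    mean_meds_per_patient: float
    n_flagged_medicines: int
    n_alerts_emitted: int
    n_engagements: int
    n_changes: int
    rules_ranked: tuple[tuple[str, int], ...]  # most-fired first, full ruleset
    deltas: dict | None  # vs previous calendar month, when computable


def _month_bounds(month: str) -> tuple[dt.date, dt.date]:
    year, mon = (int(p) for p in month.split("-"))
    start = dt.date(year, mon, 1)
    end = dt.date(year + (mon == 12), mon % 12 + 1, 1)
    return start, end


def _month_end(month: str) -> dt.date:
    year, mon = (int(p) for p in month.split("-"))
    return dt.date(year, mon, calendar.monthrange(year, mon)[1])


def _prev_month(month: str) -> str:
    year, mon = (int(p) for p in month.split("-"))
    if mon == 1:
        return f"{year - 1}-12"
    return f"{year}-{mon - 1:02d}"


def build_monthly_report(
    log: PracticeLog,
    records: Sequence[PatientRecord],
    month: str,
    ruleset: Sequence[RuleDefinition] | None = None,
    formulary: Formulary | None = None,
    config: EngineConfig | None = None,
    _with_deltas: bool = True,
) -> MonthlyReport:
    """One practice's progress report for a calendar month (``"YYYY-MM"``).

    Counters recount the raw log events inside the month; prevalences and
    flagged-medicine counts are evaluated against the records at the last
    day of the month. The previous month's report, when the log window
    covers it, supplies month-over-month deltas.
    """
    rules = list(ruleset) if ruleset is not None else default_ruleset()
    start, end = _month_bounds(month)
    if log.events and not any(start <= e.date < end for e in log.events):
        all_dates = [e.date for e in log.events]
        if start > max(all_dates) or end <= min(all_dates):
            raise ValueError(f"month {month} outside the log window")
    as_of = _month_end(month)
    prev = practice_prevalence(records, as_of)
    month_events = log.events_in(start, end)
    per_rule = {r.rule_id: 0 for r in rules}
    for e in month_events:
        if e.kind == "alert_emitted" and e.rule_id in per_rule:
            per_rule[e.rule_id] += 1
    ranked = tuple(
        sorted(per_rule.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    flagged = flagged_medicines(records, as_of, rules, formulary, config)

    report = MonthlyReport(
        practice_id=log.practice_id,
        month=month,
        n_patients=prev.n_patients,
        prop_polypharmacy=prev.prop_ge5,
        prop_hyperpolypharmacy=prev.prop_ge10,
        mean_meds_per_patient=prev.mean_meds,
        n_flagged_medicines=len(flagged),
        n_alerts_emitted=sum(1 for e in month_events if e.kind == "alert_emitted"),
        n_engagements=sum(1 for e in month_events if e.kind == "engaged"),
        n_changes=sum(1 for e in month_events if e.kind == "accepted_changed"),
        rules_ranked=ranked,
        deltas=None,
    )
    if not _with_deltas:
        return report
    prev_month = _prev_month(month)
    prev_start, prev_end = _month_bounds(prev_month)
    if any(prev_start <= e.date < prev_end for e in log.events):
        prior = build_monthly_report(
            log, records, prev_month, rules, formulary, config, _with_deltas=False
        )
        deltas = {
            "prop_polypharmacy": report.prop_polypharmacy - prior.prop_polypharmacy,
            "prop_hyperpolypharmacy": (
                report.prop_hyperpolypharmacy - prior.prop_hyperpolypharmacy
            ),
            "mean_meds_per_patient": (
                report.mean_meds_per_patient - prior.mean_meds_per_patient
            ),
            "n_alerts_emitted": report.n_alerts_emitted - prior.n_alerts_emitted,
            "n_engagements": report.n_engagements - prior.n_engagements,
            "n_changes": report.n_changes - prior.n_changes,
        }
        return MonthlyReport(**{**report.__dict__, "deltas": deltas})
    return report


_REPORT_FIELDS = [
    "practice_id",
    "month",
    "n_patients",
    "prop_polypharmacy",
    "prop_hyperpolypharmacy",
    "mean_meds_per_patient",
    "n_flagged_medicines",
    "n_alerts_emitted",
    "n_engagements",
    "n_changes",
]


def report_to_csv(report: MonthlyReport, path: str | Path) -> None:
    lines = ["field,value"]
    for name in _REPORT_FIELDS:
        lines.append(f"{name},{getattr(report, name)}")
    for rule_id, count in report.rules_ranked:
        lines.append(f"rule_triggers:{rule_id},{count}")
    if report.deltas:
        for name, value in report.deltas.items():
            lines.append(f"delta:{name},{value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def report_to_html(report: MonthlyReport, path: str | Path) -> None:
    """A small static HTML summary of the monthly report."""
    most = report.rules_ranked[:5]
    least = report.rules_ranked[-5:]
    rows = "\n".join(
        f"<tr><td>{name}</td><td>{getattr(report, name)}</td></tr>"
        for name in _REPORT_FIELDS
    )
    rank_rows = "\n".join(
        f"<tr><td>{rid}</td><td>{n}</td></tr>" for rid, n in most
    )
    tail_rows = "\n".join(
        f"<tr><td>{rid}</td><td>{n}</td></tr>" for rid, n in least
    )
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Practice report {report.practice_id} {report.month}</title></head>
<body>
<h1>Practice {report.practice_id} — {report.month}</h1>
<table border="1">{rows}</table>
<h2>Most-triggered rules</h2>
<table border="1">{rank_rows}</table>
<h2>Least-triggered rules</h2>
<table border="1">{tail_rows}</table>
</body></html>
"""
    Path(path).write_text(html, encoding="utf-8")


def query_patients(
    records: Sequence[PatientRecord],
    criterion: str,
    as_of: dt.date,
    rule_id: str | None = None,
    ruleset: Sequence[RuleDefinition] | None = None,
    formulary: Formulary | None = None,
    config: EngineConfig | None = None,
) -> list[str]:
    """Patient ids matching a query-builder criterion, sorted.

    Criteria: ``polypharmacy`` (>=5 concurrent medicines),
    ``hyperpolypharmacy`` (>=10; these patients also match ``polypharmacy``),
    ``flagged_for_review`` (any stop/reduce/review/monitor rule fires, or a
    specific ``rule_id``).
    """
    if criterion in {"polypharmacy", "hyperpolypharmacy"}:
        threshold = (
            POLYPHARMACY_THRESHOLD
            if criterion == "polypharmacy"
            else HYPERPOLYPHARMACY_THRESHOLD
        )
        return sorted(
            r.patient_id
            for r in records
            if medhist.concurrent_count(r, as_of) >= threshold
        )
    if criterion == "flagged_for_review":
        rules = list(ruleset) if ruleset is not None else default_ruleset()
        if rule_id is not None:
            rule_by_id(rule_id)  # raises KeyError on unknown ids
        out = []
        for rec in records:
            alerts = evaluate_patient(rec, rules, as_of, "silent", formulary, config)
            if rule_id is not None:
                if any(a.rule_id == rule_id for a in alerts):
                    out.append(rec.patient_id)
            elif alerts:
                out.append(rec.patient_id)
        return sorted(out)
    raise ValueError(f"unknown criterion {criterion!r}")


def inappropriate_initiation_rate(
    records: Sequence[PatientRecord],
    start: dt.date,
    end: dt.date,
    ruleset: Sequence[RuleDefinition] | None = None,
    formulary: Formulary | None = None,
    config: EngineConfig | None = None,
) -> float:
    """New orders per patient-month that fire a rule at their initiation date.

    An initiation is *inappropriate* when, evaluated on its own start date,
    the new order is cited in the evidence of a stop/reduce/review alert.
    """
    if end <= start:
        raise ValueError("end must follow start")
    rules = list(ruleset) if ruleset is not None else default_ruleset()
    n_inappropriate = 0
    for rec in records:
        for order in rec.medications:
            if not (start <= order.start_date < end):
                continue
            alerts = evaluate_patient(
                rec, rules, order.start_date, "silent", formulary, config
            )
            for alert in alerts:
                if alert.action_kind in _FLAG_ACTIONS and order.element_id in alert.evidence:
                    n_inappropriate += 1
                    break
    patient_months = len(records) * (end - start).days / 30.4375
    return n_inappropriate / patient_months if patient_months else 0.0


def _arm_measures(
    logs: Sequence[PracticeLog],
    records_before: tuple[dt.date, Sequence[PatientRecord]],
    records_after: tuple[dt.date, Sequence[PatientRecord]],
    rules: Sequence[RuleDefinition],
    formulary: Formulary | None,
    config: EngineConfig | None,
) -> dict:
    date_before, recs_before = records_before
    date_after, recs_after = records_after
    prev_b = practice_prevalence(recs_before, date_before)
    prev_a = practice_prevalence(recs_after, date_after)
    flagged_b = flagged_medicines(recs_before, date_before, rules, formulary, config)
    flagged_a = flagged_medicines(recs_after, date_after, rules, formulary, config)
    patients_flagged_a = {pid for pid, _ in flagged_a}
    outcome_counts = {detail: 0 for detail in ("gp_visit", "ed_visit", "admission", "death")}
    totals = {
        k: 0
        for k in ("alert_emitted", "engaged", "accepted_changed", "dismissed", "reverted",
                  "lab_ordered")
    }
    for log in logs:
        for e in log.events:
            if e.kind in totals:
                totals[e.kind] += 1
            elif e.kind == "outcome_event":
                outcome_counts[e.detail] += 1
    return {
        "n_engagements": totals["engaged"],
        "n_suggested_interventions": totals["alert_emitted"],
        "n_changes": totals["accepted_changed"],
        "n_dismissed": totals["dismissed"],
        "n_reversions": totals["reverted"],
        "n_lab_orders": totals["lab_ordered"],
        "prop_polypharmacy_before": prev_b.prop_ge5,
        "prop_polypharmacy_after": prev_a.prop_ge5,
        "prop_hyperpolypharmacy_before": prev_b.prop_ge10,
        "prop_hyperpolypharmacy_after": prev_a.prop_ge10,
        "mean_meds_before": prev_b.mean_meds,
        "mean_meds_after": prev_a.mean_meds,
        "n_flagged_medicines_before": len(flagged_b),
        "n_flagged_medicines_after": len(flagged_a),
        "prop_appropriate_treatment_after": (
            1.0 - len(patients_flagged_a) / prev_a.n_patients
        ),
        "inappropriate_initiation_rate": inappropriate_initiation_rate(
            recs_after, date_before, date_after, rules, formulary, config
        )
        if date_after > date_before
        else 0.0,
        "outcome_events": outcome_counts,
    }


def trial_measures(
    intervention_logs: Sequence[PracticeLog],
    control_logs: Sequence[PracticeLog],
    records_before: dict[str, tuple[dt.date, Sequence[PatientRecord]]],
    records_after: dict[str, tuple[dt.date, Sequence[PatientRecord]]],
    ruleset: Sequence[RuleDefinition] | None = None,
    formulary: Formulary | None = None,
    config: EngineConfig | None = None,
) -> dict:
    """Descriptive study measures per arm.

    ``records_before`` / ``records_after`` map arm name ("intervention",
    "control") to a dated snapshot ``(as_of, records)``. Returns a dict of
    labelled values per arm: engagement / suggested-intervention / change /
    reversion / lab-order counts, before-after polypharmacy and
    hyperpolypharmacy proportions and mean medicines per patient, flagged
    medicine counts, the appropriate-treatment proportion, the
    inappropriate-initiation rate per patient-month, and outcome-event
    counts. No inferential statistics are attached.
    """
    if not intervention_logs or not control_logs:
        raise ValueError("both arms must be present")
    for arm in ("intervention", "control"):
        if arm not in records_before or arm not in records_after:
            raise ValueError(f"missing {arm} snapshot")
    rules = list(ruleset) if ruleset is not None else default_ruleset()
    return {
        "intervention": _arm_measures(
            intervention_logs, records_before["intervention"], records_after["intervention"],
            rules, formulary, config,
        ),
        "control": _arm_measures(
            control_logs, records_before["control"], records_after["control"],
            rules, formulary, config,
        ),
    }


def sample_size_two_proportions(
    p1: float, p2: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Patients per arm to detect p1 vs p2 with a two-sided pooled z-test.

    Standard normal-approximation formula with pooled variance under the
    null; the result is rounded up. Equal proportions are undetectable and
    raise ``ValueError``.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must be in (0, 1)")
    if p1 == p2:
        raise ValueError("p1 == p2: no detectable difference")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must be in (0, 1)")
    z_alpha = norm.ppf(1.0 - alpha / 2.0)
    z_beta = norm.ppf(power)
    p_bar = (p1 + p2) / 2.0
    numerator = (
        z_alpha * math.sqrt(2.0 * p_bar * (1.0 - p_bar))
        + z_beta * math.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2))
    ) ** 2
    return math.ceil(numerator / (p1 - p2) ** 2)
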