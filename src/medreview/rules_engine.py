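"""Declarative clinical-rule evaluation with evidence-traced alerts.

A :class:`RuleDefinition` couples a stable id, an action kind (stop,
reduce_dose, review, monitor, initiate, recommend, alert), a parameter map
holding every numeric threshold the predicate reads, and the predicate
itself. Evaluating a rule against one patient record at a date either
produces an :class:`Alert` whose evidence trace lists exactly the record
elements (orders, conditions, labs, risk fields, demographics) that
satisfied each clause, or nothing.

Data-gap policy
---------------
Rules whose predicate depends on an optional clinical value (an order's
indication, the stored cardiovascular risk, a bone-density or risk flag) do
*not* fire when that value is absent. Instead the evaluation records a
machine-readable :class:`DataGap` so the gap can be audited without raising
an alert a prescriber cannot act on — unresolvable alerts are the fastest
route to alert fatigue. Setting ``EngineConfig.assume_worst=True`` flips the
policy: a missing optional value is treated as satisfying the clause.

Display vs silent mode
----------------------
Silent mode is the control-arm mechanism: alerts are computed and logged
exactly as in display mode but flagged ``displayed=False`` so they are never
surfaced at the point of care. Alert content is bit-identical between modes.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

from dateutil.relativedelta import relativedelta

from . import medhist
from .formulary import Formulary, default_formulary
from .practicelog import LogEvent, PracticeLog
from .records import ConditionRecord, MedicationOrder, PatientRecord

__all__ = [
    "ACTION_KINDS",
    "CATEGORIES",
    "RuleDefinition",
    "Alert",
    "DataGap",
    "EngineConfig",
    "EvaluationError",
    "UnknownAlertError",
    "evaluate_rule",
    "evaluate_patient",
    "evaluate_patient_detailed",
    "record_disposition",
    "alerts_to_csv",
    "alerts_to_jsonl",
]

ACTION_KINDS = frozenset(
    {"stop", "reduce_dose", "review", "monitor", "initiate", "recommend", "alert"}
)

CATEGORIES = frozenset(
    {
        "duplicate_therapy",
        "gastroprotectant",
        "constipation",
        "antithrombotic",
        "elderly",
        "psychotropic",
        "analgesic",
        "nsaid",
        "gout",
        "bisphosphonate",
        "metformin",
        "influenza",
        "interaction",
        "monitoring",
    }
)


class EvaluationError(RuntimeError):
    """The record schema lacks a data element the rule requires."""


class UnknownAlertError(KeyError):
    """A disposition referenced an alert never emitted into the log."""


@dataclass(frozen=True)
class RuleDefinition:
    rule_id: str
    category: str
    action_kind: str
    message: str
    required_elements: frozenset[str]
    parameters: dict
    info_link: str
    predicate: Callable[["RuleContext"], "list | None"]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.rule_id}: unknown category {self.category!r}")
        if self.action_kind not in ACTION_KINDS:
            raise ValueError(f"{self.rule_id}: unknown action_kind {self.action_kind!r}")


@dataclass(frozen=True)
class Alert:
    rule_id: str
    patient_id: str
    as_of: dt.date
    action_kind: str
    message: str
    evidence: tuple[str, ...]
    info_link: str
    displayed: bool

    def content_key(self) -> tuple:
        """Identity ignoring the displayed flag (silent-mode equivalence)."""
        return (
            self.rule_id,
            self.patient_id,
            self.as_of,
            self.action_kind,
            self.message,
            self.evidence,
            self.info_link,
        )


@dataclass(frozen=True)
class DataGap:
    """A rule that could not be decided because an optional value is missing."""

    rule_id: str
    patient_id: str
    as_of: dt.date
    field_name: str
    note: str


@dataclass
class EngineConfig:
    assume_worst: bool = False
    max_gap_days: int = medhist.DEFAULT_MAX_GAP_DAYS
    suppression_window_days: int = 90
    rule_parameters: dict = field(default_factory=dict)
    enabled_rules: list[str] | None = None


class RuleContext:
    """Per-evaluation working state handed to rule predicates."""

    def __init__(
        self,
        rule: RuleDefinition,
        record: PatientRecord,
        as_of: dt.date,
        formulary: Formulary,
        config: EngineConfig,
    ):
        self.rule = rule
        self.record = record
        self.as_of = as_of
        self.fm = formulary
        self.config = config
        self.params = {**rule.parameters, **config.rule_parameters.get(rule.rule_id, {})}
        self.gaps: list[DataGap] = []
        self._active: list[MedicationOrder] | None = None

    # -- record access -------------------------------------------------
    @property
    def active(self) -> list[MedicationOrder]:
        if self._active is None:
            self._active = medhist.active_medicines(self.record, self.as_of)
        return self._active

    def tags(self, order: MedicationOrder) -> frozenset[str]:
        return self.fm.classify_drug(order.drug_code)

    def active_with_tag(self, *tags: str) -> list[MedicationOrder]:
        wanted = set(tags)
        return [m for m in self.active if wanted & self.tags(m)]

    def distinct_codes(self, orders: Iterable[MedicationOrder]) -> set[str]:
        return {m.drug_code for m in orders}

    def condition(self, *codes: str) -> ConditionRecord | None:
        for c in self.record.conditions:
            if c.condition_code in codes and c.active_at(self.as_of):
                return c
        return None

    def age(self) -> int:
        return medhist.age_at(self.record, self.as_of)

    def used_longer_than(self, selector, **window) -> bool:
        return medhist.used_longer_than(
            self.record,
            selector,
            self.as_of,
            max_gap_days=self.config.max_gap_days,
            formulary=self.fm,
            **window,
        )

    def episode_orders(self, selector) -> list[MedicationOrder]:
        """Orders overlapping the current use episode of ``selector``."""
        start = medhist.episode_start(
            self.record, selector, self.as_of, self.config.max_gap_days, self.fm
        )
        if start is None:
            return []
        orders = medhist._matching_orders(self.record, selector, self.fm)
        return [m for m in orders if m.start_date <= self.as_of and m.effective_end > start]

    def stale(self, analytes, *, months: int = 0, years: int = 0) -> bool:
        return medhist.result_older_than(
            self.record, analytes, self.as_of, months=months, years=years
        )

    def last_result(self, analyte: str):
        return medhist.last_result(self.record, analyte, self.as_of)

    # -- gap handling ---------------------------------------------------
    def gap(self, field_name: str, note: str) -> bool:
        """Record a data gap; returns assume_worst so callers can write
        ``if value_missing: satisfied = ctx.gap("field", "...")``."""
        self.gaps.append(
            DataGap(self.rule.rule_id, self.record.patient_id, self.as_of, field_name, note)
        )
        return self.config.assume_worst

    # -- evidence helpers ----------------------------------------------
    @staticmethod
    def ev(*items) -> list[str]:
        out: list[str] = []
        for item in items:
            if item is None:
                continue
            if isinstance(item, str):
                out.append(item)
            elif isinstance(item, (list, tuple, set, frozenset)):
                out.extend(RuleContext.ev(*item))
            else:
                out.append(item.element_id)
        # de-duplicate preserving order
        seen: set[str] = set()
        uniq = [e for e in out if not (e in seen or seen.add(e))]
        return uniq


_REQUIRED_ATTRS = {
    "medications": "medications",
    "conditions": "conditions",
    "labs": "labs",
    "immunizations": "immunizations",
    "risk_fields": "risk_fields",
    "demographics": "birth_date",
}


def evaluate_rule(
    rule: RuleDefinition,
    record: PatientRecord,
    as_of: dt.date,
    formulary: Formulary | None = None,
    config: EngineConfig | None = None,
    displayed: bool = True,
    gaps: list[DataGap] | None = None,
) -> Alert | None:
    """Evaluate one rule against one record; Alert iff the predicate holds.

    ``gaps``, when given, collects :class:`DataGap` notes emitted by the
    predicate. Evaluation is deterministic and side-effect free on the
    record.
    """
    fm = formulary if formulary is not None else default_formulary()
    cfg = config if config is not None else EngineConfig()
    for element in rule.required_elements:
        attr = _REQUIRED_ATTRS.get(element)
        if attr is None or not hasattr(record, attr):
            raise EvaluationError(
                f"{rule.rule_id}: record schema lacks required element {element!r}"
            )
    ctx = RuleContext(rule, record, as_of, fm, cfg)
    evidence = rule.predicate(ctx)
    if gaps is not None:
        gaps.extend(ctx.gaps)
    if not evidence:
        return None
    return Alert(
        rule_id=rule.rule_id,
        patient_id=record.patient_id,
        as_of=as_of,
        action_kind=rule.action_kind,
        message=rule.message,
        evidence=tuple(evidence),
        info_link=rule.info_link,
        displayed=displayed,
    )


def _suppressed(
    log: PracticeLog | None, patient_id: str, rule_id: str, as_of: dt.date, window_days: int
) -> bool:
    if log is None:
        return False
    dismissed = log.last_dismissal(patient_id, rule_id, as_of)
    return dismissed is not None and (as_of - dismissed).days <= window_days


def evaluate_patient_detailed(
    record: PatientRecord,
    ruleset: Sequence[RuleDefinition],
    as_of: dt.date,
    mode: str = "display",
    formulary: Formulary | None = None,
    config: EngineConfig | None = None,
    log: PracticeLog | None = None,
) -> tuple[list[Alert], list[DataGap]]:
    """As :func:`evaluate_patient`, additionally returning data-gap notes."""
    if not ruleset:
        raise ValueError("ruleset must be non-empty")
    if mode not in {"display", "silent"}:
        raise ValueError(f"mode must be display or silent, got {mode!r}")
    cfg = config if config is not None else EngineConfig()
    fm = formulary if formulary is not None else default_formulary()
    displayed = mode == "display"
    alerts: list[Alert] = []
    gaps: list[DataGap] = []
    for rule in ruleset:
        if cfg.enabled_rules is not None and rule.rule_id not in cfg.enabled_rules:
            continue
        if _suppressed(log, record.patient_id, rule.rule_id, as_of, cfg.suppression_window_days):
            continue
        alert = evaluate_rule(rule, record, as_of, fm, cfg, displayed=displayed, gaps=gaps)
        if alert is not None:
            alerts.append(alert)
    return alerts, gaps


def evaluate_patient(
    record: PatientRecord,
    ruleset: Sequence[RuleDefinition],
    as_of: dt.date,
    mode: str = "display",
    formulary: Formulary | None = None,
    config: EngineConfig | None = None,
    log: PracticeLog | None = None,
) -> list[Alert]:
    """Evaluate the whole catalog against one patient, in catalog order.

    At most one alert per (patient, rule): when several drug pairs match a
    rule, all matches appear in one alert's evidence. In silent mode every
    alert carries ``displayed=False`` but is otherwise identical. When a
    ``log`` is supplied, alerts dismissed within the suppression window are
    withheld.
    """
    alerts, _ = evaluate_patient_detailed(record, ruleset, as_of, mode, formulary, config, log)
    return alerts


def record_disposition(
    alert: Alert,
    disposition: str,
    log: PracticeLog,
    date: dt.date | None = None,
) -> PracticeLog:
    """Append a prescriber disposition for an emitted alert.

    The alert must already have been emitted into the log
    (``log.record_alert``); dispositions on unknown alerts are an error.
    A ``dismissed`` disposition suppresses re-alerting for the same
    (patient, rule) for the configured suppression window.
    """
    if disposition not in {"accepted_changed", "dismissed", "deferred"}:
        raise ValueError(f"unknown disposition {disposition!r}")
    if not log.has_emission(alert.patient_id, alert.rule_id, alert.as_of):
        raise UnknownAlertError(
            f"no emitted alert for ({alert.patient_id}, {alert.rule_id}, {alert.as_of})"
        )
    log.add(
        LogEvent(
            alert.patient_id,
            alert.rule_id,
            disposition,
            date if date is not None else alert.as_of,
        )
    )
    return log


# --------------------------------------------------------------------------
# alert export

_ALERT_COLS = [
    "rule_id",
    "patient_id",
    "as_of",
    "action_kind",
    "message",
    "evidence",
    "info_link",
    "displayed",
]


def alerts_to_csv(alerts: Iterable[Alert], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ALERT_COLS)
        for a in alerts:
            writer.writerow(
                [
                    a.rule_id,
                    a.patient_id,
                    a.as_of.isoformat(),
                    a.action_kind,
                    a.message,
                    ";".join(a.evidence),
                    a.info_link,
                    "true" if a.displayed else "false",
                ]
            )


def alerts_to_jsonl(alerts: Iterable[Alert], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in alerts:
            fh.write(
                json.dumps(
                    {
                        "rule_id": a.rule_id,
                        "patient_id": a.patient_id,
                        "as_of": a.as_of.isoformat(),
                        "action_kind": a.action_kind,
                        "message": a.message,
                        "evidence": list(a.evidence),
                        "info_link": a.info_link,
                        "displayed": a.displayed,
                    }
                )
                + "\n"
            )
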