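"""Append-only practice event log.

Every observable event in a practice — an alert being emitted (displayed or
silent), a prescriber engaging with it, a disposition (change made,
dismissed, deferred), a later reversion, a suggested laboratory test being
ordered, and coded outcome events (GP visits, admissions, deaths) — is one
time-stamped row. Reports never cache state: every counter is a recount of
these raw events.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

__all__ = ["EVENT_KINDS", "OUTCOME_DETAILS", "LogEvent", "PracticeLog"]

EVENT_KINDS = frozenset(
    {
        "alert_emitted",
        "engaged",
        "accepted_changed",
        "dismissed",
        "deferred",
        "reverted",
        "lab_ordered",
        "outcome_event",
    }
)

OUTCOME_DETAILS = frozenset({"gp_visit", "ed_visit", "admission", "death"})


@dataclass(frozen=True)
class LogEvent:
    patient_id: str
    rule_id: str | None
    kind: str
    date: dt.date
    detail: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "outcome_event" and self.detail not in OUTCOME_DETAILS:
            raise ValueError(f"outcome_event requires detail in {sorted(OUTCOME_DETAILS)}")


@dataclass
class PracticeLog:
    practice_id: str
    arm: str  # "intervention" | "control"
    events: list[LogEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.arm not in {"intervention", "control"}:
            raise ValueError(f"arm must be intervention or control, got {self.arm!r}")

    def add(self, event: LogEvent) -> None:
        self.events.append(event)

    def record_alert(self, alert) -> None:
        """Log the emission of an Alert (works for displayed and silent alerts)."""
        self.add(LogEvent(alert.patient_id, alert.rule_id, "alert_emitted", alert.as_of))

    def has_emission(self, patient_id: str, rule_id: str, date: dt.date) -> bool:
        return any(
            e.kind == "alert_emitted"
            and e.patient_id == patient_id
            and e.rule_id == rule_id
            and e.date == date
            for e in self.events
        )

    def last_dismissal(self, patient_id: str, rule_id: str, before: dt.date) -> dt.date | None:
        dates = [
            e.date
            for e in self.events
            if e.kind == "dismissed"
            and e.patient_id == patient_id
            and e.rule_id == rule_id
            and e.date <= before
        ]
        return max(dates) if dates else None

    def events_in(self, start: dt.date, end: dt.date) -> list[LogEvent]:
        """Events with start <= date < end."""
        return [e for e in self.events if start <= e.date < end]

    def count(self, kind: str, start: dt.date | None = None, end: dt.date | None = None) -> int:
        return sum(
            1
            for e in self.events
            if e.kind == kind
            and (start is None or e.date >= start)
            and (end is None or e.date < end)
        )


_LOG_COLS = ["patient_id", "rule_id", "kind", "date", "detail"]


def save_log_csv(log: PracticeLog, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["practice_id", "arm"])
        writer.writerow([log.practice_id, log.arm])
        writer.writerow(_LOG_COLS)
        for e in log.events:
            writer.writerow([e.patient_id, e.rule_id or "", e.kind, e.date.isoformat(),
                             e.detail or ""])


def load_log_csv(path) -> PracticeLog:
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["practice_id", "arm"]:
            raise ValueError("log file must start with a practice_id,arm header pair")
        practice_id, arm = next(reader)
        cols = next(reader)
        if cols != _LOG_COLS:
            raise ValueError(f"log file columns must be {_LOG_COLS}")
        log = PracticeLog(practice_id, arm)
        for row in reader:
            pid, rule_id, kind, date, detail = row
            log.add(
                LogEvent(pid, rule_id or None, kind, dt.date.fromisoformat(date),
                         detail or None)
            )
    return log
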