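"""Temporal medication-history algebra.

Everything the rule catalog asks about time reduces to a handful of
primitives over one patient record and an evaluation date ``as_of``:

* which orders are *active* (half-open supply interval contains ``as_of``),
* how many *distinct* medicines are concurrently active,
* how long the current *continuous-use episode* of a drug or class has run,
  where refill gaps up to ``max_gap_days`` (default 7, a dispensing lag)
  do not break the episode,
* the total *daily dose* over concurrently active orders,
* how *recent* the latest laboratory result of an analyte is, and
* calendar age and an estimated creatinine clearance.

All "N months/years" windows are calendar arithmetic via
``dateutil.relativedelta``, never 30-day approximations, and comparator
strictness follows the clinical phrasing exactly: "taken for >6 months" from
2024-01-15 is satisfied strictly after 2024-07-15.

Selectors
---------
Operations that accept a *selector* take a drug code, a class tag, or a
set of class tags (matched as a union). When a token is both a drug code
and a class tag (e.g. ``"zopiclone"``), the class-tag reading wins — rules
are phrased over classes.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Iterable, Sequence

from dateutil.relativedelta import relativedelta

from .formulary import CLASS_TAGS, Formulary, UnknownDrugError, default_formulary
from .records import LabResult, MedicationOrder, PatientRecord

__all__ = [
    "NEVER_TESTED",
    "DEFAULT_MAX_GAP_DAYS",
    "UnknownClassError",
    "UnitMismatchError",
    "InvalidLabError",
    "active_medicines",
    "concurrent_count",
    "use_episodes",
    "episode_start",
    "continuous_use_duration",
    "used_longer_than",
    "daily_dose",
    "class_daily_dose",
    "last_result",
    "latest_result_age",
    "result_older_than",
    "age_at",
    "estimate_crcl",
]

DEFAULT_MAX_GAP_DAYS = 7

#: Marker for "no qualifying result on record"; compares greater than any
#: finite recency window, so a never-tested patient is maximally stale.
NEVER_TESTED = math.inf


class UnknownClassError(KeyError):
    def __init__(self, selector: str):
        super().__init__(selector)
        self.selector = selector

    def __str__(self) -> str:
        return f"selector {self.selector!r} is neither a class tag nor a known drug code"


class UnitMismatchError(ValueError):
    pass


class InvalidLabError(ValueError):
    pass


Selector = str | frozenset | tuple | set | list


def _matching_orders(
    record: PatientRecord, selector: Selector, formulary: Formulary | None
) -> list[MedicationOrder]:
    """Orders matching a drug code, class tag, or union of class tags."""
    if isinstance(selector, str):
        if selector in CLASS_TAGS:
            fm = formulary if formulary is not None else default_formulary()
            codes = fm.drugs_with_tag(selector)
            return [m for m in record.medications if m.drug_code in codes]
        fm = formulary if formulary is not None else default_formulary()
        if selector not in fm and not any(m.drug_code == selector for m in record.medications):
            raise UnknownClassError(selector)
        return [m for m in record.medications if m.drug_code == selector]
    tags = set(selector)
    bad = tags - CLASS_TAGS
    if bad:
        raise UnknownClassError(sorted(bad)[0])
    fm = formulary if formulary is not None else default_formulary()
    codes = set().union(*(fm.drugs_with_tag(t) for t in tags)) if tags else set()
    return [m for m in record.medications if m.drug_code in codes]


def active_medicines(record: PatientRecord, as_of: dt.date) -> list[MedicationOrder]:
    """Orders whose half-open interval [start, start+supply) contains ``as_of``.

    Stable order: by start_date, then drug_code.
    """
    active = [m for m in record.medications if m.active_at(as_of)]
    active.sort(key=lambda m: (m.start_date, m.drug_code))
    return active


def concurrent_count(
    record: PatientRecord,
    as_of: dt.date,
    counting: str = "distinct_drug_codes",
    formulary: Formulary | None = None,
) -> int:
    """Number of concurrently active medicines under the chosen counting unit.

    The polypharmacy literature counts distinct medicines, so two overlapping
    orders of one drug count once.
    """
    active = active_medicines(record, as_of)
    if counting == "distinct_drug_codes":
        return len({m.drug_code for m in active})
    if counting == "distinct_class_tags":
        fm = formulary if formulary is not None else default_formulary()
        tags: set[str] = set()
        for m in active:
            tags |= fm.classify_drug(m.drug_code)
        return len(tags)
    raise ValueError(f"unknown counting unit {counting!r}")


def _merge_intervals(
    intervals: Sequence[tuple[dt.date, dt.date]], max_gap_days: int
) -> list[tuple[dt.date, dt.date]]:
    """Merge [start, end) intervals, bridging gaps of at most ``max_gap_days``."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [ordered[0]]
    gap = dt.timedelta(days=max_gap_days)
    for start, end in ordered[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end + gap:
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def use_episodes(
    record: PatientRecord,
    selector: Selector,
    max_gap_days: int = DEFAULT_MAX_GAP_DAYS,
    formulary: Formulary | None = None,
) -> list[tuple[dt.date, dt.date]]:
    """Stitched [start, end) use episodes of the selected drug or class."""
    if max_gap_days < 0:
        raise ValueError("max_gap_days must be >= 0")
    orders = _matching_orders(record, selector, formulary)
    return _merge_intervals([(m.start_date, m.effective_end) for m in orders], max_gap_days)


def episode_start(
    record: PatientRecord,
    selector: Selector,
    as_of: dt.date,
    max_gap_days: int = DEFAULT_MAX_GAP_DAYS,
    formulary: Formulary | None = None,
) -> dt.date | None:
    """Start of the episode containing ``as_of``, or None.

    ``as_of`` is *in* an episode while supply lasts and through the grace
    gap after it ends (a refill up to ``max_gap_days`` late would have
    merged), so continuity is judged consistently with episode stitching.
    """
    grace = dt.timedelta(days=max_gap_days)
    for start, end in use_episodes(record, selector, max_gap_days, formulary):
        if start <= as_of < end + grace:
            return start
    return None


def continuous_use_duration(
    record: PatientRecord,
    selector: Selector,
    as_of: dt.date,
    max_gap_days: int = DEFAULT_MAX_GAP_DAYS,
    formulary: Formulary | None = None,
) -> int:
    """Days of continuous use up to ``as_of``, inclusive of the start day.

    0 when ``as_of`` falls outside every stitched episode. The first day of
    supply counts as day 1, so a 28-day order satisfies "taken for >= 4
    weeks" on its final covered day.
    """
    start = episode_start(record, selector, as_of, max_gap_days, formulary)
    if start is None:
        return 0
    return (as_of - start).days + 1


def used_longer_than(
    record: PatientRecord,
    selector: Selector,
    as_of: dt.date,
    *,
    months: int = 0,
    years: int = 0,
    days: int = 0,
    max_gap_days: int = DEFAULT_MAX_GAP_DAYS,
    formulary: Formulary | None = None,
) -> bool:
    """Strict calendar test: current episode has run for more than the window."""
    start = episode_start(record, selector, as_of, max_gap_days, formulary)
    if start is None:
        return False
    return start + relativedelta(years=years, months=months, days=days) < as_of


def daily_dose(record: PatientRecord, drug_code: str, as_of: dt.date) -> float:
    """Total daily dose of ``drug_code`` over concurrently active orders.

    Returned in the orders' dose unit; mixing units across summed orders is
    an error rather than a silent mg/µg blend.
    """
    active = [m for m in record.medications if m.drug_code == drug_code and m.active_at(as_of)]
    if not active:
        return 0.0
    units = {m.dose_unit for m in active}
    if len(units) > 1:
        raise UnitMismatchError(
            f"{drug_code}: mixed dose units across active orders: {sorted(units)}"
        )
    return sum(m.dose_amount * m.doses_per_day for m in active)


def class_daily_dose(
    record: PatientRecord,
    tag: str,
    as_of: dt.date,
    formulary: Formulary | None = None,
) -> float:
    """Summed daily dose over all active orders carrying class ``tag``."""
    orders = [m for m in _matching_orders(record, tag, formulary) if m.active_at(as_of)]
    units = {m.dose_unit for m in orders}
    if len(units) > 1:
        raise UnitMismatchError(f"class {tag}: mixed dose units: {sorted(units)}")
    return sum(m.dose_amount * m.doses_per_day for m in orders)


def last_result(
    record: PatientRecord, analyte_code: str, as_of: dt.date
) -> LabResult | None:
    """Most recent result of ``analyte_code`` dated on or before ``as_of``."""
    candidates = [
        lab for lab in record.labs if lab.analyte_code == analyte_code and lab.result_date <= as_of
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda lab: lab.result_date)


def latest_result_age(record: PatientRecord, analyte_code: str, as_of: dt.date) -> float:
    """Days since the most recent result, or :data:`NEVER_TESTED`."""
    lab = last_result(record, analyte_code, as_of)
    if lab is None:
        return NEVER_TESTED
    return float((as_of - lab.result_date).days)


def result_older_than(
    record: PatientRecord,
    analyte_codes: str | Iterable[str],
    as_of: dt.date,
    *,
    months: int = 0,
    years: int = 0,
) -> bool:
    """True when no result among ``analyte_codes`` falls inside the window.

    The window is strict calendar arithmetic ("not done >6 months" holds
    strictly after result_date + 6 months); a patient never tested for any
    listed analyte is maximally stale and always satisfies the test.
    """
    if isinstance(analyte_codes, str):
        analyte_codes = [analyte_codes]
    latest: dt.date | None = None
    for code in analyte_codes:
        lab = last_result(record, code, as_of)
        if lab is not None and (latest is None or lab.result_date > latest):
            latest = lab.result_date
    if latest is None:
        return True
    return latest + relativedelta(years=years, months=months) < as_of


def age_at(record: PatientRecord, as_of: dt.date) -> int:
    """Completed years of age by calendar arithmetic."""
    if as_of < record.birth_date:
        raise ValueError("as_of precedes birth_date")
    return relativedelta(as_of, record.birth_date).years


def estimate_crcl(record: PatientRecord, as_of: dt.date) -> float | None:
    """Creatinine clearance in mL/min: stored field first, else Cockcroft-Gault.

    The stored ``risk_fields.crcl_ml_min`` always wins (the source system's
    own estimate). Otherwise Cockcroft-Gault is computed from the latest
    serum creatinine (mmol/L), weight (stored field or latest weight
    measurement), age and sex::

        CrCl = (140 - age) * weight_kg / (0.815 * SCr_umol_per_L)   [male]

    scaled by 0.85 for female sex; patients recorded as ``other`` also get
    the 0.85 factor (the lower, more cautious estimate). Returns None when
    any input is unavailable.
    """
    if record.risk_fields.crcl_ml_min is not None:
        return record.risk_fields.crcl_ml_min
    scr = last_result(record, "serum_creatinine", as_of)
    if scr is None or scr.value is None:
        return None
    if scr.value <= 0:
        raise InvalidLabError(f"non-positive serum creatinine {scr.value}")
    weight = record.risk_fields.weight_kg
    if weight is None:
        wlab = last_result(record, "weight", as_of)
        weight = wlab.value if wlab is not None else None
    if weight is None or weight <= 0:
        return None
    age = age_at(record, as_of)
    scr_umol = scr.value * 1000.0  # record convention: creatinine in mmol/L
    crcl = (140 - age) * weight / (0.815 * scr_umol)
    if record.sex != "male":
        crcl *= 0.85
    return crcl
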