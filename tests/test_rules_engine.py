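"""Rule evaluation: boundaries, fixture completeness, modes, dispositions."""

import datetime as dt

import pytest

from medreview.practicelog import PracticeLog
from medreview.records import (
    ConditionRecord,
    LabResult,
    MedicationOrder,
    PatientRecord,
    RiskFields,
)
from medreview.rule_catalog import default_ruleset, rule_by_id
from medreview.rules_engine import (
    EngineConfig,
    UnknownAlertError,
    evaluate_patient,
    evaluate_patient_detailed,
    evaluate_rule,
    record_disposition,
)
from medreview.triggers import build_trigger_patient

AS_OF = dt.date(2016, 6, 1)


def _patient(age=50, sex="female"):
    from dateutil.relativedelta import relativedelta

    return PatientRecord("p", AS_OF - relativedelta(years=age, days=100), sex)


def _order(drug, *, days_ago=10, supply=30, dose=10.0, per_day=1.0, indication=None):
    return MedicationOrder(drug, dose, per_day, AS_OF - dt.timedelta(days=days_ago),
                           days_supply=supply, indication_code=indication)


class TestCatalogShape:
    def test_catalog_has_46_unique_rules(self, ruleset):
        assert len(ruleset) == 46
        assert len({r.rule_id for r in ruleset}) == 46

    def test_every_numeric_threshold_is_a_parameter(self, ruleset):
        # spot-check: overriding a parameter changes behaviour (no shadowing
        # constant inside the predicate)
        rec = _patient()
        rec.medications.append(_order("citalopram", dose=15, per_day=2))  # 30 mg/day
        rule = rule_by_id("PSY-2")
        assert evaluate_rule(rule, rec, AS_OF) is None
        lowered = EngineConfig(rule_parameters={"PSY-2": {"max_daily_mg": 20}})
        assert evaluate_rule(rule, rec, AS_OF, config=lowered) is not None


class TestPrintedComparatorBoundaries:
    """Strict/inclusive semantics exactly as the clinical wording prints them."""

    def test_citalopram_40_no_alert_40_1_alerts(self):
        rule = rule_by_id("PSY-2")
        rec = _patient()
        rec.medications.append(_order("citalopram", dose=20, per_day=2))  # exactly 40
        assert evaluate_rule(rule, rec, AS_OF) is None
        rec2 = _patient()
        rec2.medications.append(_order("citalopram", dose=20.05, per_day=2))  # 40.1
        alert = evaluate_rule(rule, rec2, AS_OF)
        assert alert is not None and alert.action_kind == "reduce_dose"

    def test_benzodiazepine_28_days_is_inclusive(self):
        rule = rule_by_id("PSY-3")
        on_day_28 = _patient()
        on_day_28.medications.append(_order("diazepam", days_ago=27, supply=40, dose=5))
        assert evaluate_rule(rule, on_day_28, AS_OF) is not None
        on_day_27 = _patient()
        on_day_27.medications.append(_order("diazepam", days_ago=26, supply=40, dose=5))
        assert evaluate_rule(rule, on_day_27, AS_OF) is None

    def test_uric_acid_not_below_0_36_fires_at_0_36(self):
        rule = rule_by_id("GOU-3")
        rec = _patient()
        rec.medications.append(_order("allopurinol", days_ago=100, supply=200, dose=300))
        rec.labs.append(LabResult("uric_acid", AS_OF - dt.timedelta(days=30), value=0.36))
        assert evaluate_rule(rule, rec, AS_OF) is not None
        rec.labs[-1] = LabResult("uric_acid", AS_OF - dt.timedelta(days=30), value=0.359)
        assert evaluate_rule(rule, rec, AS_OF) is None

    def test_potassium_4_0_exactly_does_not_fire(self):
        rule = rule_by_id("MON-2")
        rec = _patient()
        rec.conditions.append(ConditionRecord("hypokalemia_cause_resolved", AS_OF - dt.timedelta(days=60)))
        rec.medications.append(_order("potassium_chloride", days_ago=30, supply=90, dose=600))
        rec.labs.append(LabResult("serum_potassium", AS_OF - dt.timedelta(days=10), value=4.0))
        assert evaluate_rule(rule, rec, AS_OF) is None
        rec.labs[-1] = LabResult("serum_potassium", AS_OF - dt.timedelta(days=10), value=4.01)
        assert evaluate_rule(rule, rec, AS_OF) is not None

    def test_age_over_65_is_strict_for_hypnotic_rule(self):
        rule = rule_by_id("ELD-4")
        from dateutil.relativedelta import relativedelta

        exactly_65 = PatientRecord("p", AS_OF - relativedelta(years=65), "male")
        exactly_65.medications.append(_order("zopiclone", indication="insomnia", dose=7.5))
        assert evaluate_rule(rule, exactly_65, AS_OF) is None
        over_65 = _patient(age=66)
        over_65.medications.append(_order("zopiclone", indication="insomnia", dose=7.5))
        assert evaluate_rule(rule, over_65, AS_OF) is not None


class TestRuleExamples:
    def test_citalopram_60mg_daily_reduce_alert(self):
        rec = _patient()
        rec.medications.append(_order("citalopram", dose=30, per_day=2))
        alert = evaluate_rule(rule_by_id("PSY-2"), rec, AS_OF)
        assert alert.action_kind == "reduce_dose"
        assert any(e.startswith("med:citalopram") for e in alert.evidence)

    def test_duplicate_benzodiazepines_stop_alert(self):
        rec = _patient()
        rec.medications += [_order("diazepam", dose=5), _order("temazepam", dose=10)]
        alert = evaluate_rule(rule_by_id("DUP-2"), rec, AS_OF)
        assert alert.action_kind == "stop"
        assert len(alert.evidence) == 2

    def test_spironolactone_amiloride_stale_potassium_mon1_only(self, ruleset):
        rec = build_trigger_patient("MON-1", AS_OF)
        alerts = evaluate_patient(rec, ruleset, AS_OF)
        assert [a.rule_id for a in alerts] == ["MON-1"]


class TestFixtureCompleteness:
    def test_each_trigger_patient_fires_exactly_its_rule(self, trigger_bundle, ruleset):
        fired = {}
        for rec in trigger_bundle:
            alerts = evaluate_patient(rec, ruleset, AS_OF)
            fired[rec.patient_id] = [a.rule_id for a in alerts]
        assert all(
            ids == [pid.replace("trigger-", "")] for pid, ids in fired.items()
        ), {k: v for k, v in fired.items() if v != [k.replace("trigger-", "")]}

    def test_bundle_yields_exactly_46_alerts(self, trigger_bundle, ruleset):
        total = sum(len(evaluate_patient(r, ruleset, AS_OF)) for r in trigger_bundle)
        assert total == 46


class TestModes:
    def test_empty_patient_yields_nothing(self, ruleset):
        assert evaluate_patient(_patient(), ruleset, AS_OF) == []

    def test_silent_mode_differs_only_in_displayed_flag(self, trigger_bundle, ruleset):
        for rec in trigger_bundle:
            shown = evaluate_patient(rec, ruleset, AS_OF, mode="display")
            silent = evaluate_patient(rec, ruleset, AS_OF, mode="silent")
            assert [a.content_key() for a in shown] == [a.content_key() for a in silent]
            assert all(a.displayed for a in shown)
            assert not any(a.displayed for a in silent)

    def test_one_alert_per_rule_even_with_multiple_matches(self, ruleset):
        rec = _patient()
        rec.medications += [
            _order("diazepam", dose=5),
            _order("temazepam", dose=10),
            _order("lorazepam", dose=1),
        ]
        alerts = [a for a in evaluate_patient(rec, ruleset, AS_OF) if a.rule_id == "DUP-2"]
        assert len(alerts) == 1
        assert len(alerts[0].evidence) == 3  # all three matches in one trace

    def test_enabled_rules_filter(self, ruleset):
        rec = build_trigger_patient("DUP-1", AS_OF)
        cfg = EngineConfig(enabled_rules=["PSY-2"])
        assert evaluate_patient(rec, ruleset, AS_OF, config=cfg) == []


class TestDataGapPolicy:
    def test_missing_indication_emits_gap_not_alert(self, ruleset):
        rec = _patient()
        rec.medications.append(_order("omeprazole", days_ago=100, supply=200, dose=20))
        alerts, gaps = evaluate_patient_detailed(rec, ruleset, AS_OF)
        assert not any(a.rule_id == "GAS-1" for a in alerts)
        assert any(g.rule_id == "GAS-1" and g.field_name == "indication_code" for g in gaps)

    def test_assume_worst_mode_fires_instead(self, ruleset):
        rec = _patient()
        rec.medications.append(_order("omeprazole", days_ago=100, supply=200, dose=20))
        cfg = EngineConfig(assume_worst=True)
        alerts = evaluate_patient(rec, ruleset, AS_OF, config=cfg)
        assert any(a.rule_id == "GAS-1" for a in alerts)

    def test_missing_cv_risk_blocks_aspirin_rule(self):
        rec = _patient(age=55)
        rec.medications.append(
            _order("aspirin", days_ago=100, supply=200, dose=100,
                   indication="primary_cv_prevention")
        )
        gaps = []
        alert = evaluate_rule(rule_by_id("ANT-3"), rec, AS_OF, gaps=gaps)
        assert alert is None
        assert gaps and gaps[0].field_name == "cv_risk_pct"
        rec.risk_fields = RiskFields(cv_risk_pct=12.0)
        assert evaluate_rule(rule_by_id("ANT-3"), rec, AS_OF) is not None


class TestEvidenceProperties:
    def test_evidence_elements_exist_in_record(self, trigger_bundle, ruleset):
        for rec in trigger_bundle:
            known = (
                {m.element_id for m in rec.medications}
                | {c.element_id for c in rec.conditions}
                | {l.element_id for l in rec.labs}
                | {i.element_id for i in rec.immunizations}
            )
            for alert in evaluate_patient(rec, ruleset, AS_OF):
                for element in alert.evidence:
                    if element.startswith(("risk:", "demo:")):
                        continue
                    assert element in known

    def test_deleting_evidence_weakens_or_silences_the_rule(self, trigger_bundle):
        """Evidence soundness: each cited element genuinely supports the alert."""
        for rec in trigger_bundle:
            rule = rule_by_id(rec.patient_id.replace("trigger-", ""))
            alert = evaluate_rule(rule, rec, AS_OF)
            assert alert is not None
            for element in alert.evidence:
                if element.startswith(("risk:", "demo:")):
                    continue
                pruned = PatientRecord(
                    rec.patient_id, rec.birth_date, rec.sex,
                    conditions=[c for c in rec.conditions if c.element_id != element],
                    medications=[m for m in rec.medications if m.element_id != element],
                    labs=[l for l in rec.labs if l.element_id != element],
                    immunizations=list(rec.immunizations),
                    risk_fields=rec.risk_fields,
                )
                again = evaluate_rule(rule, pruned, AS_OF)
                assert again is None or len(again.evidence) < len(alert.evidence)

    def test_locality_unrelated_medicine_never_changes_output(self, trigger_bundle, ruleset):
        """Adding a drug with no tag referenced by a rule leaves it unchanged."""
        for rec in trigger_bundle:
            rule = rule_by_id(rec.patient_id.replace("trigger-", ""))
            if rule.rule_id in {"GOU-2", "MON-3", "MON-4"}:
                # these read untagged analytes only; levothyroxine is still inert
                pass
            with_extra = PatientRecord(
                rec.patient_id, rec.birth_date, rec.sex,
                conditions=list(rec.conditions),
                medications=rec.medications
                + [_order("cetirizine", days_ago=3, supply=10, dose=10)],
                labs=list(rec.labs),
                immunizations=list(rec.immunizations),
                risk_fields=rec.risk_fields,
            )
            before = evaluate_rule(rule, rec, AS_OF)
            after = evaluate_rule(rule, with_extra, AS_OF)
            if rule.rule_id == "CON-1":
                continue  # cetirizine carries the constipating tag CON-1 reads
            assert (before is None) == (after is None)
            if before is not None:
                assert before.evidence == after.evidence


class TestDispositions:
    def _emitted(self, ruleset):
        rec = _patient()
        rec.medications += [
            _order("famotidine", days_ago=10, supply=400, dose=20),
            _order("omeprazole", days_ago=10, supply=400, dose=20),
        ]
        log = PracticeLog("prac-1", "intervention")
        [alert] = evaluate_patient(rec, ruleset, AS_OF)
        log.record_alert(alert)
        return rec, alert, log

    def test_acceptance_increments_change_count(self, ruleset):
        _, alert, log = self._emitted(ruleset)
        record_disposition(alert, "accepted_changed", log)
        assert log.count("accepted_changed") == 1

    def test_dismissal_suppresses_realerting_within_window(self, ruleset):
        rec, alert, log = self._emitted(ruleset)
        record_disposition(alert, "dismissed", log)
        next_day = AS_OF + dt.timedelta(days=1)
        assert evaluate_patient(rec, ruleset, next_day, log=log) == []
        past_window = AS_OF + dt.timedelta(days=91)
        realerts = evaluate_patient(rec, ruleset, past_window, log=log)
        assert [a.rule_id for a in realerts] == ["DUP-1"]

    def test_disposition_on_unknown_alert_errors(self, ruleset):
        _, alert, _ = self._emitted(ruleset)
        empty_log = PracticeLog("prac-2", "control")
        with pytest.raises(UnknownAlertError):
            record_disposition(alert, "dismissed", empty_log)
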