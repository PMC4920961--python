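# medreview

Rule-based medication review for primary-care records: a deprescribing and
monitoring decision-support engine with polypharmacy audit reporting and a
calibrated synthetic-population generator.

## The problem

Polypharmacy — the concurrent use of five or more medicines (ten or more is
*hyperpolypharmacy*) — is common, rising, and a major driver of adverse drug
events, yet systematic medication review rarely fits inside a primary-care
consultation. `medreview` implements the machinery of an automated review: a
catalog of 46 clinical rules is evaluated against each patient's structured
record (conditions, medication orders, laboratory results, immunizations,
stored risk fields) at a chosen date, and each rule that holds raises an
**alert** carrying a suggested action (stop, reduce dose, review, monitor,
initiate, recommend), an information link, and an **evidence trace** listing
exactly the record elements that satisfied the predicate.

The rules cover duplicate therapy, lingering gastroprotectants,
constipating drugs in chronic constipation, time-limited anticoagulation
after a first venous thromboembolism, high-risk medicines in the elderly,
psychotropics (including hypnotic courses of four weeks or more),
analgesics and NSAIDs, gout prophylaxis and monitoring, bisphosphonate
duration, metformin in renal impairment, seasonal influenza vaccination,
four drug-drug interaction patterns, and five laboratory-monitoring
recency rules.

Two evaluation modes support an intervention-versus-control study design:
**display** mode surfaces alerts at the point of care, while **silent**
mode computes and logs the identical alerts without revealing them — the
control-arm mechanism. Practice-level reporting recounts the raw event log
into monthly progress reports, and a query builder lists patients with
polypharmacy or flagged medicines.

## The quantitative core

* **Temporal medication algebra** — an order is active on the half-open
  interval `[start, start + days_supply)`; continuous-use episodes merge
  orders across refill gaps of at most 7 days (configurable); all
  "N months/years" windows are strict calendar arithmetic, and every
  printed comparator keeps its exact strictness (citalopram fires above
  40 mg/day, not at it; a 28-day hypnotic course satisfies "≥ 4 weeks";
  urate 0.36 mmol/L fires "not < 0.36"; potassium 4.0 does not fire "> 4.0").
* **Medication-count calibration** — the synthetic generator fits a
  two-component mixture (low-use component on 0–4 medicines; heavy-use
  component `5 + Geometric(q)`) whose tails satisfy
  `P(count ≥ 5) = 0.085` and `P(count ≥ 11) = 0.026 = 0.085·q⁶` exactly,
  matching the national dispensing figures its defaults target.
* **Sample size** — patients per arm for a two-sided two-proportion
  comparison by the pooled-variance normal approximation,
  `n = ⌈(z₁₋α/₂√(2p̄q̄) + z₁₋β√(p₁q₁ + p₂q₂))² / (p₁−p₂)²⌉`,
  validated by Monte-Carlo power simulation rather than any fixed oracle.

## Worked example

```python
import datetime as dt
from medreview import default_ruleset, evaluate_patient, build_trigger_patient

as_of = dt.date(2016, 6, 1)
patient = build_trigger_patient("PSY-2", as_of)   # citalopram 30 mg twice daily
for alert in evaluate_patient(patient, default_ruleset(), as_of):
    print(alert.rule_id, alert.action_kind, "|", alert.message)
    print("  evidence:", list(alert.evidence))
```

prints

```
PSY-2 reduce_dose | Citalopram above 40 mg daily; reduce the dose.
  evidence: ['med:citalopram:2016-05-12']
```

i.e. the patient's 60 mg/day citalopram exceeds the 40 mg daily ceiling, so
the dose-reduction rule fires, citing the offending order. From the shell,
the same pipeline end to end:

```bash
medreview simulate --n 1000 --seed 7 --plant all --out scratch/pop
medreview evaluate --bundle scratch/pop --as-of 2016-06-01 --mode silent \
    --out scratch/alerts.jsonl
medreview query --bundle scratch/pop --criterion polypharmacy --as-of 2016-06-01
medreview samplesize --p1 0.11 --p2 0.31
```

The `simulate` call writes a five-table CSV bundle of 1,000 random patients
plus 46 planted rule-trigger patients; `evaluate` emits one JSON-lines
alert per fired rule; `samplesize` prints `64` (patients per arm for 11%
vs 31% at 80% power, α = 0.05).

## Layout

```
src/medreview/
  records.py       patient-record types, validation, CSV/JSON bundle I/O
  formulary.py     drug→class ontology, reference lists, candidate filter
  medhist.py       active orders, episodes, doses, lab recency, age, CrCl
  rules_engine.py  evaluator, alerts, data-gap policy, dispositions
  rule_catalog.py  the 46 rule definitions
  triggers.py      one minimal trigger patient per rule (validation bundle)
  synthpop.py      calibrated synthetic populations
  reporting.py     polypharmacy metrics, monthly reports, queries, trial measures
  practicelog.py   append-only practice event log
  cli.py           evaluate / validate / simulate / report / query / samplesize
docs/methods.md    modelling and design notes
```
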