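# Methods

## Record model

The patient record is a minimal sufficient model of a primary-care patient
management system, not a claim about any deployed schema: demographics, a
coded problem list with onset/abatement dates, medication orders with dose,
supply window and optional indication, dated laboratory results,
immunizations, and three stored risk fields (cardiovascular risk percent,
creatinine clearance, weight). Vocabularies (condition codes, analyte
codes, indication codes, drug class tags) are registered open enumerations:
rules test membership of specific codes, and unknown codes surface as
validation violations rather than silently disarming a rule.

Two conventions do most of the temporal work:

* **Half-open supply intervals.** An order is active on
  `[start_date, start_date + days_supply)`: active on the first day of
  supply, inactive on the day the supply exhausts. This is the standard
  dispensing convention; it has to be fixed explicitly because "taking a
  medicine on date d" is otherwise ambiguous at both edges.
* **Calendar windows, printed strictness.** Every "N weeks/months/years"
  window is calendar arithmetic (`dateutil.relativedelta`), never a 30-day
  approximation: "for > 6 months" from 15 January is satisfied strictly
  after 15 July. Comparator strictness mirrors the clinical wording glyph
  for glyph — "> 65 years" strict, "≥ 4 weeks" inclusive, "> 40 mg daily"
  strict, "not < 0.36 mmol/L" fires at 0.36, "> 4.0 mmol/L" silent at 4.0.

## Continuous-use episodes

Duration predicates ("taken for ≥ 4 weeks", "continuous use for > 5 years")
are evaluated over *stitched episodes*: a drug's (or class's) order
intervals are merged, bridging refill gaps of at most `max_gap_days`
(default 7 — a dispensing lag, the standard persistence-analysis
convention; configurable). A patient remains "in" an episode through the
grace gap after supply ends, consistent with the stitching rule. Duration
counts from the episode start to the evaluation date inclusive of the
start day, so a 28-day course satisfies "≥ 4 weeks" on its final covered
day. Duration is monotone non-decreasing within an episode and drops to
zero beyond episode end plus the gap; widening the gap can only lengthen
episodes.

## The rule catalog

Forty-six rules in fourteen categories, each a pure predicate over one
record at one date. Every numeric threshold lives in the rule's parameter
map and can be overridden per deployment; the predicate bodies contain no
literals. Notable operationalizations, chosen where the clinical wording
leaves room:

* **"Elderly"** is ≥ 65 for the loop-diuretic and spironolactone rules
  (undefined in the source wording; the conventional cut-point), while
  rules that print "> 65", "> 75", "> 85" stay strict.
* **"Long-term"** loop diuretics and corticosteroids is > 90 days of
  continuous use.
* **Metformin in renal impairment** triggers below 30 mL/min creatinine
  clearance (configurable); clearance is the stored field when present,
  else Cockcroft–Gault from the latest creatinine, weight, age and sex
  (patients recorded as `other` sex get the 0.85 factor — the lower, more
  cautious estimate).
* **Recurrent gout** is ≥ 2 acute-treatment orders (NSAID or colchicine
  with a gout-flare indication) starting within the trailing 12 months.
* **The antipsychotics-in-dementia exception** ("non-pharmacological
  options failed and the patient is a threat") is not computable from
  routine records; it is modelled as an explicit documented condition code
  (`behavioral_risk_exception`) that vetoes the rule.
* **Anticoagulant stop rules** read the *absence* of a
  `continuing_vte_risk` condition as "no continuing provoking risk": an
  unrecorded risk factor does not protect the prescription.
* **Gastroprotection review** treats "the irritant has now been stopped"
  as "no NSAID/aspirin/corticosteroid active at the evaluation date"; no
  look-back limit on how recently it stopped.
* The **lithium** rule alerts when any single panel member is overdue
  (each test is individually required), whereas the **allopurinol
  monitoring** rule requires both urate *and* renal function to be overdue
  (its wording bundles them as one monitoring obligation); serum
  creatinine stands in for the urea-and-electrolytes panel.

### Data-gap policy

Predicates that need an optional clinical value (an order's indication,
stored cardiovascular risk, BMD-stabilized or hypokalemia-resolved flags)
do **not** fire when the value is absent; the evaluation emits a
machine-readable data-gap note instead. Rationale: an alert the prescriber
cannot verify from the record is noise, and alert fatigue is the main
failure mode of prompt systems. `assume_worst = true` flips the policy for
audit use. Gaps are emitted narrowly — only when the rule was otherwise
satisfiable (e.g. a long-running loop diuretic with no indication at all).

### Alerts, evidence, modes

At most one alert per (patient, rule) per evaluation; when several drug
pairs match, all matches appear in one evidence trace. Evidence lists
exactly the element ids (orders, conditions, labs, `risk:` fields,
`demo:age` for the age-qualified vaccination cohort) that satisfied the
clauses; deleting any cited element either silences the rule or strictly
shrinks the trace. Silent mode produces bit-identical alert content with
`displayed = false`. A dismissed alert suppresses re-alerting for the same
(patient, rule) for 90 days (configurable).

## Synthetic populations

The generator emulates the slice of a de-identified historical database
the rules read. Its defaults are the study conditions, not tuning knobs:

* **Medication counts** come from a two-component mixture — low-use on 0–4
  medicines (truncated geometric, ratio 0.6) with weight `1 − P(≥5)`, and
  heavy-use `5 + Geometric(q)` with weight `P(≥5)` — calibrated to the
  national 2013–2014 tails `P(≥5) = 8.5%`, `P(≥11) = 2.6%`. Both tails
  have closed forms (`P(≥5) = w`, `P(≥11) = w·q⁶`), so calibration is
  exact. All of a patient's orders are active at the single index date
  (2016-06-01 by default), making the concurrent count equal the drawn
  count by construction.
* **Conditions** are drawn independently at fixed prevalences chosen as
  plausible general-practice figures (diabetes 8%, osteoarthritis 10%,
  heart failure 2%, schizophrenia 0.5%, …) — high enough to exercise
  every rule at population scale, with no claim of demographic fidelity.
* **Laboratory panels** are generated for the analytes a patient's drugs
  make relevant; recency is a mixture of recent and overdue draws (20%
  overdue by default), so monitoring rules fire at a controllable rate.
  Ages are Normal(52, 19) clipped to 18–95; indications attach to 40% of
  eligible orders; 55% of patients carry an influenza vaccination dated
  within the past 13 months (so some fall outside the 12-month window the
  vaccination rule checks).
* **Planted patients**: for any requested rule ids, the generator appends
  the corresponding minimal trigger patients (`planted-<RULE-ID>`), each
  engineered to fire exactly its rule under the default catalog — recent
  influenza vaccination for anyone vaccine-eligible, fresh monitoring labs
  for ACE-inhibitor/lithium users, hypnotic courses under four weeks
  unless the rule under test needs more.

The whole bundle is a pure function of the parameter object including the
seed. What passing tests on these populations shows is that the *rule
logic* behaves as specified under realistic co-prescription density; they
say nothing about coding quality, missingness patterns, or longitudinal
dynamics of real records, all of which are deliberately out of scope.

## Reporting and trial measures

All report counters are recounts of raw practice-log events (emission,
engagement, disposition, reversion, lab order, coded outcome events) —
nothing is cached. Prevalences are computed from the record bundle at the
month's last day. "Inappropriately prescribed medicine" is
operationalized as any active medicine cited in the evidence of a fired
stop/reduce/review rule; the "appropriate treatment" proportion is the
complement of patients with at least one such flag. The inappropriate
*initiation* rate counts new orders per patient-month that fire a rule on
their own start date. Outcome events are consumed as coded log entries
with no attribution logic.

The sample-size routine uses the pooled-variance normal approximation for
a two-sided two-proportion test, rounded up. It is validated by
self-consistency — simulated power of the same pooled z-test at the
returned n stays within two percentage points of the request across a
ten-point grid of moderate proportions (the approximation's validity
domain; extreme proportions with tiny effects would need exact methods).
No published per-arm figure is used as an oracle.

## Numerical and degenerate-input choices

* Never-tested analytes compare as infinitely stale (a patient never
  tested is the strongest case for a monitoring alert), except where a
  rule needs an actual value (urate target, potassium threshold), in which
  case absence silences that rule and leaves the untested case to its
  monitoring counterpart.
* Mixed dose units across summed orders raise rather than blend.
* Leap-day birthdays take the date library's 28-February anniversary
  convention.
* Empty patient collections are errors for prevalence (a 0/0 proportion),
  but empty medication lists, empty months and empty candidate lists are
  ordinary inputs with well-defined outputs.

## Problem sizes

The validation bundle is 46 patients (one per rule). Oracle-equivalence
checks run the engine against independently written flat predicates on
1,000 seeded synthetic patients; calibration recovery uses 20,000 patients
against 95% binomial intervals; Monte-Carlo power uses 100,000 replicates
per grid point. These sizes make the stochastic checks' error negligible
relative to their tolerance bands while keeping the full suite around ten
seconds.

## Known limitations

* The formulary is an exemplar (~80 agents) with conservative
  antimuscarinic/QT reference lists; real deployments must supply their
  own formulary CSV and reference lists, and the weak/strong opioid split
  (tramadol and codeine as weak) is a documented, overridable default.
* Adherence (MPR/PDC), dose tapering, interaction severity grading, and
  cost analysis are out of scope.
* Indication codes drive several rules; records that never code
  indications will see data-gap notes instead of alerts unless
  `assume_worst` is enabled.
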