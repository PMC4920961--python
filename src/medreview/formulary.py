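"""Drug-to-class ontology, reference lists, and candidate prioritization.

Clinical rules are phrased over therapeutic classes ("H2-receptor antagonists
with proton pump inhibitors"), so every drug code resolves to a set of class
tags through a :class:`Formulary`. A small default formulary of exemplar
agents ships with the package — enough to exercise every rule — and a
practice can load its own ``formulary.csv`` to replace it.

Antimuscarinic and QT-prolonging membership are *reference lists*: extra
tags applied on top of a drug's therapeutic classes, loadable from plain
text files (one drug code per line). The shipped defaults are deliberately
conservative (well-established members only).

The candidate-prioritization filter reproduces the rule-selection step in
which proposed interventions targeting drugs dispensed fewer than a
threshold number of times per year nationally (default 5000) are dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CLASS_TAGS",
    "DrugEntry",
    "Formulary",
    "CandidateRule",
    "UnknownDrugError",
    "default_formulary",
    "load_formulary_csv",
    "load_reference_list",
    "prioritize_candidates",
    "DEFAULT_DISPENSING_THRESHOLD",
]

DEFAULT_DISPENSING_THRESHOLD = 5000

CLASS_TAGS = frozenset(
    {
        "benzodiazepine",
        "zopiclone",
        "antipsychotic",
        "atypical_antipsychotic",
        "quetiapine_or_clozapine",
        "ssri",
        "tca",
        "h2ra",
        "ppi",
        "nsaid",
        "aspirin_antiplatelet",
        "antiplatelet",
        "vka",
        "dti",
        "xa_inhibitor",
        "loop_diuretic",
        "diuretic",
        "spironolactone",
        "potassium_sparing",
        "potassium_supplement",
        "statin",
        "first_gen_antihistamine",
        "orphenadrine",
        "opioid_strong",
        "opioid_weak_codeine",
        "opioid_weak_tramadol",
        "opioid_long_acting",
        "paracetamol_codeine_combo",
        "paracetamol",
        "colchicine",
        "allopurinol",
        "bisphosphonate",
        "systemic_corticosteroid",
        "metformin",
        "citalopram",
        "lithium",
        "ace_inhibitor",
        "arb",
        "beta_blocker",
        "verapamil_diltiazem",
        "antimuscarinic",
        "qt_prolonging",
        "constipating",
        "metoclopramide",
        "prochlorperazine",
        "promethazine",
    }
)


class UnknownDrugError(KeyError):
    """Raised when a drug code is absent from the formulary."""

    def __init__(self, drug_code: str):
        super().__init__(drug_code)
        self.drug_code = drug_code

    def __str__(self) -> str:
        return f"unknown drug code {self.drug_code!r}"


@dataclass(frozen=True)
class DrugEntry:
    drug_code: str
    display_name: str
    class_tags: frozenset[str]

    def __post_init__(self) -> None:
        if not self.class_tags:
            raise ValueError(f"{self.drug_code}: class_tags must be non-empty")
        unknown = self.class_tags - CLASS_TAGS
        if unknown:
            raise ValueError(f"{self.drug_code}: unregistered class tags {sorted(unknown)}")


class Formulary:
    """Immutable drug_code -> DrugEntry map with an inverse class index."""

    def __init__(self, entries: Iterable[DrugEntry]):
        self.entries: dict[str, DrugEntry] = {}
        for e in entries:
            if e.drug_code in self.entries:
                raise ValueError(f"duplicate drug_code {e.drug_code!r}")
            self.entries[e.drug_code] = e
        self.class_index: dict[str, frozenset[str]] = {}
        index: dict[str, set[str]] = {tag: set() for tag in CLASS_TAGS}
        for e in self.entries.values():
            for tag in e.class_tags:
                index[tag].add(e.drug_code)
        self.class_index = {tag: frozenset(codes) for tag, codes in index.items()}

    def classify_drug(self, drug_code: str) -> frozenset[str]:
        """Class tags of ``drug_code``; raises :class:`UnknownDrugError` if absent."""
        try:
            return self.entries[drug_code].class_tags
        except KeyError:
            raise UnknownDrugError(drug_code) from None

    def drugs_with_tag(self, tag: str) -> frozenset[str]:
        if tag not in CLASS_TAGS:
            raise KeyError(f"unregistered class tag {tag!r}")
        return self.class_index[tag]

    def has_tag(self, drug_code: str, tag: str) -> bool:
        return tag in self.classify_drug(drug_code)

    def with_reference_tags(self, tag: str, drug_codes: Iterable[str]) -> "Formulary":
        """New formulary with ``tag`` added to each listed drug (reference lists)."""
        codes = set(drug_codes)
        missing = codes - self.entries.keys()
        if missing:
            raise UnknownDrugError(sorted(missing)[0])
        return Formulary(
            DrugEntry(e.drug_code, e.display_name, frozenset(e.class_tags | {tag}))
            if e.drug_code in codes
            else e
            for e in self.entries.values()
        )

    def __contains__(self, drug_code: str) -> bool:
        return drug_code in self.entries

    def __len__(self) -> int:
        return len(self.entries)


# Exemplar default formulary. Tag assignments are deliberately parsimonious:
# a drug carries a tag only when at least one rule depends on that membership
# being present (or absent). Antimuscarinic and QT memberships below are the
# conservative default reference lists.
_DEFAULT_TABLE: list[tuple[str, str, str]] = [
    # hypnotics / anxiolytics
    ("diazepam", "Diazepam", "benzodiazepine"),
    ("temazepam", "Temazepam", "benzodiazepine"),
    ("lorazepam", "Lorazepam", "benzodiazepine"),
    ("clonazepam", "Clonazepam", "benzodiazepine"),
    ("zopiclone", "Zopiclone", "zopiclone"),
    # antipsychotics
    ("haloperidol", "Haloperidol", "antipsychotic;qt_prolonging"),
    ("chlorpromazine", "Chlorpromazine", "antipsychotic;antimuscarinic;constipating"),
    ("risperidone", "Risperidone", "antipsychotic;atypical_antipsychotic"),
    ("olanzapine", "Olanzapine", "antipsychotic;atypical_antipsychotic;constipating"),
    ("quetiapine", "Quetiapine", "antipsychotic;atypical_antipsychotic;quetiapine_or_clozapine"),
    (
        "clozapine",
        "Clozapine",
        "antipsychotic;atypical_antipsychotic;quetiapine_or_clozapine;antimuscarinic;constipating",
    ),
    # antidepressants
    ("citalopram", "Citalopram", "ssri;citalopram;qt_prolonging"),
    ("escitalopram", "Escitalopram", "ssri;qt_prolonging"),
    ("fluoxetine", "Fluoxetine", "ssri"),
    ("sertraline", "Sertraline", "ssri"),
    ("paroxetine", "Paroxetine", "ssri"),
    ("amitriptyline", "Amitriptyline", "tca;antimuscarinic;constipating"),
    ("nortriptyline", "Nortriptyline", "tca;antimuscarinic"),
    # acid suppression
    ("famotidine", "Famotidine", "h2ra"),
    ("ranitidine", "Ranitidine", "h2ra"),
    ("omeprazole", "Omeprazole", "ppi"),
    ("pantoprazole", "Pantoprazole", "ppi"),
    # NSAIDs / antiplatelets / anticoagulants
    ("ibuprofen", "Ibuprofen", "nsaid"),
    ("naproxen", "Naproxen", "nsaid"),
    ("diclofenac", "Diclofenac", "nsaid"),
    ("celecoxib", "Celecoxib", "nsaid"),
    ("aspirin", "Aspirin (low dose)", "aspirin_antiplatelet;antiplatelet"),
    ("clopidogrel", "Clopidogrel", "antiplatelet"),
    ("warfarin", "Warfarin", "vka"),
    ("dabigatran", "Dabigatran", "dti"),
    ("rivaroxaban", "Rivaroxaban", "xa_inhibitor"),
    # diuretics / potassium
    ("furosemide", "Furosemide", "loop_diuretic;diuretic"),
    ("bumetanide", "Bumetanide", "loop_diuretic;diuretic"),
    ("bendroflumethiazide", "Bendroflumethiazide", "diuretic"),
    ("hydrochlorothiazide", "Hydrochlorothiazide", "diuretic"),
    ("spironolactone", "Spironolactone", "spironolactone;potassium_sparing;diuretic"),
    ("amiloride", "Amiloride", "potassium_sparing;diuretic"),
    ("potassium_chloride", "Potassium chloride", "potassium_supplement"),
    # lipids
    ("atorvastatin", "Atorvastatin", "statin"),
    ("simvastatin", "Simvastatin", "statin"),
    # antihistamines / antimuscarinics
    (
        "chlorpheniramine",
        "Chlorpheniramine",
        "first_gen_antihistamine;antimuscarinic;constipating",
    ),
    ("diphenhydramine", "Diphenhydramine", "first_gen_antihistamine;antimuscarinic"),
    ("cetirizine", "Cetirizine", "constipating"),  # second generation; kept for contrast
    ("orphenadrine", "Orphenadrine", "orphenadrine;antimuscarinic"),
    ("oxybutynin", "Oxybutynin", "antimuscarinic;constipating"),
    ("solifenacin", "Solifenacin", "antimuscarinic;constipating"),
    # analgesics
    ("morphine", "Morphine", "opioid_strong;constipating"),
    ("oxycodone", "Oxycodone", "opioid_strong;constipating"),
    ("oxycodone_cr", "Oxycodone CR", "opioid_strong;opioid_long_acting;constipating"),
    ("fentanyl_patch", "Fentanyl patch", "opioid_strong;opioid_long_acting"),
    ("methadone", "Methadone", "opioid_strong;opioid_long_acting;qt_prolonging"),
    ("codeine", "Codeine", "opioid_weak_codeine;constipating"),
    ("tramadol", "Tramadol", "opioid_weak_tramadol"),
    ("paracetamol", "Paracetamol", "paracetamol"),
    (
        "paracetamol_codeine",
        "Paracetamol + codeine",
        "paracetamol_codeine_combo;paracetamol;opioid_weak_codeine;constipating",
    ),
    # gout
    ("colchicine", "Colchicine", "colchicine"),
    ("allopurinol", "Allopurinol", "allopurinol"),
    # bone / endocrine
    ("alendronate", "Alendronate", "bisphosphonate"),
    ("zoledronate", "Zoledronate", "bisphosphonate"),
    ("prednisone", "Prednisone", "systemic_corticosteroid"),
    ("dexamethasone", "Dexamethasone", "systemic_corticosteroid"),
    ("metformin", "Metformin", "metformin"),
    ("lithium", "Lithium carbonate", "lithium"),
    # cardiovascular
    ("lisinopril", "Lisinopril", "ace_inhibitor"),
    ("enalapril", "Enalapril", "ace_inhibitor"),
    ("losartan", "Losartan", "arb"),
    ("candesartan", "Candesartan", "arb"),
    ("metoprolol", "Metoprolol", "beta_blocker"),
    ("atenolol", "Atenolol", "beta_blocker"),
    ("sotalol", "Sotalol", "beta_blocker;qt_prolonging"),
    ("verapamil", "Verapamil", "verapamil_diltiazem;constipating"),
    ("diltiazem", "Diltiazem", "verapamil_diltiazem"),
    ("amiodarone", "Amiodarone", "qt_prolonging"),
    ("amlodipine", "Amlodipine", "constipating"),
    # antiemetics / prokinetics
    ("metoclopramide", "Metoclopramide", "metoclopramide"),
    ("prochlorperazine", "Prochlorperazine", "prochlorperazine"),
    ("promethazine", "Promethazine", "promethazine;first_gen_antihistamine;antimuscarinic"),
    ("domperidone", "Domperidone", "qt_prolonging"),
    # antimicrobial with QT liability, for interaction coverage
    ("erythromycin", "Erythromycin", "qt_prolonging"),
    # common co-medication background without rule-bearing tags beyond these
    ("levothyroxine", "Levothyroxine", "constipating"),
]


def default_formulary() -> Formulary:
    """The shipped exemplar formulary (~80 drugs covering every rule)."""
    return Formulary(
        DrugEntry(code, name, frozenset(tags.split(";"))) for code, name, tags in _DEFAULT_TABLE
    )


def load_formulary_csv(path: str | Path) -> Formulary:
    """Load ``formulary.csv``: drug_code, display_name, semicolon-delimited class_tags."""
    entries = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"drug_code", "display_name", "class_tags"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"formulary csv missing column(s): {sorted(missing)}")
        for row in reader:
            entries.append(
                DrugEntry(
                    row["drug_code"],
                    row["display_name"],
                    frozenset(t for t in row["class_tags"].split(";") if t),
                )
            )
    return Formulary(entries)


def load_reference_list(path: str | Path) -> list[str]:
    """One drug code per line; blank lines and ``#`` comments ignored."""
    codes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            codes.append(line)
    return codes


@dataclass(frozen=True)
class CandidateRule:
    """A proposed intervention with national annual dispensing counts per target drug."""

    rule_id: str
    annual_dispensings: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.annual_dispensings.values()):
            raise ValueError(f"{self.rule_id}: negative annual_dispensings")


def prioritize_candidates(
    candidates: Sequence[CandidateRule], threshold: int = DEFAULT_DISPENSING_THRESHOLD
) -> list[CandidateRule]:
    """Retain candidates whose best-dispensed target drug reaches ``threshold``.

    A candidate is excluded when every target drug is dispensed fewer than
    ``threshold`` times a year nationally (strictly below); the boundary
    value itself is retained. Order is preserved; the result is a subset of
    the input, and the filter is idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [
        c
        for c in candidates
        if c.annual_dispensings and max(c.annual_dispensings.values()) >= threshold
    ]
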