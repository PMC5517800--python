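"""Seeded, ground-truthed synthetic EHR fixtures.

No real patient data ever enters this package.  Instead, this module
generates medication entries in the messy free-text dialect the parser is
built for — doses embedded in either field, decorated drug names with
inline schedule inserts and brand synonyms, as-directed and as-needed
sigs, weekday-list schedules, name/sig dose conflicts — each paired with
the ground truth the generator used, so parser, classifier and screener
can be tested end-to-end with known answers.  A cohort generator layers
ages, ICD-9 codes at configured condition prevalences, appointment dates
and per-patient medication lists on top.

Everything is driven by a single integer seed through ``random.Random``;
the same spec always yields byte-identical output.
"""
from __future__ import annotations

import datetime as dt
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .formulary import Category, ClassificationPolicy, FormularyEntry
from .sig_parser import Freq, RawMedicationEntry, Unit

__all__ = [
    "GeneratorSpec",
    "CohortParams",
    "EntryGroundTruth",
    "PatientGroundTruth",
    "default_formulary",
    "generate_medication_entries",
    "generate_patient_cohort",
]

#: Entry archetypes emulating the free-text dialects seen in the wild.
ARCHETYPES = (
    "clean_name_dose",   # dose in name, quantity+frequency phrase in sig
    "sig_dose",          # bare name, dose and frequency in sig
    "decorated",         # decorated name (inline insert / synonym / tags)
    "as_directed",       # dosing delegated to a clinic
    "prn",               # as-needed, no standing schedule
    "weekly",            # weekday-list schedule
    "conflict",          # name and sig disagree on the dose
)

DEFAULT_DIALECT_MIX = {
    "clean_name_dose": 0.40,
    "sig_dose": 0.20,
    "decorated": 0.15,
    "as_directed": 0.05,
    "prn": 0.05,
    "weekly": 0.05,
    "conflict": 0.10,
}


@dataclass(frozen=True)
class CohortParams:
    """Population parameters for synthetic cohorts: an older-adult
    polypharmacy screening population with common chronic conditions."""

    age_min: int = 60
    age_max: int = 94
    htn_prevalence: float = 0.55
    dm_prevalence: float = 0.30
    mean_drugs_per_patient: float = 6.0
    window_start: dt.date = dt.date(2015, 11, 11)
    window_days: int = 14


@dataclass(frozen=True)
class GeneratorSpec:
    seed: int = 0
    n: int = 100
    anomaly_rate: float = 0.0
    dialect_mix: dict = field(default_factory=lambda: dict(DEFAULT_DIALECT_MIX))
    cohort_params: CohortParams = CohortParams()

    def __post_init__(self) -> None:
        if not 0.0 <= self.anomaly_rate <= 1.0:
            raise ValueError("anomaly_rate must be in [0, 1]")
        total = sum(self.dialect_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("dialect_mix weights must sum to 1")
        if set(self.dialect_mix) - set(ARCHETYPES):
            raise ValueError("unknown archetype in dialect_mix")


@dataclass(frozen=True)
class EntryGroundTruth:
    """What the generator intended for one entry; None fields mean
    'no such component exists in this entry'."""

    base_name: str
    category: Category
    parseable: bool
    dose_value: Optional[float] = None
    dose_unit: Optional[Unit] = None
    schedule_code: Freq = Freq.UNKNOWN
    per_day: Optional[int] = None
    per_week: Optional[int] = None
    quantity: int = 1
    total_daily_dose: Optional[float] = None


@dataclass(frozen=True)
class PatientGroundTruth:
    htn: bool
    dm: bool
    n_drugs_of_interest: int
    entry_truths: tuple[EntryGroundTruth, ...] = ()


# ---------------------------------------------------------------------------
# Built-in synthetic formulary
# ---------------------------------------------------------------------------

_OF_INTEREST = [
    ("GABAPENTIN", "ANTICONVULSANT"),
    ("PREGABALIN", "ANTICONVULSANT"),
    ("LAMOTRIGINE", "ANTICONVULSANT"),
    ("CARBAMAZEPINE", "ANTICONVULSANT"),
    ("AMITRIPTYLINE", "ANTIDEPRESSANT"),
    ("NORTRIPTYLINE", "ANTIDEPRESSANT"),
    ("DULOXETINE", "ANTIDEPRESSANT"),
    ("SERTRALINE", "ANTIDEPRESSANT"),
    ("METOPROLOL TARTRATE", "BETA_BLOCKER"),
    ("METOPROLOL SUCCINATE", "BETA_BLOCKER"),
    ("PROPRANOLOL", "BETA_BLOCKER"),
    ("LISINOPRIL", "ACE_INHIBITOR"),
    ("AMLODIPINE", "CALCIUM_BLOCKER"),
    ("FUROSEMIDE", "DIURETIC"),
    ("WARFARIN NA", "ANTICOAGULANT"),
    ("SUMATRIPTAN SUCCINATE", "ANTIMIGRAINE"),
    ("ATORVASTATIN", "STATIN"),
    ("METFORMIN", "ANTIDIABETIC"),
    ("OMEPRAZOLE", "PPI"),
    ("TRAMADOL", "OPIOID_ANALGESIC"),
]

_EXCLUDED = [
    ("MULTIVITAMIN", "VITAMINS"),
    ("ASCORBIC ACID", "VITAMINS"),
    ("CYANOCOBALAMIN", "VITAMINS"),
    ("NIACIN", "VITAMINS"),
    ("GUAIFENESIN", "COUGH_COLD"),
    ("DEXTROMETHORPHAN", "COUGH_COLD"),
    ("HYDROCORTISONE CREAM", "DERM_TOPICAL"),
    ("TRIAMCINOLONE CREAM", "DERM_TOPICAL"),
    ("ARTIFICIAL TEARS", "OPHTHALMIC"),
    ("LATANOPROST", "OPHTHALMIC"),
]

_SUPPLIES = [
    "LANCETS BLOOD GLUCOSE",
    "SYRINGE INSULIN 1ML",
    "SPACER AEROSOL INHALER",
    "DIAPERS ADULT",
]

#: Brand synonyms used by the decorated-name archetype.
_BRANDS = {
    "LAMOTRIGINE": "LAMICTAL",
    "NIACIN": "SLO-NIACIN",
    "SERTRALINE": "ZOLOFT",
    "DULOXETINE": "CYMBALTA",
    "OMEPRAZOLE": "PRILOSEC",
    "ATORVASTATIN": "LIPITOR",
}

_INDICATIONS = ["SEIZURES", "PAIN", "BLOOD PRESSURE", "MOOD", "CHOLESTEROL"]

_DOSE_VALUES = [5, 10, 20, 25, 50, 75, 100, 150, 300, 500]

_PHRASES = [
    ("BEDTIME", Freq.QHS, 1),
    ("ONCE DAILY", Freq.QD, 1),
    ("TWICE DAILY", Freq.BID, 2),
    ("THREE TIMES A DAY", Freq.TID, 3),
    ("FOUR TIMES A DAY", Freq.QID, 4),
]

_WEEKDAYS = ["MONDAY", "TUESDAY", "WEDNESDAY", "THURSDAY", "FRIDAY", "SATURDAY", "SUNDAY"]

#: Unparseable sig texts: no dose-grammar match, no schedule cue.
_ANOMALY_SIGS = [
    "USE PER PROTOCOL",
    "SEE NOTE IN CHART",
    "APPLY SPARINGLY TO AFFECTED AREA",
    "",
]


def default_formulary() -> list[FormularyEntry]:
    """A small synthetic formulary spanning drugs of interest, excluded
    classes, short-course antibiotics and non-drug supplies."""
    entries = [
        FormularyEntry(name, cls) for name, cls in _OF_INTEREST + _EXCLUDED
    ]
    entries += [
        FormularyEntry("AMOXICILLIN", "ANTIBIOTIC"),
        FormularyEntry("CIPROFLOXACIN", "ANTIBIOTIC"),
    ]
    entries += [FormularyEntry(name, "SUPPLY", is_supply=True) for name in _SUPPLIES]
    return entries


def _category_for(entry: FormularyEntry, policy: ClassificationPolicy) -> Category:
    if entry.is_supply:
        return Category.SUPPLY
    if entry.drug_class in policy.excluded_classes:
        return Category.EXCLUDED
    return Category.OF_INTEREST


def _weighted_choice(rng: random.Random, mix: dict) -> str:
    r = rng.random()
    acc = 0.0
    for name in ARCHETYPES:
        acc += mix.get(name, 0.0)
        if r < acc:
            return name
    return ARCHETYPES[0]


def _make_entry(
    rng: random.Random,
    archetype: str,
    drug: FormularyEntry,
    policy: ClassificationPolicy,
) -> tuple[RawMedicationEntry, EntryGroundTruth]:
    name = drug.canonical_name
    category = _category_for(drug, policy)
    v = float(rng.choice(_DOSE_VALUES))
    phrase, code, per_day = rng.choice(_PHRASES)
    form = rng.choice(["TAB", "CAP"])
    admin = "TABLET" if form == "TAB" else "CAPSULE"

    if archetype == "clean_name_dose":
        qty = rng.choice([1, 1, 1, 2])
        qword = "ONE" if qty == 1 else "TWO"
        plural = "" if qty == 1 else "S"
        entry = RawMedicationEntry(
            name_text=f"{name} {v:g} MG, {form}",
            sig_text=f"TAKE {qword} {admin}{plural} BY MOUTH {phrase}",
        )
        truth = EntryGroundTruth(
            base_name=name, category=category, parseable=True,
            dose_value=v, dose_unit=Unit.MG, schedule_code=code,
            per_day=per_day, quantity=qty, total_daily_dose=v * qty * per_day,
        )
    elif archetype == "sig_dose":
        entry = RawMedicationEntry(
            name_text=f"{name} {form}",
            sig_text=f"{v:g}MG BY MOUTH {phrase}",
        )
        truth = EntryGroundTruth(
            base_name=name, category=category, parseable=True,
            dose_value=v, dose_unit=Unit.MG, schedule_code=code,
            per_day=per_day, total_daily_dose=v * per_day,
        )
    elif archetype == "decorated":
        style = rng.randrange(3)
        tokens = name.split()
        if style == 0 and len(tokens) >= 2:
            name_text = f"{tokens[0]}*{phrase}*{' '.join(tokens[1:])} {form}"
        elif style == 1 and name in _BRANDS:
            name_text = f"{name}({_BRANDS[name]}) {form}, SA"
        else:
            name_text = f"{name}<{rng.choice(_INDICATIONS)}> {form}"
        entry = RawMedicationEntry(
            name_text=name_text,
            sig_text=f"{v:g}MG BY MOUTH {phrase}",
        )
        truth = EntryGroundTruth(
            base_name=name, category=category, parseable=True,
            dose_value=v, dose_unit=Unit.MG, schedule_code=code,
            per_day=per_day, total_daily_dose=v * per_day,
        )
    elif archetype == "as_directed":
        entry = RawMedicationEntry(
            name_text=f"{name} {v:g}MG {form}",
            sig_text="TAKE AS DIRECTED BY MOUTH AS INSTRUCTED BY CLINIC",
        )
        truth = EntryGroundTruth(
            base_name=name, category=category, parseable=True,
            dose_value=v, dose_unit=Unit.MG, schedule_code=Freq.AS_DIRECTED,
        )
    elif archetype == "prn":
        entry = RawMedicationEntry(
            name_text=f"{name} {v:g}MG {form}",
            sig_text=f"TAKE ONE {admin} BY MOUTH AS NEEDED FOR PAIN",
        )
        truth = EntryGroundTruth(
            base_name=name, category=category, parseable=True,
            dose_value=v, dose_unit=Unit.MG, schedule_code=Freq.PRN,
        )
    elif archetype == "weekly":
        k = rng.choice([2, 3])
        days = rng.sample(_WEEKDAYS, k)
        days.sort(key=_WEEKDAYS.index)
        day_list = ", ".join(days[:-1]) + " AND " + days[-1]
        entry = RawMedicationEntry(
            name_text=f"{name} {form}",
            sig_text=f"{v:g}MG MOUTH {day_list}",
        )
        truth = EntryGroundTruth(
            base_name=name, category=category, parseable=True,
            dose_value=v, dose_unit=Unit.MG,
            schedule_code=Freq.WEEKLY_DAYS, per_week=k,
        )
    elif archetype == "conflict":
        entry = RawMedicationEntry(
            name_text=f"{name}, COATED({v:g} MG) {form}, EC",
            sig_text=f"{2 * v:g}MG MOUTH",
        )
        truth = EntryGroundTruth(
            base_name=name, category=category, parseable=True,
            dose_value=2 * v, dose_unit=Unit.MG, schedule_code=Freq.UNKNOWN,
        )
    else:  # pragma: no cover - guarded by GeneratorSpec validation
        raise ValueError(archetype)
    return entry, truth


def _make_anomalous_entry(
    rng: random.Random, drug: FormularyEntry, policy: ClassificationPolicy
) -> tuple[RawMedicationEntry, EntryGroundTruth]:
    """An entry no grammar pattern matches: no dose, no schedule cue."""
    entry = RawMedicationEntry(
        name_text=f"{drug.canonical_name} MISC",
        sig_text=rng.choice(_ANOMALY_SIGS),
    )
    return entry, EntryGroundTruth(
        base_name=drug.canonical_name,
        category=_category_for(drug, policy),
        parseable=False,
    )


def generate_medication_entries(
    spec: GeneratorSpec,
    formulary: Optional[Sequence[FormularyEntry]] = None,
    policy: ClassificationPolicy = ClassificationPolicy(),
) -> list[tuple[RawMedicationEntry, EntryGroundTruth]]:
    """Generate ``spec.n`` messy medication entries with ground truth.

    Archetypes are drawn from ``spec.dialect_mix``; with probability
    ``spec.anomaly_rate`` an entry is replaced by one that defeats every
    grammar pattern (ground truth marks it unparseable).  Drugs are drawn
    from the non-supply formulary entries.  Deterministic under the seed.
    """
    formulary = list(formulary) if formulary is not None else default_formulary()
    drugs = [e for e in formulary if not e.is_supply]
    if not drugs:
        raise ValueError("formulary must contain at least one non-supply drug")
    rng = random.Random(spec.seed)
    out = []
    for _ in range(spec.n):
        drug = rng.choice(drugs)
        if rng.random() < spec.anomaly_rate:
            out.append(_make_anomalous_entry(rng, drug, policy))
        else:
            archetype = _weighted_choice(rng, spec.dialect_mix)
            out.append(_make_entry(rng, archetype, drug, policy))
    return out


_HTN_CODES = ["401.1", "401.9", "402.90", "403.90", "405.99"]
_DM_CODES = ["250.00", "250.02", "250.60"]
_NOISE_CODES = ["272.4", "530.81", "311", "715.90", "V58.69", "285.9"]


def generate_patient_cohort(
    spec: GeneratorSpec,
    formulary: Optional[Sequence[FormularyEntry]] = None,
    policy: ClassificationPolicy = ClassificationPolicy(),
) -> list[tuple["PatientSnapshot", PatientGroundTruth]]:
    """Generate ``spec.n`` patient snapshots with ground truth.

    Ages are uniform on the configured bounds; hypertension and diabetes
    are independent Bernoulli draws at the configured prevalences,
    realized as conventional ICD-9 codes plus unrelated noise codes;
    appointments are uniform in the configured window; each patient
    carries a medication list of distinct drugs mixing of-interest,
    excluded and supply entries.  The ground-truth drugs-of-interest count
    is the number of distinct OF_INTEREST base names on the list.
    """
    from .cohort import PatientSnapshot

    formulary = list(formulary) if formulary is not None else default_formulary()
    drugs = [e for e in formulary if not e.is_supply]
    supplies = [e for e in formulary if e.is_supply]
    p = spec.cohort_params
    rng = random.Random(spec.seed)
    cohort = []
    for i in range(spec.n):
        age = rng.randint(p.age_min, p.age_max)
        htn = rng.random() < p.htn_prevalence
        dm = rng.random() < p.dm_prevalence
        codes = set()
        if htn:
            codes.add(rng.choice(_HTN_CODES))
        if dm:
            codes.add(rng.choice(_DM_CODES))
        for _ in range(rng.randint(0, 3)):
            codes.add(rng.choice(_NOISE_CODES))
        appt = p.window_start + dt.timedelta(days=rng.randrange(p.window_days))

        n_drugs = min(len(drugs), 1 + _poisson(rng, max(p.mean_drugs_per_patient - 1, 0)))
        chosen = rng.sample(drugs, n_drugs)
        if supplies and rng.random() < 0.3:
            chosen.append(rng.choice(supplies))
        meds = []
        truths = []
        n_of_interest = 0
        seen_bases = set()
        for drug in chosen:
            if drug.is_supply:
                entry = RawMedicationEntry(name_text=drug.canonical_name, sig_text="")
                truth = EntryGroundTruth(
                    base_name=drug.canonical_name,
                    category=Category.SUPPLY,
                    parseable=False,
                )
            else:
                if rng.random() < spec.anomaly_rate:
                    entry, truth = _make_anomalous_entry(rng, drug, policy)
                else:
                    archetype = _weighted_choice(rng, spec.dialect_mix)
                    entry, truth = _make_entry(rng, archetype, drug, policy)
            meds.append(entry)
            truths.append(truth)
            if truth.category is Category.OF_INTEREST and truth.base_name not in seen_bases:
                seen_bases.add(truth.base_name)
                n_of_interest += 1
        snapshot = PatientSnapshot(
            patient_id=f"P{i:05d}",
            age=age,
            icd9_codes=frozenset(codes),
            appointment_date=appt,
            clinic_name=rng.choice(["PRIMARY CARE A", "PRIMARY CARE B", "GERIATRICS"]),
            medications=tuple(meds),
            contact=f"PATIENT {i:05d} / 555-01{i % 100:02d}",
        )
        cohort.append(
            (
                snapshot,
                PatientGroundTruth(
                    htn=htn, dm=dm,
                    n_drugs_of_interest=n_of_interest,
                    entry_truths=tuple(truths),
                ),
            )
        )
    return cohort


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's method; lam is small here so this is fine."""
    if lam <= 0:
        return 0
    limit = pow(2.718281828459045, -lam)
    k, prod = 0, rng.random()
    while prod > limit:
        k += 1
        prod *= rng.random()
    return k
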