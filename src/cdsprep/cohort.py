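"""Recruitment stratification: age x drugs-of-interest screening grids.

Patients with clinic appointments inside a date window are bucketed by age
band and by the number of prescribed drugs of interest (after weeding out
supplies and excluded classes), and each cell is annotated with how many
of its patients carry only hypertension, only diabetes, or both — the
ICD-9 scan behind the H/D/B annotations of a polypharmacy recruitment
screen.  Cells retain their patient lists so a coordinator can pull the
contact details for any highlighted stratum.
"""
from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .formulary import Category, ClassificationPolicy, FormularyEntry, classify
from .patterns import DEFAULT_REGISTRY, PatternRegistry
from .sig_parser import RawMedicationEntry, parse_entry

__all__ = [
    "PatientSnapshot",
    "CodePolicy",
    "AgeBand",
    "GridCell",
    "ScreeningGrid",
    "comorbidity_flags",
    "count_drugs_of_interest",
    "build_screening_grid",
    "list_patients_in_cells",
    "DEFAULT_AGE_BANDS",
]

logger = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^[VE]?\d+(\.\d+)?$")


@dataclass(frozen=True)
class PatientSnapshot:
    """One patient as extracted for screening: demographics, diagnosis
    codes, the scheduled appointment, and the raw medication list."""

    patient_id: str
    age: int
    icd9_codes: frozenset[str]
    appointment_date: dt.date
    clinic_name: str = ""
    medications: tuple[RawMedicationEntry, ...] = ()
    contact: str = ""

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")


@dataclass(frozen=True)
class CodePolicy:
    """ICD-9 category prefixes defining each screened condition.

    Defaults follow the conventional groupings: hypertension 401-405,
    diabetes mellitus 250.  Matching is on the integer category before
    the dot; V/E codes never match a numeric prefix.
    """

    hypertension_prefixes: frozenset[int] = frozenset(range(401, 406))
    diabetes_prefixes: frozenset[int] = frozenset({250})


def match_code_prefixes(icd9_codes: Iterable[str], prefixes: frozenset[int]) -> bool:
    """True iff any code's category (the part before the dot) is in ``prefixes``.

    Malformed code strings are skipped with a logged warning.
    """
    for code in icd9_codes:
        code = code.strip()
        if not _CODE_RE.match(code):
            logger.warning("skipping malformed ICD9 code %r", code)
            continue
        category = code.split(".", 1)[0]
        if category[0] in "VE":  # V/E supplementary codes: not numeric categories
            continue
        if int(category) in prefixes:
            return True
    return False


def comorbidity_flags(
    icd9_codes: Iterable[str], code_policy: CodePolicy = CodePolicy()
) -> tuple[bool, bool]:
    """Scan a patient's ICD-9 codes for hypertension and diabetes."""
    codes = list(icd9_codes)
    return (
        match_code_prefixes(codes, code_policy.hypertension_prefixes),
        match_code_prefixes(codes, code_policy.diabetes_prefixes),
    )


def count_drugs_of_interest(
    medications: Sequence[RawMedicationEntry],
    formulary: Sequence[FormularyEntry],
    policy: ClassificationPolicy = ClassificationPolicy(),
    registry: PatternRegistry = DEFAULT_REGISTRY,
) -> int:
    """Number of distinct drugs of interest on a medication list.

    Each entry is parsed and classified; entries normalizing to the same
    base name count once.
    """
    names = set()
    for med in medications:
        classified = classify(parse_entry(med, registry), formulary, policy, registry)
        if classified.category is Category.OF_INTEREST:
            names.add(classified.base_name)
    return len(names)


@dataclass(frozen=True)
class AgeBand:
    """A closed integer age interval; ``high`` None means open-ended (85+)."""

    low: int
    high: Optional[int]

    @property
    def label(self) -> str:
        return f"{self.low}+" if self.high is None else f"{self.low}-{self.high}"

    def contains(self, age: int) -> bool:
        return age >= self.low and (self.high is None or age <= self.high)


DEFAULT_AGE_BANDS: tuple[AgeBand, ...] = (
    AgeBand(65, 74),
    AgeBand(75, 84),
    AgeBand(85, None),
)

#: Label for patients whose age falls outside every configured band.
OTHER_BAND = "other"


@dataclass(frozen=True)
class GridCell:
    n_total: int = 0
    n_htn_only: int = 0
    n_dm_only: int = 0
    n_both: int = 0
    patients: tuple[PatientSnapshot, ...] = ()


@dataclass(frozen=True)
class ScreeningGrid:
    window: tuple[dt.date, dt.date]
    age_band_labels: tuple[str, ...]
    drug_count_labels: tuple[str, ...]
    cells: Mapping[tuple[str, str], GridCell]

    @property
    def n_patients(self) -> int:
        return sum(c.n_total for c in self.cells.values())


def _drug_count_label(count: int, max_count: int) -> str:
    return f"{max_count}+" if count >= max_count else str(count)


def build_screening_grid(
    cohort: Sequence[PatientSnapshot],
    window: tuple[dt.date, dt.date],
    formulary: Sequence[FormularyEntry],
    age_bands: Sequence[AgeBand] = DEFAULT_AGE_BANDS,
    policy: ClassificationPolicy = ClassificationPolicy(),
    code_policy: CodePolicy = CodePolicy(),
    registry: PatternRegistry = DEFAULT_REGISTRY,
    max_drug_count: int = 10,
) -> ScreeningGrid:
    """Build the age-band x drug-count screening grid for a cohort.

    The window is half-open ``[start, end)`` so consecutive weekly runs
    never double-count a boundary day.  A patient appearing more than once
    is counted once at the earliest in-window appointment.  Ages outside
    every configured band land in an explicit "other" band rather than
    being dropped; drug counts at or above ``max_drug_count`` share a top
    overflow bucket.  Output ordering is deterministic and independent of
    the input ordering of the cohort.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must be after start")

    in_window: dict[str, PatientSnapshot] = {}
    for p in cohort:
        if not (start <= p.appointment_date < end):
            continue
        seen = in_window.get(p.patient_id)
        if seen is None or (p.appointment_date, p.patient_id) < (
            seen.appointment_date,
            seen.patient_id,
        ):
            in_window[p.patient_id] = p

    band_labels = tuple(b.label for b in age_bands) + (OTHER_BAND,)
    count_labels = tuple(
        _drug_count_label(c, max_drug_count) for c in range(max_drug_count + 1)
    )

    assignments: dict[tuple[str, str], list[tuple[PatientSnapshot, bool, bool]]] = {
        (b, c): [] for b in band_labels for c in count_labels
    }
    for p in in_window.values():
        band = next((b.label for b in age_bands if b.contains(p.age)), OTHER_BAND)
        count = count_drugs_of_interest(p.medications, formulary, policy, registry)
        htn, dm = comorbidity_flags(p.icd9_codes, code_policy)
        assignments[(band, _drug_count_label(count, max_drug_count))].append((p, htn, dm))

    cells = {}
    for key, members in assignments.items():
        members.sort(key=lambda m: (m[0].appointment_date, m[0].patient_id))
        cells[key] = GridCell(
            n_total=len(members),
            n_htn_only=sum(1 for _, h, d in members if h and not d),
            n_dm_only=sum(1 for _, h, d in members if d and not h),
            n_both=sum(1 for _, h, d in members if h and d),
            patients=tuple(p for p, _, _ in members),
        )
    return ScreeningGrid(
        window=(start, end),
        age_band_labels=band_labels,
        drug_count_labels=count_labels,
        cells=cells,
    )


def list_patients_in_cells(
    grid: ScreeningGrid, selected_cells: Iterable[tuple[str, str]]
) -> list[PatientSnapshot]:
    """Patients in the selected cells, sorted by appointment date then id.

    The recruitment workflow's "Show Patient List": highlight strata,
    get the people (with their contact blocks) behind the counts.
    """
    patients: list[PatientSnapshot] = []
    for key in selected_cells:
        if key not in grid.cells:
            raise KeyError(f"no such grid cell: {key}")
        patients.extend(grid.cells[key].patients)
    patients.sort(key=lambda p: (p.appointment_date, p.patient_id))
    return patients


def grid_to_frame(grid: ScreeningGrid):
    """Render the grid as a table: rows = age bands, columns = drug counts,
    each cell formatted ``n (H.. D.. B..)`` in the recruitment-screen style."""
    import pandas as pd

    data = {}
    for band in grid.age_band_labels:
        row = {}
        for count in grid.drug_count_labels:
            c = grid.cells[(band, count)]
            row[count] = f"{c.n_total} (H{c.n_htn_only} D{c.n_dm_only} B{c.n_both})"
        data[band] = row
    return pd.DataFrame.from_dict(data, orient="index")[list(grid.drug_count_labels)]
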