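"""Staging-store preprocessing: minimal derived facts for real-time lookup.

A decision-support front end cannot afford warehouse-latency queries at the
point of care, so the warehouse extract is reduced ahead of time to the
minimum the rules need: per patient, a boolean flag per disease in a
configured panel (derived from the ICD-9 history, with no raw codes
retained) and, for a configured drug panel, the drugs previously but not
currently prescribed with the date of their most recent prescription.
Records are staged in full-replacement refresh cycles, emulating a weekly
warehouse download.
"""
from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .cohort import match_code_prefixes

__all__ = [
    "MedicationHistoryEvent",
    "StagedPatientRecord",
    "StagingStore",
    "preprocess_diagnoses",
    "derive_prior_medications",
]


@dataclass(frozen=True)
class MedicationHistoryEvent:
    """One historical prescription fill: patient, normalized drug name, date."""

    patient_id: str
    base_name: str
    prescription_date: dt.date


@dataclass(frozen=True)
class StagedPatientRecord:
    """The staged view of one patient: disease flags and prior medications.

    Deliberately minimal — no ICD-9 codes and no per-fill history survive
    staging, only the booleans and (name, last date) pairs the real-time
    rules consume.
    """

    patient_id: str
    disease_flags: Mapping[str, bool]
    prior_medications: tuple[tuple[str, dt.date], ...]
    staged_at: str

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "disease_flags": dict(self.disease_flags),
            "prior_medications": [
                [name, date.isoformat()] for name, date in self.prior_medications
            ],
            "staged_at": self.staged_at,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StagedPatientRecord":
        return cls(
            patient_id=str(d["patient_id"]),
            disease_flags={k: bool(v) for k, v in d["disease_flags"].items()},
            prior_medications=tuple(
                (name, dt.date.fromisoformat(date))
                for name, date in d["prior_medications"]
            ),
            staged_at=str(d["staged_at"]),
        )


def preprocess_diagnoses(
    icd9_codes: Iterable[str], disease_panel: Mapping[str, Sequence[int]]
) -> dict[str, bool]:
    """Reduce an ICD-9 code history to one boolean per panel disease.

    Nothing but the flags is returned (minimum-necessary contract); codes
    matching no panel prefix simply leave every flag false.
    """
    if not disease_panel:
        raise ValueError("disease panel must be non-empty")
    codes = list(icd9_codes)
    return {
        disease: match_code_prefixes(codes, frozenset(int(p) for p in prefixes))
        for disease, prefixes in disease_panel.items()
    }


def derive_prior_medications(
    history: Sequence[MedicationHistoryEvent],
    current: Iterable[str],
    drug_panel: Iterable[str],
) -> list[tuple[str, dt.date]]:
    """Panel drugs previously but not currently prescribed, with last date.

    For each panel drug present in the history but absent from the current
    medication set, emits ``(name, max prescription date)``; sorted by name.
    Names are assumed already normalized to base names.
    """
    current_set = set(current)
    panel_set = set(drug_panel)
    last_date: dict[str, dt.date] = {}
    for event in history:
        if event.base_name not in panel_set or event.base_name in current_set:
            continue
        prev = last_date.get(event.base_name)
        if prev is None or event.prescription_date > prev:
            last_date[event.base_name] = event.prescription_date
    return sorted(last_date.items())


class StagingStore:
    """An embedded single-file staging table with refresh-cycle semantics.

    ``stage`` inserts records under a refresh tag; re-staging a patient
    fully replaces that patient's record (weekly-refresh semantics).
    ``query`` returns the most recently staged record, or None for an
    unknown patient — explicitly distinguishable from a staged record
    whose flags are all false.
    """

    def __init__(self) -> None:
        self._records: dict[str, StagedPatientRecord] = {}

    def stage(
        self, records: Iterable[StagedPatientRecord], refresh_tag: Optional[str] = None
    ) -> None:
        for record in records:
            if refresh_tag is not None and record.staged_at != refresh_tag:
                record = StagedPatientRecord(
                    patient_id=record.patient_id,
                    disease_flags=record.disease_flags,
                    prior_medications=record.prior_medications,
                    staged_at=refresh_tag,
                )
            self._records[record.patient_id] = record

    def query(self, patient_id: str) -> Optional[StagedPatientRecord]:
        return self._records.get(patient_id)

    def __len__(self) -> int:
        return len(self._records)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for pid in sorted(self._records):
                fh.write(json.dumps(self._records[pid].to_dict()) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "StagingStore":
        store = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    store.stage([StagedPatientRecord.from_dict(json.loads(line))])
        return store


def stage_patient(
    patient_id: str,
    icd9_codes: Iterable[str],
    history: Sequence[MedicationHistoryEvent],
    current: Iterable[str],
    disease_panel: Mapping[str, Sequence[int]],
    drug_panel: Iterable[str],
    refresh_tag: str,
) -> StagedPatientRecord:
    """Run both preprocessing reductions and assemble one staged record."""
    return StagedPatientRecord(
        patient_id=patient_id,
        disease_flags=preprocess_diagnoses(icd9_codes, disease_panel),
        prior_medications=tuple(derive_prior_medications(history, current, drug_panel)),
        staged_at=refresh_tag,
    )
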