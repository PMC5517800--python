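"""File-based I/O: delimited and JSON-lines readers/writers.

The toolkit is file-based by design — extraction from the source EHR is
out of scope — so every pipeline stage reads and writes small, explicit
text formats: CSV/TSV or JSON-lines for medication entries and cohorts,
JSON-lines for parsed output and staged records, TSV for summaries.
"""
from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort import PatientSnapshot, ScreeningGrid
from .fixtures import EntryGroundTruth, PatientGroundTruth
from .sig_parser import ParsedMedication, RawMedicationEntry

ENTRY_COLUMNS = ["name_text", "sig_text", "source", "dose_text"]


def read_entries(path: str | Path, fmt: str = "csv") -> list[RawMedicationEntry]:
    """Read raw medication entries from csv/tsv/jsonl."""
    if fmt == "jsonl":
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    entries.append(RawMedicationEntry.from_dict(json.loads(line)))
        return entries
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return [RawMedicationEntry.from_dict(row) for row in df.to_dict("records")]


def write_entries_csv(entries: Iterable[RawMedicationEntry], path: str | Path) -> None:
    pd.DataFrame([e.to_dict() for e in entries], columns=ENTRY_COLUMNS).to_csv(
        path, index=False
    )


def write_parsed_jsonl(parsed: Iterable[ParsedMedication], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in parsed:
            fh.write(json.dumps(p.to_dict()) + "\n")


def write_parsed_summary_tsv(
    parsed: Sequence[ParsedMedication], path: str | Path
) -> None:
    rows = []
    for p in parsed:
        rows.append(
            {
                "drug": p.raw.name_text,
                "dose": "" if p.dose is None else p.dose.value,
                "unit": "" if p.dose is None else p.dose.unit.value,
                "schedule": p.schedule.code.value,
                "daily_dose": ""
                if p.total_daily_dose is None
                else p.total_daily_dose.value,
                "status": "|".join(sorted(f.value for f in p.status)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def parse_report(parsed: Sequence[ParsedMedication]) -> dict:
    """Parse-failure rate and per-flag counts for a batch."""
    n = len(parsed)
    flag_counts: dict[str, int] = {}
    for p in parsed:
        for f in p.status:
            flag_counts[f.value] = flag_counts.get(f.value, 0) + 1
    n_no_tdd = sum(1 for p in parsed if p.total_daily_dose is None)
    return {
        "n_entries": n,
        "n_without_total_daily_dose": n_no_tdd,
        "failure_rate": (n_no_tdd / n) if n else 0.0,
        "flag_counts": dict(sorted(flag_counts.items())),
    }


def snapshot_to_dict(p: PatientSnapshot) -> dict:
    return {
        "patient_id": p.patient_id,
        "age": p.age,
        "icd9_codes": sorted(p.icd9_codes),
        "appointment_date": p.appointment_date.isoformat(),
        "clinic_name": p.clinic_name,
        "medications": [m.to_dict() for m in p.medications],
        "contact": p.contact,
    }


def snapshot_from_dict(d: dict) -> PatientSnapshot:
    return PatientSnapshot(
        patient_id=str(d["patient_id"]),
        age=int(d["age"]),
        icd9_codes=frozenset(str(c) for c in d.get("icd9_codes", [])),
        appointment_date=dt.date.fromisoformat(d["appointment_date"]),
        clinic_name=str(d.get("clinic_name", "")),
        medications=tuple(
            RawMedicationEntry.from_dict(m) for m in d.get("medications", [])
        ),
        contact=str(d.get("contact", "")),
    )


def read_cohort_jsonl(path: str | Path) -> list[PatientSnapshot]:
    cohort = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                cohort.append(snapshot_from_dict(json.loads(line)))
    return cohort


def write_cohort_jsonl(cohort: Iterable[PatientSnapshot], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in cohort:
            fh.write(json.dumps(snapshot_to_dict(p)) + "\n")


def write_grid(grid: ScreeningGrid, out_dir: str | Path) -> None:
    """Write a grid as a TSV matrix plus a JSON cell-detail file."""
    from .cohort import grid_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid_to_frame(grid).to_csv(out / "grid.tsv", sep="\t")
    detail = {
        "window": [grid.window[0].isoformat(), grid.window[1].isoformat()],
        "cells": {
            f"{band}|{count}": {
                "n_total": c.n_total,
                "n_htn_only": c.n_htn_only,
                "n_dm_only": c.n_dm_only,
                "n_both": c.n_both,
                "patient_ids": [p.patient_id for p in c.patients],
            }
            for (band, count), c in grid.cells.items()
        },
    }
    (out / "grid.json").write_text(json.dumps(detail, indent=1))


def write_ground_truth_jsonl(
    truths: Iterable[EntryGroundTruth | PatientGroundTruth], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for t in truths:
            if isinstance(t, EntryGroundTruth):
                d = {
                    "base_name": t.base_name,
                    "category": t.category.value,
                    "parseable": t.parseable,
                    "dose_value": t.dose_value,
                    "dose_unit": None if t.dose_unit is None else t.dose_unit.value,
                    "schedule_code": t.schedule_code.value,
                    "per_day": t.per_day,
                    "per_week": t.per_week,
                    "quantity": t.quantity,
                    "total_daily_dose": t.total_daily_dose,
                }
            else:
                d = {
                    "htn": t.htn,
                    "dm": t.dm,
                    "n_drugs_of_interest": t.n_drugs_of_interest,
                }
            fh.write(json.dumps(d) + "\n")
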