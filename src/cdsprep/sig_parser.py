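"""Dose / schedule extraction from free-text medication fields.

The prescription stream delivers two free-text fields per medication: a
Drug Name field (which often embeds the dose, e.g. ``GABAPENTIN 300 MG,
CAP``) and a Sig field with the administration instruction (``TAKE ONE
CAPSULE BY MOUTH THREE TIMES A DAY``).  This module scans both with a small
pattern grammar, maps frequency phrases onto prescription abbreviations
(QHS, QD, BID, TID, QID, ...), and computes the total daily dose

    total daily dose = dose x quantity per administration x administrations/day

whenever a dose and a daily schedule are both recoverable.  Parsing never
fails: entries whose text defeats the grammar come back with status flags
(NO_DOSE, NO_SCHEDULE, ...) and the raw text retained verbatim so a
downstream display can always fall back to the unprocessed fields.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .patterns import DEFAULT_REGISTRY, PER_DAY, PatternRegistry

__all__ = [
    "Source",
    "SourceField",
    "Unit",
    "Flag",
    "RawMedicationEntry",
    "DoseMatch",
    "ScheduleCode",
    "ParsedMedication",
    "TotalDailyDose",
    "extract_dose",
    "extract_schedule",
    "extract_quantity",
    "parse_entry",
    "total_daily_dose",
]


class Source(str, enum.Enum):
    """Origin of a raw medication entry."""

    VA_PRESCRIBED = "VA_PRESCRIBED"
    NON_VA = "NON_VA"
    CDW = "CDW"


class SourceField(str, enum.Enum):
    NAME = "NAME"
    SIG = "SIG"


class Unit(str, enum.Enum):
    MG = "MG"
    MCG = "MCG"
    MEQ = "MEQ"


class Flag(str, enum.Enum):
    """Parse status flags carried on a ParsedMedication."""

    OK = "OK"
    NO_DOSE = "NO_DOSE"
    NO_SCHEDULE = "NO_SCHEDULE"
    DOSE_CONFLICT = "DOSE_CONFLICT"
    PRN = "PRN"
    WEEKLY = "WEEKLY"
    AS_DIRECTED = "AS_DIRECTED"


class Freq(str, enum.Enum):
    """Schedule code vocabulary: daily abbreviations plus the non-daily
    outcomes (weekday lists, as-needed, as-directed, unparseable)."""

    QD = "QD"
    QAM = "QAM"
    QHS = "QHS"
    BID = "BID"
    TID = "TID"
    QID = "QID"
    Q4H = "Q4H"
    Q12H = "Q12H"
    WEEKLY_DAYS = "WEEKLY_DAYS"
    PRN = "PRN"
    AS_DIRECTED = "AS_DIRECTED"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class RawMedicationEntry:
    """A Drug Name / Sig free-text pair exactly as retrieved from the EHR.

    ``dose_text`` mirrors the EHR's dedicated dose field, which in practice
    is almost always blank with the dose embedded in name or sig instead.
    """

    name_text: str
    sig_text: str = ""
    source: Source = Source.VA_PRESCRIBED
    dose_text: str = ""

    def __post_init__(self) -> None:
        if not self.name_text:
            raise ValueError("name_text must be non-empty")

    def to_dict(self) -> dict:
        return {
            "name_text": self.name_text,
            "sig_text": self.sig_text,
            "source": self.source.value,
            "dose_text": self.dose_text,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RawMedicationEntry":
        return cls(
            name_text=str(d["name_text"]),
            sig_text=str(d.get("sig_text") or ""),
            source=Source(d.get("source") or "VA_PRESCRIBED"),
            dose_text=str(d.get("dose_text") or ""),
        )


@dataclass(frozen=True)
class DoseMatch:
    """One dose-grammar match: a value, unit and its span in the source."""

    value: float
    unit: Unit
    span: tuple[int, int] = (0, 0)
    source_field: SourceField = SourceField.NAME

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("dose value must be positive")

    def same_dose(self, other: "DoseMatch") -> bool:
        return self.value == other.value and self.unit == other.unit


@dataclass(frozen=True)
class ScheduleCode:
    """A schedule outcome: a code plus its per-day or per-week multiplier.

    ``per_day`` is defined exactly for the daily abbreviations (QD=QAM=QHS=1,
    BID=Q12H=2, TID=3, QID=4, Q4H=6); ``per_week`` only for weekday lists.
    """

    code: Freq
    per_day: Optional[int] = None
    per_week: Optional[int] = None

    def __post_init__(self) -> None:
        expected = PER_DAY.get(self.code.value)
        if expected is not None and self.per_day != expected:
            raise ValueError(f"{self.code.value} implies per_day={expected}")
        if expected is None and self.per_day is not None:
            raise ValueError(f"{self.code.value} carries no per_day multiplier")
        if (self.code is Freq.WEEKLY_DAYS) != (self.per_week is not None):
            raise ValueError("per_week is defined iff code is WEEKLY_DAYS")

    @classmethod
    def daily(cls, code: Freq | str) -> "ScheduleCode":
        code = Freq(code)
        return cls(code=code, per_day=PER_DAY[code.value])

    @classmethod
    def weekly(cls, per_week: int) -> "ScheduleCode":
        return cls(code=Freq.WEEKLY_DAYS, per_week=per_week)


UNKNOWN_SCHEDULE = ScheduleCode(code=Freq.UNKNOWN)


@dataclass(frozen=True)
class TotalDailyDose:
    value: float
    unit: Unit


@dataclass(frozen=True)
class ParsedMedication:
    """Structured parse of one raw entry.

    ``dose`` is the governing dose (a dose stated in the sig wins over one
    embedded in the drug name); a losing, disagreeing match is kept in
    ``conflict_dose`` and flagged rather than silently dropped.  Additional
    matches beyond the first in either field land in ``extra_doses`` for
    diagnostics.  The raw entry is always retained verbatim.
    """

    raw: RawMedicationEntry
    dose: Optional[DoseMatch]
    schedule: ScheduleCode
    quantity_multiplier: int = 1
    total_daily_dose: Optional[TotalDailyDose] = None
    status: frozenset[Flag] = frozenset()
    conflict_dose: Optional[DoseMatch] = None
    extra_doses: tuple[DoseMatch, ...] = ()

    def to_dict(self) -> dict:
        return {
            "raw": self.raw.to_dict(),
            "dose": None
            if self.dose is None
            else {
                "value": self.dose.value,
                "unit": self.dose.unit.value,
                "source_field": self.dose.source_field.value,
            },
            "quantity_multiplier": self.quantity_multiplier,
            "schedule": {
                "code": self.schedule.code.value,
                "per_day": self.schedule.per_day,
                "per_week": self.schedule.per_week,
            },
            "total_daily_dose": None
            if self.total_daily_dose is None
            else {
                "value": self.total_daily_dose.value,
                "unit": self.total_daily_dose.unit.value,
            },
            "status": sorted(f.value for f in self.status),
            "conflict_dose": None
            if self.conflict_dose is None
            else {
                "value": self.conflict_dose.value,
                "unit": self.conflict_dose.unit.value,
                "source_field": self.conflict_dose.source_field.value,
            },
        }


def extract_dose(
    text: str,
    registry: PatternRegistry = DEFAULT_REGISTRY,
    source_field: SourceField = SourceField.NAME,
) -> list[DoseMatch]:
    """Return every non-overlapping, left-to-right dose-grammar match.

    The grammar accepts an optional opening parenthesis, a decimal number,
    optional whitespace, a unit (MG/MCG/MEQ, any letter case) and an
    optional closing parenthesis — matching strings like ``32.5 MG``,
    ``18MCG`` and ``(1.5 meq)``.  No match is a normal outcome.
    """
    matches = []
    for m in registry.dose_pattern.finditer(text):
        value = float(m.group("value"))
        if value <= 0:
            # "0 MG" satisfies the grammar but is not a dose; the match is
            # dropped after consuming its span, so scanning is unchanged.
            continue
        matches.append(
            DoseMatch(
                value=value,
                unit=Unit(m.group("unit").upper()),
                span=m.span(),
                source_field=source_field,
            )
        )
    return matches


def extract_schedule(
    text: str, registry: PatternRegistry = DEFAULT_REGISTRY
) -> ScheduleCode:
    """Map a sig string to a schedule code.

    Cue classes are tried in a fixed precedence order: as-needed phrases
    (PRN), then as-directed, then the frequency-phrase grammar, then
    weekday lists; anything else is UNKNOWN.  PRN outranks a frequency
    phrase because a maximum-use cap ("DO NOT USE MORE THAN TWICE PER
    WEEK") does not establish a standing daily schedule.
    """
    if not text:
        return UNKNOWN_SCHEDULE
    if registry.prn_pattern.search(text):
        return ScheduleCode(code=Freq.PRN)
    if registry.as_directed_pattern.search(text):
        return ScheduleCode(code=Freq.AS_DIRECTED)
    m = registry.schedule_pattern.search(text)
    if m:
        code = registry.schedule_code_for_phrase(m.group(0))
        return ScheduleCode.daily(code)
    days = {d.group(0).upper() for d in registry.weekday_pattern.finditer(text)}
    if days:
        return ScheduleCode.weekly(per_week=len(days))
    return UNKNOWN_SCHEDULE


def extract_cdw_schedule(
    text: str, registry: PatternRegistry = DEFAULT_REGISTRY
) -> ScheduleCode:
    """Map a standardized warehouse schedule code (``QD``, ``QAM``, ``BID``,
    ``Q4H``, ``Q12H``, ...) directly; NULL/empty or unrecognized -> UNKNOWN."""
    code = (text or "").strip().upper()
    if code in ("", "NULL"):
        return UNKNOWN_SCHEDULE
    if code in registry.cdw_codes and code in PER_DAY:
        return ScheduleCode.daily(code)
    if code == "PRN":
        return ScheduleCode(code=Freq.PRN)
    return UNKNOWN_SCHEDULE


def extract_quantity(
    text: str, registry: PatternRegistry = DEFAULT_REGISTRY
) -> int:
    """Per-administration quantity from phrases like ``TAKE TWO TABLETS``.

    Only quantity words adjacent to a unit-of-administration word count;
    default is 1.
    """
    m = registry.quantity_pattern.search(text or "")
    if not m:
        return 1
    return registry.quantity_words[m.group(1).upper()]


def total_daily_dose(
    dose: Optional[DoseMatch], quantity: int, schedule: ScheduleCode
) -> Optional[TotalDailyDose]:
    """dose x quantity x administrations-per-day, in the dose's own unit.

    Undefined (None) whenever the dose is missing or the schedule has no
    per-day multiplier (PRN, as-directed, weekday lists, unknown).  Units
    are never interconverted: a silent MCG<->MG mix-up is a thousandfold
    clinical error, so the result always carries the dose unit unchanged.
    """
    if dose is None or schedule.per_day is None:
        return None
    return TotalDailyDose(value=dose.value * quantity * schedule.per_day, unit=dose.unit)


def _status_flags(
    dose: Optional[DoseMatch],
    schedule: ScheduleCode,
    tdd: Optional[TotalDailyDose],
    conflict: Optional[DoseMatch],
) -> frozenset[Flag]:
    flags = set()
    if dose is None:
        flags.add(Flag.NO_DOSE)
    if schedule.code in (Freq.UNKNOWN, Freq.AS_DIRECTED):
        flags.add(Flag.NO_SCHEDULE)
    if schedule.code is Freq.AS_DIRECTED:
        flags.add(Flag.AS_DIRECTED)
    if schedule.code is Freq.PRN:
        flags.add(Flag.PRN)
    if schedule.code is Freq.WEEKLY_DAYS:
        flags.add(Flag.WEEKLY)
    if conflict is not None:
        flags.add(Flag.DOSE_CONFLICT)
    if tdd is not None and conflict is None:
        flags.add(Flag.OK)
    return frozenset(flags)


def parse_entry(
    entry: RawMedicationEntry, registry: PatternRegistry = DEFAULT_REGISTRY
) -> ParsedMedication:
    """Parse one raw entry into a structured medication record.

    Doses are scanned in both fields; a sig-borne dose governs (the sig
    states the administered amount) and a disagreeing name-borne dose is
    surfaced as a conflict.  Warehouse-sourced entries carry standardized
    schedule codes and bypass the free-text frequency grammar.  Every
    input yields a result; failure is expressed only through status flags.
    """
    name_doses = extract_dose(entry.name_text, registry, SourceField.NAME)
    sig_doses = extract_dose(entry.sig_text, registry, SourceField.SIG)

    dose: Optional[DoseMatch] = None
    conflict: Optional[DoseMatch] = None
    extras: list[DoseMatch] = name_doses[1:] + sig_doses[1:]
    if sig_doses:
        dose = sig_doses[0]
        if name_doses and not name_doses[0].same_dose(dose):
            conflict = name_doses[0]
    elif name_doses:
        dose = name_doses[0]

    if entry.source is Source.CDW:
        schedule = extract_cdw_schedule(entry.sig_text, registry)
    else:
        schedule = extract_schedule(entry.sig_text, registry)
    quantity = extract_quantity(entry.sig_text, registry)
    tdd = total_daily_dose(dose, quantity, schedule)
    return ParsedMedication(
        raw=entry,
        dose=dose,
        schedule=schedule,
        quantity_multiplier=quantity,
        total_daily_dose=tdd,
        status=_status_flags(dose, schedule, tdd, conflict),
        conflict_dose=conflict,
        extra_doses=tuple(extras),
    )
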