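"""Extensible pattern registry for dose, schedule and quantity matching.

Production sig parsers are never finished: new free-text dialects keep
appearing in the prescription stream, so the unit alternatives, schedule
phrases, quantity words and standardized-code tables all live in a registry
that can be extended from a YAML/JSON config file rather than being baked
into the matching code.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: Administrations-per-day multiplier for each daily schedule code.
PER_DAY: Mapping[str, int] = {
    "QD": 1,
    "QAM": 1,
    "QHS": 1,
    "BID": 2,
    "TID": 3,
    "QID": 4,
    "Q4H": 6,
    "Q12H": 2,
}

#: Schedule phrase -> code mapping for the free-text frequency grammar.
DEFAULT_SCHEDULE_PHRASES: Mapping[str, str] = {
    r"bedtime": "QHS",
    r"once[\s]*daily": "QD",
    r"twice[\s]*daily": "BID",
    r"three[\s]*times[\s]*a[\s]*day": "TID",
    r"four[\s]*times[\s]*a[\s]*day": "QID",
}

DEFAULT_PRN_PHRASES: Sequence[str] = (r"as[\s]*needed", r"\bprn\b")
DEFAULT_AS_DIRECTED_PHRASES: Sequence[str] = (r"as[\s]*directed",)

DEFAULT_WEEKDAYS: Sequence[str] = (
    "MONDAY",
    "TUESDAY",
    "WEDNESDAY",
    "THURSDAY",
    "FRIDAY",
    "SATURDAY",
    "SUNDAY",
)

#: Quantity words mapped to integer multipliers (per-administration count).
DEFAULT_QUANTITY_WORDS: Mapping[str, int] = {
    "ONE": 1,
    "TWO": 2,
    "THREE": 3,
    "FOUR": 4,
    "1": 1,
    "2": 2,
    "3": 3,
    "4": 4,
}

DEFAULT_ADMIN_UNITS: Sequence[str] = ("TABLET", "CAPSULE", "TAB", "CAP")

#: Standardized schedule codes as delivered by the data warehouse dialect.
DEFAULT_CDW_CODES: Sequence[str] = tuple(PER_DAY)

DEFAULT_DOSE_UNITS: Sequence[str] = ("MG", "MCG", "MEQ")


def _unit_alternation(units: Sequence[str]) -> str:
    """Render unit names as the case-insensitive character-class alternation
    style of the dose grammar, e.g. MG -> ``[mM][gG]``."""
    alts = []
    for unit in units:
        alts.append("".join(f"[{c.lower()}{c.upper()}]" for c in unit))
    return "|".join(alts)


@dataclass(frozen=True)
class PatternRegistry:
    """Compiled matching tables for one parser configuration.

    The defaults reproduce the dose grammar
    ``[(]?[\\d]*[.]?[\\d]+[\\s]*([mM][gG]|[mM][cC][gG]|[mM][eE][qQ])[)]?``
    and the schedule grammar
    ``(bedtime|once[\\s]*daily|twice[\\s]*daily|three[\\s]*times[\\s]*a[\\s]*day|four[\\s]*times[\\s]*a[\\s]*day)``
    plus the extension phrases needed for as-needed, as-directed and
    weekday-list sigs.
    """

    dose_units: tuple[str, ...] = tuple(DEFAULT_DOSE_UNITS)
    schedule_phrases: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULE_PHRASES)
    )
    prn_phrases: tuple[str, ...] = tuple(DEFAULT_PRN_PHRASES)
    as_directed_phrases: tuple[str, ...] = tuple(DEFAULT_AS_DIRECTED_PHRASES)
    weekdays: tuple[str, ...] = tuple(DEFAULT_WEEKDAYS)
    quantity_words: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_QUANTITY_WORDS)
    )
    admin_units: tuple[str, ...] = tuple(DEFAULT_ADMIN_UNITS)
    cdw_codes: tuple[str, ...] = tuple(DEFAULT_CDW_CODES)

    @property
    def dose_pattern(self) -> re.Pattern:
        return re.compile(
            r"[(]?(?P<value>[\d]*[.]?[\d]+)[\s]*"
            rf"(?P<unit>{_unit_alternation(self.dose_units)})[)]?"
        )

    @property
    def schedule_pattern(self) -> re.Pattern:
        return re.compile("(" + "|".join(self.schedule_phrases) + ")", re.IGNORECASE)

    @property
    def prn_pattern(self) -> re.Pattern:
        return re.compile("|".join(self.prn_phrases), re.IGNORECASE)

    @property
    def as_directed_pattern(self) -> re.Pattern:
        return re.compile("|".join(self.as_directed_phrases), re.IGNORECASE)

    @property
    def weekday_pattern(self) -> re.Pattern:
        return re.compile(r"\b(" + "|".join(self.weekdays) + r")\b", re.IGNORECASE)

    @property
    def quantity_pattern(self) -> re.Pattern:
        words = "|".join(re.escape(w) for w in self.quantity_words)
        units = "|".join(f"{re.escape(u)}S?" for u in self.admin_units)
        return re.compile(rf"\b({words})[\s]+({units})\b", re.IGNORECASE)

    def schedule_code_for_phrase(self, phrase: str) -> str:
        """Map a matched free-text phrase back to its schedule code."""
        for pattern, code in self.schedule_phrases.items():
            if re.fullmatch(pattern, phrase, re.IGNORECASE):
                return code
        raise KeyError(phrase)


def load_registry(path: str | Path) -> PatternRegistry:
    """Load a registry from a YAML or JSON config file.

    Any omitted section falls back to the built-in defaults, so a config
    that only adds one new schedule phrase stays one line long.
    """
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    cfg = cfg or {}
    kwargs = {}
    if "dose_units" in cfg:
        kwargs["dose_units"] = tuple(str(u).upper() for u in cfg["dose_units"])
    for key in ("prn_phrases", "as_directed_phrases", "weekdays", "admin_units", "cdw_codes"):
        if key in cfg:
            kwargs[key] = tuple(cfg[key])
    if "schedule_phrases" in cfg:
        merged = dict(DEFAULT_SCHEDULE_PHRASES)
        merged.update(cfg["schedule_phrases"])
        kwargs["schedule_phrases"] = merged
    if "quantity_words" in cfg:
        merged_q = dict(DEFAULT_QUANTITY_WORDS)
        merged_q.update({str(k): int(v) for k, v in cfg["quantity_words"].items()})
        kwargs["quantity_words"] = merged_q
    return PatternRegistry(**kwargs)


DEFAULT_REGISTRY = PatternRegistry()
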