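"""Drug-name normalization, formulary matching and medication partitioning.

Drug Name fields arrive decorated: doses embedded mid-name, inline schedule
inserts between asterisks (``METOPROLOL*TWICE DAILY*TARTRATE TAB``), brand
synonyms in parentheses, ``[OTC]`` tags, ``<INDICATION>`` notes, and form
suffixes (TAB, CAP, SA, EC...).  Matching such a name against the formulary
— the table that carries the drug class for every listed drug — requires
stripping the decoration down to a base name first.

Classification then partitions each medication for polypharmacy screening:
non-drug supplies (lancets, syringes, spacers, diapers) are weeded out,
configured classes (vitamins, cough/cold remedies, OTC products, skin
creams, ophthalmic agents, short-course antibiotics) are excluded from the
count, and the remainder are the drugs of interest.
"""
from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .patterns import DEFAULT_REGISTRY, PatternRegistry
from .sig_parser import ParsedMedication, extract_dose

__all__ = [
    "FormularyEntry",
    "ClassificationPolicy",
    "ClassifiedMedication",
    "Decoration",
    "Tag",
    "MatchQuality",
    "Category",
    "normalize_name",
    "match_formulary",
    "classify",
    "load_formulary_csv",
    "load_policy",
]


class Tag(str, enum.Enum):
    OTC = "OTC"
    SYNONYM = "SYNONYM"
    INLINE_SCHEDULE = "INLINE_SCHEDULE"
    INDICATION = "INDICATION"
    NOTE = "NOTE"


class MatchQuality(str, enum.Enum):
    EXACT = "EXACT"
    NORMALIZED = "NORMALIZED"
    UNMATCHED = "UNMATCHED"


class Category(str, enum.Enum):
    SUPPLY = "SUPPLY"
    EXCLUDED = "EXCLUDED"
    OF_INTEREST = "OF_INTEREST"
    UNMATCHED = "UNMATCHED"


@dataclass(frozen=True)
class Decoration:
    """A stripped name decoration: its kind and, where applicable, its text."""

    kind: Tag
    value: Optional[str] = None


@dataclass(frozen=True)
class FormularyEntry:
    canonical_name: str
    drug_class: str
    is_supply: bool = False

    def __post_init__(self) -> None:
        if not self.is_supply and not self.drug_class:
            raise ValueError("drug_class required for non-supply entries")


@dataclass(frozen=True)
class ClassificationPolicy:
    """Pure configuration for the medication partition.

    ``excluded_classes`` are dropped from the drugs-of-interest count;
    ``antibiotic_classes`` are excluded only when a days-supply at or below
    ``antibiotic_days_supply_max`` marks the course as short-term (class
    membership alone cannot distinguish a 10-day course from chronic
    suppression therapy).  ``supply_keywords`` catch supplies that slipped
    into the medication list without a formulary supply flag.
    """

    excluded_classes: frozenset[str] = frozenset(
        {"VITAMINS", "COUGH_COLD", "OTC_REMEDY", "DERM_TOPICAL", "OPHTHALMIC"}
    )
    supply_keywords: frozenset[str] = frozenset(
        {"LANCET", "SYRINGE", "SPACER", "DIAPER", "TEST STRIP", "NEEDLE"}
    )
    antibiotic_classes: frozenset[str] = frozenset({"ANTIBIOTIC"})
    antibiotic_days_supply_max: int = 30


#: Dosage-form and release-modifier tokens stripped from drug names.
FORM_WORDS = frozenset(
    {
        "TAB", "TABS", "TABLET", "TABLETS",
        "CAP", "CAPS", "CAPSULE", "CAPSULES",
        "SA", "EC", "CR", "SR", "ER", "XR", "XL",
        "INJ", "SOLN", "SUSP",
    }
)

_ASTERISK = re.compile(r"\*([^*]*)\*")
_ANGLE = re.compile(r"<\s*([^<>]*?)\s*>")
_BRACKET = re.compile(r"\[([^\[\]]*)\]")
_PAREN = re.compile(r"\(([^()]*)\)")


def _blank_spans(text: str, spans: Iterable[tuple[int, int]]) -> str:
    chars = list(text)
    for lo, hi in spans:
        for i in range(lo, hi):
            chars[i] = " "
    return "".join(chars)


def normalize_name(
    name_text: str, registry: PatternRegistry = DEFAULT_REGISTRY
) -> tuple[str, frozenset[Decoration]]:
    """Strip a decorated Drug Name down to its base name.

    Returns the residual base name (uppercased, whitespace collapsed) and
    the set of decorations removed.  Dose substrings are located with the
    dose grammar before parenthesized synonyms are interpreted, so
    ``(81 MG)`` is recognized as a dose, not a brand synonym.  An entry
    that strips to nothing returns an empty base name.
    """
    s = name_text.upper()
    tags: set[Decoration] = set()

    def _collect(pattern: re.Pattern, kind: Tag, text: str) -> str:
        def repl(m: re.Match) -> str:
            value = m.group(1).strip()
            if kind is Tag.NOTE and value == "OTC":
                tags.add(Decoration(Tag.OTC))
            elif value:
                tags.add(Decoration(kind, value))
            return " "

        return pattern.sub(repl, text)

    s = _collect(_ASTERISK, Tag.INLINE_SCHEDULE, s)
    s = _collect(_ANGLE, Tag.INDICATION, s)
    s = _collect(_BRACKET, Tag.NOTE, s)
    s = _blank_spans(s, (d.span for d in extract_dose(s, registry)))
    s = _collect(_PAREN, Tag.SYNONYM, s)
    s = re.sub(r"[.,;]", " ", s)
    tokens = [t for t in s.split() if t not in FORM_WORDS]
    return " ".join(tokens), frozenset(tags)


def match_formulary(
    base_name: str, formulary: Sequence[FormularyEntry]
) -> tuple[Optional[FormularyEntry], MatchQuality]:
    """Match a normalized base name against the formulary.

    Exact canonical-name equality wins outright.  Failing that, a single
    candidate whose canonical name is a token-prefix of the base name (or
    vice versa) matches as NORMALIZED.  Ambiguity — several candidates,
    e.g. bare ``METOPROLOL`` against both tartrate and succinate salts —
    resolves to UNMATCHED: for a screening application, never guess among
    drugs.
    """
    if not base_name:
        return None, MatchQuality.UNMATCHED
    for entry in formulary:
        if entry.canonical_name == base_name:
            return entry, MatchQuality.EXACT
    base_tokens = base_name.split()
    candidates = []
    for entry in formulary:
        canon_tokens = entry.canonical_name.split()
        k = min(len(base_tokens), len(canon_tokens))
        if k and base_tokens[:k] == canon_tokens[:k]:
            candidates.append(entry)
    if len(candidates) == 1:
        return candidates[0], MatchQuality.NORMALIZED
    return None, MatchQuality.UNMATCHED


@dataclass(frozen=True)
class ClassifiedMedication:
    parsed: ParsedMedication
    base_name: str
    decorations: frozenset[Decoration]
    matched: Optional[FormularyEntry]
    match_quality: MatchQuality
    category: Category


def classify(
    parsed: ParsedMedication,
    formulary: Sequence[FormularyEntry],
    policy: ClassificationPolicy = ClassificationPolicy(),
    registry: PatternRegistry = DEFAULT_REGISTRY,
    days_supply: Optional[int] = None,
) -> ClassifiedMedication:
    """Partition one parsed medication into exactly one category.

    Order of precedence: SUPPLY (formulary supply flag or keyword hit),
    then EXCLUDED (excluded class, OTC tag, or short-course antibiotic),
    then OF_INTEREST for any other formulary match, else UNMATCHED.
    """
    base, tags = normalize_name(parsed.raw.name_text, registry)
    matched, quality = match_formulary(base, formulary)
    upper = parsed.raw.name_text.upper()
    if (matched is not None and matched.is_supply) or any(
        kw in upper for kw in policy.supply_keywords
    ):
        category = Category.SUPPLY
    elif Decoration(Tag.OTC) in tags or (
        matched is not None and matched.drug_class in policy.excluded_classes
    ):
        category = Category.EXCLUDED
    elif (
        matched is not None
        and matched.drug_class in policy.antibiotic_classes
        and days_supply is not None
        and days_supply <= policy.antibiotic_days_supply_max
    ):
        category = Category.EXCLUDED
    elif matched is not None:
        category = Category.OF_INTEREST
    else:
        category = Category.UNMATCHED
    return ClassifiedMedication(
        parsed=parsed,
        base_name=base,
        decorations=tags,
        matched=matched,
        match_quality=quality,
        category=category,
    )


def load_formulary_csv(path: str | Path) -> list[FormularyEntry]:
    """Read a formulary table (columns canonical_name, drug_class, is_supply)."""
    df = pd.read_csv(path)
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            FormularyEntry(
                canonical_name=str(row.canonical_name).upper(),
                drug_class=("" if pd.isna(row.drug_class) else str(row.drug_class)),
                is_supply=bool(row.is_supply),
            )
        )
    return entries


def load_policy(path: str | Path) -> ClassificationPolicy:
    """Read a classification policy from YAML/JSON config."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("excluded_classes", "supply_keywords", "antibiotic_classes"):
        if key in cfg:
            kwargs[key] = frozenset(str(v).upper() for v in cfg[key])
    if "antibiotic_days_supply_max" in cfg:
        kwargs["antibiotic_days_supply_max"] = int(cfg["antibiotic_days_supply_max"])
    return ClassificationPolicy(**kwargs)
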