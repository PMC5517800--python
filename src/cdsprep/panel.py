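"""Dependent-field consistency for a prognosis-calculator lab panel.

The FIB-4 liver-fibrosis index is derived from age, AST, ALT and platelet
count:

    FIB-4 = (age [years] x AST [U/L]) / (platelets [10^9/L] x sqrt(ALT [U/L]))

and bucketed into low / indeterminate / high ranges (default cut-points
1.45 and 3.25).  On a calculator screen these four quantities are
dependent fields: while the three component labs are present the range is
selected automatically and recomputed on every component edit; if the user
instead sets the range (or value) manually, the component values are not
used and so are removed.  This module implements that state machine as a
pure function over an immutable panel state, so every reachable state
satisfies the consistency invariants by construction.
"""
from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Optional, Union

__all__ = [
    "AST",
    "ALT",
    "PLATELETS",
    "LabOrigin",
    "LabResult",
    "Fib4Mode",
    "Fib4Range",
    "PanelState",
    "FieldEdit",
    "compute_fib4",
    "classify_fib4",
    "apply_field_edit",
    "lab_recency_view",
]

AST = "AST"
ALT = "ALT"
PLATELETS = "PLATELETS"
COMPONENTS = (AST, ALT, PLATELETS)

#: Pseudo-fields accepted by apply_field_edit for the derived quantity.
FIB4_FIELD = "FIB4"
FIB4_RANGE_FIELD = "FIB4_RANGE"


class LabOrigin(str, enum.Enum):
    EHR = "EHR"
    USER = "USER"


class Fib4Mode(str, enum.Enum):
    AUTO = "AUTO"
    MANUAL = "MANUAL"


class Fib4Range(str, enum.Enum):
    LOW = "LOW"
    INDETERMINATE = "INDETERMINATE"
    HIGH = "HIGH"


@dataclass(frozen=True)
class LabResult:
    """One lab value on the panel; EHR-origin results carry a result date,
    user-entered overrides are undated."""

    analyte: str
    value: float
    result_date: Optional[dt.date] = None
    origin: LabOrigin = LabOrigin.EHR

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("lab value must be positive")
        if self.origin is LabOrigin.EHR and self.result_date is None:
            raise ValueError("EHR-origin results require a result date")


def compute_fib4(age: float, ast: float, alt: float, platelets: float) -> float:
    """FIB-4 = (age x AST) / (platelets x sqrt(ALT)).

    Units: age in years, AST/ALT in U/L, platelets in 10^9/L.
    """
    if min(age, ast, alt, platelets) <= 0:
        raise ValueError("all FIB-4 inputs must be positive")
    return (age * ast) / (platelets * math.sqrt(alt))


def classify_fib4(
    value: float, thresholds: tuple[float, float] = (1.45, 3.25)
) -> Fib4Range:
    """LOW below the lower cut-point, HIGH above the upper, else
    INDETERMINATE (boundary values fall in the closed middle interval)."""
    t_low, t_high = thresholds
    if value < t_low:
        return Fib4Range.LOW
    if value > t_high:
        return Fib4Range.HIGH
    return Fib4Range.INDETERMINATE


@dataclass(frozen=True)
class PanelState:
    """Immutable panel state; construct with :meth:`create` so the derived
    FIB-4 value/range and the mode invariants are established."""

    age: int
    labs: Mapping[str, LabResult]
    fib4_mode: Fib4Mode = Fib4Mode.AUTO
    fib4_value: Optional[float] = None
    fib4_range: Optional[Fib4Range] = None
    thresholds: tuple[float, float] = (1.45, 3.25)
    passthrough_analytes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "labs", MappingProxyType(dict(self.labs)))
        if self.fib4_mode is Fib4Mode.MANUAL and any(
            c in self.labs for c in COMPONENTS
        ):
            raise ValueError("manual FIB-4 override must clear component labs")

    @classmethod
    def create(
        cls,
        age: int,
        labs: Mapping[str, LabResult] = {},
        thresholds: tuple[float, float] = (1.45, 3.25),
        passthrough_analytes: frozenset[str] = frozenset(),
    ) -> "PanelState":
        """Build an AUTO-mode state, deriving FIB-4 from whatever component
        labs are present (all three required for a value)."""
        state = cls(
            age=age,
            labs=labs,
            fib4_mode=Fib4Mode.AUTO,
            thresholds=thresholds,
            passthrough_analytes=frozenset(passthrough_analytes),
        )
        return _recompute(state)

    def lab_value(self, analyte: str) -> Optional[float]:
        lab = self.labs.get(analyte)
        return None if lab is None else lab.value


def _recompute(state: PanelState) -> PanelState:
    """Re-derive fib4_value/range for an AUTO-mode state."""
    values = [state.lab_value(c) for c in COMPONENTS]
    if all(v is not None for v in values):
        value = compute_fib4(state.age, *values)  # type: ignore[arg-type]
        rng = classify_fib4(value, state.thresholds)
    else:
        value = None
        rng = None
    return PanelState(
        age=state.age,
        labs=state.labs,
        fib4_mode=Fib4Mode.AUTO,
        fib4_value=value,
        fib4_range=rng,
        thresholds=state.thresholds,
        passthrough_analytes=state.passthrough_analytes,
    )


@dataclass(frozen=True)
class FieldEdit:
    """One user edit: a field name and a new value, or None to clear.

    ``field`` is a component analyte (AST/ALT/PLATELETS), a passthrough
    analyte declared on the state, ``FIB4`` (manual value) or
    ``FIB4_RANGE`` (manual range).
    """

    field: str
    value: Union[float, str, Fib4Range, None]


def apply_field_edit(state: PanelState, edit: FieldEdit) -> PanelState:
    """Apply one edit, returning a new state; the input is never modified.

    Component edits in AUTO mode recompute FIB-4; in MANUAL mode they
    first drop the override and return to AUTO (starting from empty
    components — the override removed them, and "removed" is not
    "parked").  Setting FIB4 or FIB4_RANGE manually switches to MANUAL and
    clears the three component labs.  Clearing a manual override returns
    to AUTO with FIB-4 unknown.  Unknown fields are rejected with
    ValueError and no partial update.
    """
    f = edit.field
    if f in COMPONENTS:
        labs = dict(state.labs)
        if edit.value is None:
            labs.pop(f, None)
        else:
            labs[f] = LabResult(
                analyte=f, value=float(edit.value), origin=LabOrigin.USER
            )
        # A MANUAL state holds no component labs, so `labs` here is just
        # the edited component; falling back to AUTO with the rest empty.
        return _recompute(
            PanelState(
                age=state.age,
                labs=labs,
                fib4_mode=Fib4Mode.AUTO,
                thresholds=state.thresholds,
                passthrough_analytes=state.passthrough_analytes,
            )
        )
    if f in (FIB4_FIELD, FIB4_RANGE_FIELD):
        labs = {k: v for k, v in state.labs.items() if k not in COMPONENTS}
        if edit.value is None:
            return _recompute(
                PanelState(
                    age=state.age,
                    labs=labs,
                    fib4_mode=Fib4Mode.AUTO,
                    thresholds=state.thresholds,
                    passthrough_analytes=state.passthrough_analytes,
                )
            )
        if f == FIB4_FIELD:
            value = float(edit.value)
            if value <= 0:
                raise ValueError("manual FIB-4 value must be positive")
            rng = classify_fib4(value, state.thresholds)
        else:
            value = None
            rng = Fib4Range(edit.value)
        return PanelState(
            age=state.age,
            labs=labs,
            fib4_mode=Fib4Mode.MANUAL,
            fib4_value=value,
            fib4_range=rng,
            thresholds=state.thresholds,
            passthrough_analytes=state.passthrough_analytes,
        )
    if f in state.passthrough_analytes or f in state.labs:
        labs = dict(state.labs)
        if edit.value is None:
            labs.pop(f, None)
        else:
            labs[f] = LabResult(
                analyte=f, value=float(edit.value), origin=LabOrigin.USER
            )
        return PanelState(
            age=state.age,
            labs=labs,
            fib4_mode=state.fib4_mode,
            fib4_value=state.fib4_value,
            fib4_range=state.fib4_range,
            thresholds=state.thresholds,
            passthrough_analytes=state.passthrough_analytes,
        )
    raise ValueError(f"unknown panel field: {f!r}")


def lab_recency_view(state: PanelState) -> list[tuple[str, float, Optional[dt.date]]]:
    """All present labs with their result dates, sorted by analyte name;
    user-entered values appear undated (date None)."""
    return [
        (lab.analyte, lab.value, lab.result_date if lab.origin is LabOrigin.EHR else None)
        for lab in sorted(state.labs.values(), key=lambda l: l.analyte)
    ]
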