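"""Dose/schedule extraction and total-daily-dose computation."""
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdsprep import (
    DoseMatch,
    Flag,
    Freq,
    RawMedicationEntry,
    ScheduleCode,
    Source,
    SourceField,
    Unit,
    extract_dose,
    extract_quantity,
    extract_schedule,
    parse_entry,
    total_daily_dose,
)


@pytest.mark.parametrize(
    "text, expected",
    [
        ("GABAPENTIN 300 MG, CAP", [(300.0, Unit.MG)]),
        ("32.5 MG", [(32.5, Unit.MG)]),
        ("18MCG", [(18.0, Unit.MCG)]),
        ("(1.5 meq)", [(1.5, Unit.MEQ)]),
        ("PROPRANOLOL TAB", []),
        ("ASPIRIN, ENTERIC COATED(81 MG) TAB, EC", [(81.0, Unit.MG)]),
        ("", []),
        ("10MG THEN 20 MG", [(10.0, Unit.MG), (20.0, Unit.MG)]),
    ],
)
def test_extract_dose_examples(text, expected):
    assert [(m.value, m.unit) for m in extract_dose(text)] == expected


def test_dose_match_span_reparses_to_same_value():
    text = "ASPIRIN, ENTERIC COATED(81 MG) TAB, EC"
    (m,) = extract_dose(text)
    lo, hi = m.span
    (again,) = extract_dose(text[lo:hi])
    assert (again.value, again.unit) == (m.value, m.unit)


@pytest.mark.parametrize(
    "text, code, per_day, per_week",
    [
        ("TAKE ONE CAPSULE BY MOUTH THREE TIMES A DAY", Freq.TID, 3, None),
        ("AT BEDTIME", Freq.QHS, 1, None),
        ("ONCE DAILY", Freq.QD, 1, None),
        ("TWICE DAILY", Freq.BID, 2, None),
        ("FOUR TIMES A DAY", Freq.QID, 4, None),
        ("once  daily", Freq.QD, 1, None),
        (
            "TAKE AS DIRECTED BY MOUTH AS INSTRUCTED BY VA ANTICOAGULATION "
            "CLINIC (TO PREVENT BLOOD CLOTS)",
            Freq.AS_DIRECTED,
            None,
            None,
        ),
        ("20MG MOUTH MONDAY, WEDNESDAY AND FRIDAY", Freq.WEEKLY_DAYS, None, 3),
        ("MONDAY AND MONDAY", Freq.WEEKLY_DAYS, None, 1),
        ("AS NEEDED FOR PAIN", Freq.PRN, None, None),
        ("10MG MOUTH DAILY(1000)", Freq.UNKNOWN, None, None),
        ("", Freq.UNKNOWN, None, None),
    ],
)
def test_extract_schedule(text, code, per_day, per_week):
    s = extract_schedule(text)
    assert (s.code, s.per_day, s.per_week) == (code, per_day, per_week)


def test_prn_cap_outranks_frequency_phrase():
    # a max-use cap does not establish a standing schedule
    s = extract_schedule("AS NEEDED, AT MOST TWICE DAILY")
    assert s.code is Freq.PRN and s.per_day is None


@pytest.mark.parametrize(
    "text, qty",
    [
        ("TAKE ONE CAPSULE BY MOUTH THREE TIMES A DAY", 1),
        ("TAKE TWO TABLETS BY MOUTH ONCE DAILY", 2),
        ("TAKE 3 TABS DAILY", 3),
        ("162MG MOUTH", 1),
        ("", 1),
        ("ONE DAY AT A TIME", 1),  # quantity word not adjacent to a dose form
    ],
)
def test_extract_quantity(text, qty):
    assert extract_quantity(text) == qty


@pytest.mark.parametrize(
    "dose, qty, schedule, expected",
    [
        ((300.0, Unit.MG), 1, ScheduleCode.daily(Freq.TID), (900.0, Unit.MG)),
        ((50.0, Unit.MG), 1, ScheduleCode(code=Freq.PRN), None),
        ((10.0, Unit.MG), 2, ScheduleCode.daily(Freq.Q12H), (40.0, Unit.MG)),
        ((18.0, Unit.MCG), 1, ScheduleCode.daily(Freq.QD), (18.0, Unit.MCG)),
    ],
)
def test_total_daily_dose(dose, qty, schedule, expected):
    value, unit = dose
    tdd = total_daily_dose(DoseMatch(value=value, unit=unit), qty, schedule)
    if expected is None:
        assert tdd is None
    else:
        assert (tdd.value, tdd.unit) == expected


@given(
    value=st.floats(min_value=0.01, max_value=1e4),
    qty=st.integers(1, 4),
    code=st.sampled_from([Freq.QD, Freq.QAM, Freq.QHS, Freq.BID, Freq.TID, Freq.QID, Freq.Q4H, Freq.Q12H]),
    unit=st.sampled_from(list(Unit)),
)
def test_total_daily_dose_scales_with_dose(value, qty, code, unit):
    schedule = ScheduleCode.daily(code)
    one = total_daily_dose(DoseMatch(value=value, unit=unit), qty, schedule)
    two = total_daily_dose(DoseMatch(value=2 * value, unit=unit), qty, schedule)
    assert two.value == pytest.approx(2 * one.value)
    assert one.unit is unit and two.unit is unit


WORKED_EXAMPLE = RawMedicationEntry(
    name_text="GABAPENTIN 300 MG, CAP",
    sig_text="TAKE ONE CAPSULE BY MOUTH THREE TIMES A DAY",
)


def test_worked_example_total_daily_dose():
    p = parse_entry(WORKED_EXAMPLE)
    assert p.dose.value == 300.0 and p.dose.unit is Unit.MG
    assert p.dose.source_field is SourceField.NAME
    assert p.schedule.code is Freq.TID and p.schedule.per_day == 3
    assert p.quantity_multiplier == 1
    assert (p.total_daily_dose.value, p.total_daily_dose.unit) == (900.0, Unit.MG)
    assert p.status == frozenset({Flag.OK})


ANOMALOUS_PAIRS = [
    (
        "ASPIRIN, ENTERIC COATED(81 MG) TAB, EC",
        "162MG MOUTH",
        dict(
            dose=(162.0, Unit.MG, SourceField.SIG),
            code=Freq.UNKNOWN,
            flags={Flag.DOSE_CONFLICT, Flag.NO_SCHEDULE},
            conflict=(81.0, Unit.MG),
        ),
    ),
    (
        "WARFARIN NA 5MG TAB",
        "TAKE AS DIRECTED BY MOUTH AS INSTRUCTED BY VA ANTICOAGULATION "
        "CLINIC (TO PREVENT BLOOD CLOTS)",
        dict(
            dose=(5.0, Unit.MG, SourceField.NAME),
            code=Freq.AS_DIRECTED,
            flags={Flag.NO_SCHEDULE, Flag.AS_DIRECTED},
            conflict=None,
        ),
    ),
    (
        "LISINOPRIL TAB",
        "10MG MOUTH DAILY(1000)",
        dict(
            dose=(10.0, Unit.MG, SourceField.SIG),
            code=Freq.UNKNOWN,
            flags={Flag.NO_SCHEDULE},
            conflict=None,
        ),
    ),
    (
        "FUROSEMIDE TAB",
        "20MG MOUTH MONDAY, WEDNESDAY AND FRIDAY",
        dict(
            dose=(20.0, Unit.MG, SourceField.SIG),
            code=Freq.WEEKLY_DAYS,
            flags={Flag.WEEKLY},
            conflict=None,
            per_week=3,
        ),
    ),
    (
        "SUMATRIPTAN SUCCINATE 50MG TAB",
        "TAKE ONE TABLET BY MOUTH AS NEEDED AT ONSET OF HEADACHE. CAN TAKE "
        "AN ADDITIONAL TABLET 1 HOUR LATER IF NEEDED. DO NOT USE MORE THAN "
        "TWICE PER WEEK",
        dict(
            dose=(50.0, Unit.MG, SourceField.NAME),
            code=Freq.PRN,
            flags={Flag.PRN},
            conflict=None,
        ),
    ),
]


@pytest.mark.parametrize("name,sig,expected", ANOMALOUS_PAIRS, ids=lambda v: str(v)[:12])
def test_anomalous_entries(name, sig, expected):
    """The representative hard cases: conflicts, as-directed, weekday
    lists, as-needed caps — all parse to flags, never to exceptions."""
    entry = RawMedicationEntry(name_text=name, sig_text=sig)
    p = parse_entry(entry)
    assert (p.dose.value, p.dose.unit, p.dose.source_field) == expected["dose"]
    assert p.schedule.code is expected["code"]
    if "per_week" in expected:
        assert p.schedule.per_week == expected["per_week"]
    assert p.status == frozenset(expected["flags"])
    if expected["conflict"] is None:
        assert p.conflict_dose is None
    else:
        assert (p.conflict_dose.value, p.conflict_dose.unit) == expected["conflict"]
    assert p.total_daily_dose is None
    # fallback contract: the raw entry is retained byte-for-byte
    assert p.raw is entry
    assert (p.raw.name_text, p.raw.sig_text) == (name, sig)


def test_agreeing_name_and_sig_doses_do_not_conflict():
    p = parse_entry(RawMedicationEntry("WARFARIN NA 5MG TAB", "5MG MOUTH ONCE DAILY"))
    assert p.conflict_dose is None
    assert p.dose.source_field is SourceField.SIG
    assert p.status == frozenset({Flag.OK})


def test_multiple_doses_in_one_field_first_wins_rest_diagnosed():
    p = parse_entry(RawMedicationEntry("DRUG 10MG / 20MG TAB", ""))
    assert p.dose.value == 10.0
    assert [m.value for m in p.extra_doses] == [20.0]


def test_no_dose_no_schedule_flags():
    p = parse_entry(RawMedicationEntry("PROPRANOLOL TAB", "USE PER PROTOCOL"))
    assert p.dose is None and p.total_daily_dose is None
    assert p.status == frozenset({Flag.NO_DOSE, Flag.NO_SCHEDULE})


@pytest.mark.parametrize(
    "sig, code, per_day",
    [
        ("QD", Freq.QD, 1),
        ("QAM", Freq.QAM, 1),
        ("BID", Freq.BID, 2),
        ("Q4H", Freq.Q4H, 6),
        ("Q12H", Freq.Q12H, 2),
        ("NULL", Freq.UNKNOWN, None),
        ("", Freq.UNKNOWN, None),
    ],
)
def test_cdw_standardized_schedule_dialect(sig, code, per_day):
    entry = RawMedicationEntry("GABAPENTIN 300 MG", sig, source=Source.CDW)
    p = parse_entry(entry)
    assert p.schedule.code is code and p.schedule.per_day == per_day


def test_parse_entry_is_deterministic_and_pure():
    a = parse_entry(WORKED_EXAMPLE)
    b = parse_entry(WORKED_EXAMPLE)
    assert a == b


def test_schedule_per_day_mapping_is_fixed():
    expected = {"QD": 1, "QAM": 1, "QHS": 1, "BID": 2, "TID": 3, "QID": 4, "Q4H": 6, "Q12H": 2}
    for code, per_day in expected.items():
        assert ScheduleCode.daily(code).per_day == per_day
    with pytest.raises(ValueError):
        ScheduleCode(code=Freq.TID, per_day=2)
    with pytest.raises(ValueError):
        ScheduleCode(code=Freq.PRN, per_day=1)
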