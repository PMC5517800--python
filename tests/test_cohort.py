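"""Comorbidity flags, drugs-of-interest counts, and the screening grid."""
import datetime as dt

import pytest

from cdsprep import (
    CodePolicy,
    PatientSnapshot,
    RawMedicationEntry,
    build_screening_grid,
    comorbidity_flags,
    count_drugs_of_interest,
    list_patients_in_cells,
)
from cdsprep.cohort import DEFAULT_AGE_BANDS, OTHER_BAND, _drug_count_label
from cdsprep.fixtures import GeneratorSpec, generate_patient_cohort

WINDOW = (dt.date(2015, 11, 11), dt.date(2015, 11, 25))


@pytest.mark.parametrize(
    "codes, expected",
    [
        ({"401.1"}, (True, False)),
        ({"250.00", "401.9"}, (True, True)),
        ({"405.99"}, (True, False)),
        ({"250.60"}, (False, True)),
        ({"272.4", "530.81"}, (False, False)),
        (set(), (False, False)),
        ({"V58.69", "E849"}, (False, False)),  # supplementary codes never match
        ({"4011"}, (False, False)),  # category is the part before the dot
    ],
)
def test_comorbidity_flags(codes, expected):
    assert comorbidity_flags(codes) == expected


def test_malformed_codes_skipped_with_warning(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="cdsprep.cohort"):
        assert comorbidity_flags({"garbage!", "401.9"}) == (True, False)
    assert any("malformed" in r.message for r in caplog.records)


def test_custom_code_policy():
    policy = CodePolicy(hypertension_prefixes=frozenset({999}))
    assert comorbidity_flags({"401.9"}, policy) == (False, False)
    assert comorbidity_flags({"999.1"}, policy) == (True, False)


def _med(name, sig=""):
    return RawMedicationEntry(name_text=name, sig_text=sig)


def test_count_drugs_of_interest_excludes_and_dedupes(formulary, policy):
    meds = [
        _med("GABAPENTIN 300 MG, CAP"),          # of interest
        _med("GABAPENTIN 100 MG, CAP"),          # same base name: counted once
        _med("LISINOPRIL TAB", "10MG MOUTH"),    # of interest
        _med("MULTIVITAMIN TAB"),                # excluded class
        _med("LANCETS BLOOD GLUCOSE"),           # supply
        _med("XYZZY ELIXIR"),                    # unmatched
    ]
    assert count_drugs_of_interest(meds, formulary, policy) == 2
    assert count_drugs_of_interest([], formulary, policy) == 0


def _brute_force_grid_counts(cohort, window, formulary, policy, age_bands, max_count=10):
    """Independent per-patient tally: no shared code with the grid builder
    beyond the classifiers it is specified to agree with."""
    start, end = window
    best = {}
    for p in cohort:
        if start <= p.appointment_date < end:
            if p.patient_id not in best or p.appointment_date < best[p.patient_id].appointment_date:
                best[p.patient_id] = p
    tallies = {}
    for p in best.values():
        band = OTHER_BAND
        for b in age_bands:
            if b.contains(p.age):
                band = b.label
                break
        n = count_drugs_of_interest(p.medications, formulary, policy)
        label = f"{max_count}+" if n >= max_count else str(n)
        htn, dm = comorbidity_flags(p.icd9_codes)
        key = (band, label)
        t = tallies.setdefault(key, [0, 0, 0, 0])
        t[0] += 1
        if htn and not dm:
            t[1] += 1
        elif dm and not htn:
            t[2] += 1
        elif htn and dm:
            t[3] += 1
    return tallies


def test_grid_matches_brute_force_oracle(formulary, policy):
    cohort = [p for p, _ in generate_patient_cohort(GeneratorSpec(seed=7, n=200), formulary)]
    grid = build_screening_grid(cohort, WINDOW, formulary, policy=policy)
    oracle = _brute_force_grid_counts(cohort, WINDOW, formulary, policy, DEFAULT_AGE_BANDS)
    for key, cell in grid.cells.items():
        expected = oracle.get(key, [0, 0, 0, 0])
        assert [cell.n_total, cell.n_htn_only, cell.n_dm_only, cell.n_both] == expected


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_grid_partition_invariants(seed, formulary, policy):
    cohort = [p for p, _ in generate_patient_cohort(GeneratorSpec(seed=seed, n=120), formulary)]
    grid = build_screening_grid(cohort, WINDOW, formulary, policy=policy)
    in_window = {
        p.patient_id for p in cohort if WINDOW[0] <= p.appointment_date < WINDOW[1]
    }
    assert grid.n_patients == len(in_window)
    seen = []
    for cell in grid.cells.values():
        assert cell.n_htn_only + cell.n_dm_only + cell.n_both <= cell.n_total
        assert cell.n_total == len(cell.patients)
        seen.extend(p.patient_id for p in cell.patients)
    assert sorted(seen) == sorted(in_window)  # every patient in exactly one cell


def test_grid_invariant_to_input_ordering(formulary, policy):
    cohort = [p for p, _ in generate_patient_cohort(GeneratorSpec(seed=9, n=80), formulary)]
    a = build_screening_grid(cohort, WINDOW, formulary, policy=policy)
    b = build_screening_grid(list(reversed(cohort)), WINDOW, formulary, policy=policy)
    assert a == b


def test_single_patient_trace(formulary, policy):
    patient = PatientSnapshot(
        patient_id="P1",
        age=78,
        icd9_codes=frozenset({"401.9", "250.00"}),
        appointment_date=dt.date(2015, 11, 12),
        medications=tuple(
            _med(f"{name} 10 MG, TAB", "TAKE ONE TABLET BY MOUTH ONCE DAILY")
            for name in ["GABAPENTIN", "LISINOPRIL", "AMLODIPINE", "FUROSEMIDE",
                         "ATORVASTATIN", "METFORMIN"]
        ),
    )
    grid = build_screening_grid([patient], WINDOW, formulary, policy=policy)
    cell = grid.cells[("75-84", "6")]
    assert (cell.n_total, cell.n_both, cell.n_htn_only, cell.n_dm_only) == (1, 1, 0, 0)
    assert grid.n_patients == 1


def test_empty_cohort_all_cells_zero(formulary, policy):
    grid = build_screening_grid([], WINDOW, formulary, policy=policy)
    assert grid.n_patients == 0
    assert all(c.n_total == 0 for c in grid.cells.values())


def test_age_outside_bands_goes_to_other_band(formulary, policy):
    p = PatientSnapshot(
        patient_id="P2", age=40, icd9_codes=frozenset(),
        appointment_date=dt.date(2015, 11, 12),
    )
    grid = build_screening_grid([p], WINDOW, formulary, policy=policy)
    assert grid.cells[(OTHER_BAND, "0")].n_total == 1


def test_half_open_window_and_earliest_appointment(formulary, policy):
    mk = lambda pid, day: PatientSnapshot(
        patient_id=pid, age=70, icd9_codes=frozenset(),
        appointment_date=dt.date(2015, 11, day),
    )
    cohort = [mk("A", 25), mk("B", 11), mk("B", 20)]  # A on end date; B twice
    grid = build_screening_grid(cohort, WINDOW, formulary, policy=policy)
    assert grid.n_patients == 1
    (patient,) = grid.cells[("65-74", "0")].patients
    assert patient.appointment_date == dt.date(2015, 11, 11)


def test_drug_count_overflow_bucket(formulary, policy):
    assert _drug_count_label(10, 10) == "10+"
    assert _drug_count_label(14, 10) == "10+"
    assert _drug_count_label(9, 10) == "9"


def test_list_patients_in_cells(formulary, policy):
    cohort = [p for p, _ in generate_patient_cohort(GeneratorSpec(seed=13, n=60), formulary)]
    grid = build_screening_grid(cohort, WINDOW, formulary, policy=policy)
    everyone = list_patients_in_cells(grid, list(grid.cells))
    assert len(everyone) == grid.n_patients
    assert everyone == sorted(everyone, key=lambda p: (p.appointment_date, p.patient_id))
    nonempty = [k for k, c in grid.cells.items() if c.n_total][:2]
    sizes = [grid.cells[k].n_total for k in nonempty]
    assert len(list_patients_in_cells(grid, nonempty)) == sum(sizes)
    assert list_patients_in_cells(grid, []) == []
    with pytest.raises(KeyError):
        list_patients_in_cells(grid, [("no-band", "0")])
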