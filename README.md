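# cdsprep

A preprocessing toolkit for turning messy electronic-health-record
medication and diagnosis extracts into clinical-decision-support inputs.
It is aimed at informatics teams who receive EHR medication lists as
free-text *Drug Name* / *Sig* field pairs (the VistA-style dialect, where
the dose may be embedded in either field and the schedule is prose) and
need structured doses, drug classes, polypharmacy counts and consistent
lab-panel state on the other side.

## What it does

**Sig parsing and total daily dose** (`cdsprep.sig_parser`). Doses are
located with the grammar

```
[(]? [\d]*[.]?[\d]+ [\s]* (MG | MCG | MEQ) [)]?      # "32.5 MG", "18MCG", "(1.5 meq)"
```

and schedules with a frequency-phrase grammar (`bedtime`, `once daily`,
`twice daily`, `three times a day`, `four times a day`) mapped onto
prescription abbreviations with fixed administrations-per-day
multipliers (QD = QAM = QHS = 1, BID = Q12H = 2, TID = 3, QID = 4,
Q4H = 6), plus as-needed, as-directed and weekday-list handling. The
total daily dose is

```
TDD = dose × quantity per administration × administrations per day
```

computed only when a dose and a daily schedule are both recoverable;
units are never interconverted. A dose stated in the sig outranks one
embedded in the name, and a disagreement is flagged as a conflict rather
than silently resolved. Unparseable entries come back with status flags
and the raw text retained verbatim, so a display can always fall back to
the unprocessed fields. The pattern registry is extensible from a YAML
config.

**Formulary classification** (`cdsprep.formulary`). Decorated names
(`METOPROLOL*TWICE DAILY*TARTRATE TAB`, `NIACIN(SLO-NIACIN) [OTC] TAB, SA`)
are normalized to base names, matched against a formulary table carrying
drug classes, and partitioned into non-drug supplies, excluded classes
(vitamins, cough/cold, OTC, skin creams, ophthalmics, short-course
antibiotics) and drugs of interest for polypharmacy counting.

**Cohort screening** (`cdsprep.cohort`). Patients with appointments in a
half-open date window are bucketed into an age-band × drug-count grid,
each cell annotated with only-hypertension / only-diabetes / both counts
from an ICD-9 prefix scan (401–405 and 250 by default), with per-cell
patient lists.

**Staging preprocessing** (`cdsprep.staging`). Diagnosis histories are
reduced to one boolean per configured disease and medication histories to
previously-but-not-currently prescribed panel drugs with their most
recent prescription date — the minimal facts a real-time lookup store
needs.

**Panel consistency** (`cdsprep.panel`). The FIB-4 liver-fibrosis index,

```
FIB-4 = (age × AST) / (platelets × √ALT)
```

is auto-derived while AST, ALT and platelet count are present and
re-derived on every component edit; a manual range override removes the
three component values, and the state machine guarantees the two modes
never mix. Lab recency (result dates) is always inspectable.

**Synthetic fixtures** (`cdsprep.fixtures`). Seeded generators emit
ground-truthed medication entries in the messy dialect and whole patient
cohorts, so everything above is testable without any real patient data.

## Worked example

```python
from cdsprep import RawMedicationEntry, parse_entry

entry = RawMedicationEntry(
    name_text="GABAPENTIN 300 MG, CAP",
    sig_text="TAKE ONE CAPSULE BY MOUTH THREE TIMES A DAY",
)
p = parse_entry(entry)
print(f"dose={p.dose.value:g} {p.dose.unit.value}  "
      f"schedule={p.schedule.code.value} (x{p.schedule.per_day}/day)  "
      f"total daily dose={p.total_daily_dose.value:g} {p.total_daily_dose.unit.value}")
```

prints

```
dose=300 MG  schedule=TID (x3/day)  total daily dose=900 MG
```

— 300 MG is found in the name field, "THREE TIMES A DAY" maps to TID
(3 administrations/day), and 300 × 1 × 3 = 900 MG/day. The same pipeline
from the shell, plus a screening grid over a synthetic cohort:

```
$ cdsprep fib4 --age 50 --ast 40 --alt 25 --plt 200
FIB-4 = 2.00 (INDETERMINATE)

$ cdsprep make-fixtures --seed 5 --n 40 --cohort --out fx
$ cdsprep screen-cohort --cohort fx/cohort.jsonl --window 2015-11-11:2015-11-25 --out fx/grid
40 in-window patients -> fx/grid
```

`fx/grid/grid.tsv` then holds the age × drug-count matrix; e.g. the
`75-84` row's column `5` reading `3 (H3 D0 B0)` means three patients aged
75–84 taking 5 drugs of interest, all three with hypertension only.

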