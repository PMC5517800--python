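# Methods

This note documents the models and procedures cdsprep implements, the
design choices made where the problem was genuinely open, and what the
synthetic fixtures do and do not establish about real EHR data.

## The parsing model

Each medication arrives as two free-text fields: a Drug Name and a Sig
(administration instruction). The dedicated dose field that nominally
exists in the source system is treated as unreliable and is retained but
not scanned: in practice the dose is embedded in the name or the sig.

**Dose grammar.** Doses are located by scanning for an optional opening
parenthesis, a decimal number, optional whitespace, one of the units MG /
MCG / MEQ in any letter case, and an optional closing parenthesis.
Matching is non-overlapping and left-to-right. Two deliberate choices:

- *Zero is not a dose.* The grammar as written accepts "0 MG"; the
  extractor matches it, consumes its span (so scanning positions are
  unaffected), and then drops it, because a zero-valued dose can only be
  noise and would poison downstream arithmetic.
- *No unit conversion, ever.* MCG is not converted to MG. A silent
  thousandfold error is the dominant clinical risk in dose handling, so
  totals always carry the unit of the matched dose and comparisons are
  strict on (value, unit) pairs.

**Dose precedence.** When both fields yield doses, the sig wins: the sig
states what the patient administers, while the name states what tablet
strength is dispensed (an 81 MG tablet taken as 162 MG means two
tablets). The losing match is retained as `conflict_dose` and the entry
is flagged `DOSE_CONFLICT` rather than resolved silently — the conflict
itself is clinically informative. Within one field, the first (leftmost)
match governs and later matches are kept in a diagnostics list.

**Schedule grammar.** Free-text frequency phrases map to prescription
abbreviations with fixed multipliers: bedtime→QHS, once daily→QD, twice
daily→BID, three times a day→TID, four times a day→QID, with
administrations/day QD=QAM=QHS=1, BID=Q12H=2, TID=3, QID=4, Q4H=6. Three
extension cue classes cover the recurrent non-daily dialects: as-needed
phrases (PRN), as-directed phrases, and weekday lists (mapped to a
per-week count of distinct day names). Cue classes are tested in the
fixed precedence order PRN > as-directed > frequency phrase > weekday
list > unknown. PRN outranks a frequency phrase deliberately: a
maximum-use cap ("DO NOT USE MORE THAN TWICE PER WEEK") names a
frequency without establishing a standing schedule. Bare "DAILY" without
a count word is *not* in the default grammar and maps to unknown; sites
that want it can add `daily: QD` to a pattern config, since the registry
(units, phrases, quantity words, weekday names, standardized codes) is
configuration, reflecting the reality that such pattern logic needs
regular extension as new dialects appear.

Warehouse-sourced entries (`source=CDW`) carry standardized schedule
codes rather than prose, and are mapped directly through the code table;
an empty or literal `NULL` schedule maps to unknown.

**Quantity.** "TAKE TWO TABLETS" multiplies the per-administration dose
by 2. Only the words ONE–FOUR (or digits 1–4) directly adjacent to a
unit-of-administration word (tablet/capsule/tab/cap) are honored;
anything else defaults to 1. Dose ranges ("1-2 TABLETS") are not
quantified.

**Total daily dose** = dose × quantity × administrations/day, defined
only when both a dose and a daily schedule exist. Weekly schedules
intentionally yield *no* total daily dose: averaging 3×/week into a
fractional daily value would misstate what the patient takes on any
given day; the per-administration dose and per-week count are reported
instead.

**Status flags.** `NO_DOSE` when no dose was found; `NO_SCHEDULE` when
no daily schedule is determinable and no recognized non-daily pattern
explains why (i.e. schedule is unknown or as-directed); `PRN`, `WEEKLY`,
`AS_DIRECTED` name the recognized non-daily outcomes; `DOSE_CONFLICT` as
above; `OK` exactly when a total daily dose exists and no conflict does.
Parsing never raises: every entry yields a result, and the raw entry is
retained byte-for-byte so a fallback display of the unprocessed fields
is always possible.

## Name normalization and classification

Normalization uppercases, then strips asterisk-delimited inline inserts
(recorded as `INLINE_SCHEDULE` tags), angle-bracketed indication notes,
square-bracketed tags (`[OTC]` becomes the OTC tag), dose substrings
(located with the dose grammar *before* parentheses are interpreted, so
`(81 MG)` is a dose, not a synonym), parenthesized brand synonyms, and
dosage-form/release tokens (TAB, CAP, SA, EC, SR, XR, ...), finally
collapsing whitespace. The operation is idempotent. An entry that strips
to nothing yields an empty base name and classifies as unmatched.

Formulary matching tries exact canonical-name equality, then a unique
token-prefix relation in either direction ("LISINOPRIL COATED" matches
the canonical "LISINOPRIL"); ambiguity — bare "METOPROLOL" against both
salts — is resolved to *unmatched*, never to a guess, because in a
screening application a false drug identity is worse than a missing one.

Classification partitions every medication into exactly one of: SUPPLY
(formulary supply flag or a keyword hit for lancets, syringes, spacers,
diapers and the like, which the source system stores as "medications"),
EXCLUDED (configured drug classes — vitamins, cough/cold, OTC remedies,
topical skin preparations, ophthalmics — or an OTC tag on the name),
OF_INTEREST (any other formulary match) or UNMATCHED. Short-term
antibiotics cannot be identified from class alone, so antibiotic classes
are excluded only when a days-supply value ≤ 30 (configurable) is
supplied with the entry; without that evidence the drug is retained.
The shipped class codes are descriptive defaults and pure configuration —
real deployments substitute their formulary's own class vocabulary.

## Cohort screening

The screening grid filters to appointments in a half-open `[start, end)`
window (so weekly runs tile without double counting), counts each
patient once at their earliest in-window appointment, and assigns each
to one (age band, drug-count) cell. Default bands are 65–74, 75–84, 85+;
ages outside every band land in an explicit "other" band rather than
being dropped. Drug counts are distinct OF_INTEREST base names
(duplicate strengths of one drug count once); counts at or above 10
share an overflow bucket. Condition annotation is mutually exclusive
per patient: only-hypertension, only-diabetes, both; patients with
neither remain in the cell total without a dedicated tally. Hypertension
is ICD-9 categories 401–405, diabetes 250, matched on the integer
category before the dot; V/E supplementary codes never match and
malformed code strings are skipped with a logged warning. Grid output
ordering is deterministic and invariant to input order.

## Staging

The staging reductions implement a minimum-necessary contract: diagnosis
histories become one boolean per configured disease (no codes retained),
and medication histories become (base name, most recent prescription
date) pairs for panel drugs *not* in the current medication set.
"Currently prescribed" is defined by the supplied current-name set, not
by date arithmetic on fills, since no fill-to-active rule is part of the
model. The store is an embedded in-memory table with JSON-lines
persistence; staging under a refresh tag fully replaces a patient's
record, and querying an unknown patient returns an explicit not-found
(None) distinguishable from a staged all-false record. The disease panel
is configuration; the test suite uses a five-disease neuropathic-pain
panel as its example.

## Panel state machine

FIB-4 = (age × AST) / (platelets × √ALT), age in years, AST/ALT in U/L,
platelets in 10⁹/L. Range cut-points default to the standard 1.45 / 3.25
and are configurable; boundary values classify as indeterminate (closed
middle interval). The state is immutable and every transition returns a
fresh state, so the two invariants — manual mode never coexists with a
stored component value, and auto mode always carries exactly the value
the formula gives (or none, if a component is missing) — are enforced at
construction and hold in every reachable state. Re-entering auto mode
after a manual override starts from empty components: the override
*removed* the values, and restoring them would resurrect data the user
explicitly discarded. Non-component analytes pass through untouched;
user-entered values are undated in the recency view, EHR values carry
their result dates. Behavioural fields (tobacco, alcohol, adherence,
hepatitis-C status) are outside the model: they are clinician-entered by
design and nothing is inferred from the record. A scoring hook for a
full prognosis index can be layered on top but is deliberately not
implemented here.

## Synthetic fixtures

The generator emulates the documented free-text dialects as seven entry
archetypes — clean name-borne dose, sig-borne dose, decorated name,
as-directed, as-needed, weekday list, name/sig dose conflict — drawn
with configurable weights (defaults: 0.40 / 0.20 / 0.15 / 0.05 / 0.05 /
0.05 / 0.10, dominated by the clean forms since anomalies are the
minority in practice). An `anomaly_rate` fraction of entries is replaced
by text no grammar pattern matches, with ground truth marking them
unparseable. Cohorts draw ages uniformly on 60–94, hypertension and
diabetes as independent Bernoulli draws (defaults 0.55 / 0.30, typical
of an older primary-care population), appointments uniform in a 14-day
window, and per-patient medication lists of distinct drugs (mean ≈ 6,
shifted Poisson) mixing of-interest, excluded and supply items. All
randomness flows from one integer seed through a single `random.Random`;
identical specs yield identical output.

What passing on fixtures shows: the pipeline inverts the generator's
dialect exactly (100 % ground-truth recovery at anomaly rate 0) and its
failure flagging tracks injected anomalies at the configured rate. What
it does not show: coverage of real-world dialect frequencies, misspelled
drug names, free-text the archetypes do not model, or local formulary
vocabularies — the archetypes are modeled on documented example strings,
not estimated from data, and real deployments should expect to extend
the pattern registry.

## Problem sizes and numerical notes

The test suite runs the grammar-fidelity comparison exhaustively over
small sub-alphabets (lengths ≤ 4) and by seeded sampling over the full
restricted alphabet (lengths ≤ 8; the full space at length 8 is ~10¹¹
strings, so sampling is the honest option), 20 000 samples in the
acceptance tier; round-trip recovery at n = 1 000 entries; grid
correctness against an independent brute-force tally at cohorts of
n = 500; and panel safety over 10 000 random edit sequences. Dose
values compare exactly (they are parsed decimals, not computed floats);
FIB-4 comparisons use a relative tolerance of about 10⁻⁶.
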