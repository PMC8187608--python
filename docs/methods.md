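# Methods

## The metric

Disease burden in a workforce is measured as working life years lost per
10,000 person-years of working time ("per myriad"). For employee *i* with
personal window *P_i* — the intersection of the observation window *W*
(default 2012-04-01 to 2018-03-31, half-open) with the working-age span
from the 20th to the 60th birthday — every calendar day in *P_i* is labelled
at most once as lost to **sickness absence**, **mortality** or
**ill-health retirement**:

* A certified absence spell contributes its days inside *P_i* and strictly
  before any terminal (death/retirement) date.
* Death on date *d* contributes the days of `[d, ∞) ∩ P_i`, attributed to
  the cause of death (the death certificate's code when present, otherwise
  the terminal spell's diagnosis).
* Ill-health retirement on date *r* contributes the days of
  `[r, ∞) ∩ P_i`, attributed to the diagnosis of the spell that ended in
  retirement.

The terminal consequence begins on the terminal date itself and the spell
is truncated there (zero-gap handoff), so the three day-sets are pairwise
disjoint by construction. Someone dying on their 60th birthday, or a spell
ending on the window start date, contributes exactly zero.

All spans are half-open `[start, end)` calendar-date intervals; lengths are
day counts, converted to years by division by 365.25 (a Julian year keeps
multi-year burdens stable across leap years). Spell end dates in the CSV
schemas are therefore *exclusive*; if source data record the last absent
day inclusively, one day per spell must be added on import, and estimates
produced under the two conventions can differ by one day per spell.

### Long-term filter and spell merging

Only long-term spells (raw certified length ≥ `ltsa_min_days`, default 30,
inclusive) are counted. The filter applies to the spell *as certified*,
before window clipping: a 45-day spell with 10 days inside the window is
long-term illness and contributes those 10 days. Overlapping or abutting
spells in the same disease category are fused; overlapping spells with
conflicting categories raise a data-integrity error naming the employee
and dates — concurrent contradictory certificates are surfaced, not
resolved by guesswork. At most one terminal event per employee is
accepted; a death date preceding a spell start, or retirement and death
both present, are rejected as errors.

## Disease categories

Codes are grouped by their three-character ICD-10 base code into 20
categories: the standard chapter blocks, with the injury chapter
(S00–T98) and the external-cause chapter (V01–Y98) pooled and re-split
into *Intentional self-harm* (X60–X84) and *External causes/injuries
except intentional self-harm*. The endocrine row is accepted as E00–E99
(E91–E99 are unassigned in ICD-10, so the wider range is harmless).
Sub-classification digits never change the category. Codes in no category
(U codes, the perinatal chapter, unassigned gaps such as D49 or K94–K99)
raise an error by default; an explicit `unclassified` bucket is available
by configuration. The table ships as an editable CSV inside the package.

## Denominator, rates and intervals

The person-year denominator of a stratum is the sum of annual headcounts
(by year × sex × 5-year band) falling in the stratum, one person-year per
head per annual census. Whether the original annual counts assign
mid-year hires fractional person-years is unknowable from published
totals; the one-head-one-person-year convention is documented here, not
asserted as anyone else's.

The per-myriad rate is `years_lost / denominator × 10,000`. The 95%
interval treats the person-years lost as a Poisson count `c` and uses the
normal approximation `(c − z√c, c + z√c) / denominator × 10,000`, lower
bound floored at zero; `c = 0` degenerates to `(0, 0)`. At the scale of
interest (thousands of person-years lost against ~5 × 10⁵ person-years)
this is numerically indistinguishable from a binomial approximation and
within one rounding unit of an exact Garwood interval; the choice matters
only in the last printed decimal. Both the normal and the exact interval
reproduce five of the six published reference bounds exactly when fed the
*rounded* published point estimates; the remaining bound sits on a
rounding boundary (83.3485 → 83.3 vs a printed 83.4) and is consistent
with either method given the unpublished unrounded inputs.

Stratum comparisons use a 1-df chi-squared test without continuity
correction on the 2×2 table of (person-years lost, person-years not
lost), rounded to whole person-years because the test assumes counts.

## The burden table and its exact identities

Every cell of the stratified table is internally an **integer count of
lost calendar days**; years, rates and intervals derive from it. This
makes three identities exact, not approximate:

* consequence decomposition: `sa + mortality + retirement = total`;
* group additivity: the 20 category rows sum to the all-cause row;
* stratum additivity: the four sex × age cells sum to the whole cohort,
  because each burden day is assigned to the age group the employee
  occupies *on that day* (an employee crossing 40 mid-window splits
  between cells on the birthday).

Presentation (the `summary()` report) rounds to one decimal and formats
`est (lo, hi)`; it never changes a number.

## The synthetic cohort generator

The generator emulates the record structure of a large multi-company
occupational cohort: roster (sex, birth date), long-term absence spells
with diagnosis and outcome, a death-certificate path for deaths not
preceded by recorded long-term absence, and annual April-1 headcount
censuses. Per employee, absence onsets follow a homogeneous Poisson
process on the personal window; each onset draws a disease category
(categorical by rate share), a log-normal duration in days, and an
outcome on the (return, retirement, death) simplex. A new spell cannot
begin while one is running, so conflicting overlaps never occur; the
first terminal event censors everything later. Spells straddle the window
edges and the 60th birthday by construction. Terminal spells shorter than
the 30-day threshold are re-routed realistically: a short fatal spell
surfaces as a death-certificate record, a short retirement leaves the
workforce silently (visible only to headcounts).

Default parameters describe the study conditions the package targets:
80,000 workers, 81% male, ages uniform on 20–60 at the window start, a
six-year window, onset rates 0.009/0.0025/0.0025 per person-year for
mental/neoplastic/circulatory disease, log-normal durations (median 90
days, log-sd 0.8), outcome simplices (0.93, 0.065, 0.005) /
(0.84, 0.08, 0.08) / (0.87, 0.06, 0.07), and direct-death rates of
1.0/0.7/0.7 × 10⁻⁴ per person-year for neoplasms/circulatory/self-harm.
These were set once by closed-form expectation so the default scenario
lands at the published order of magnitude (total ≈ 85 per myriad,
components ≈ 41/17/28 for SA/mortality/retirement); they are a scale
anchor, not a disease-specific calibration.

`expected_burden` estimates the generator's true per-myriad burden as the
mean over independent replicates (default 20; replicate seeds drawn from
a generator seeded with the scenario seed, so the schedule is
reproducible). Recovery tests compare a single large run against this
Monte-Carlo expectation within three replicate standard deviations.

### What the simulator does not emulate

Real cohorts have seasonal hiring and attrition, non-uniform age
pyramids, diagnosis-specific duration distributions, job-change attrition
(which the metric attributes to nothing, and which inflates observed
retirement burden), recurrence correlation within employees, and dirty
coding. Passing tests therefore demonstrate that the *accounting* is
exact and the *estimation* recovers known rates under clean conditions —
not that any particular real workforce matches the default rates.

## Numerical and design choices

* Day-to-year conversion by 365.25; all identities are checked on integer
  days, where they are exact.
* Birthday arithmetic: Feb 29 birthdays clamp to Feb 28 in non-leap years
  (dateutil convention), applied identically in the accounting layer and
  the simulator.
* `outcome_date` defaults to the spell end for terminal outcomes and must
  lie within the spell.
* Dates are strict ISO 8601; ambiguous formats are rejected.
* Test problem sizes: the randomized-oracle suite uses 1,000 histories;
  parameter recovery uses one 50,000-employee run against a 20-replicate
  expectation; interval coverage uses 500 cohorts of 2,000 employees
  against a 50-replicate truth at 10,000 employees. These sizes give
  Monte-Carlo error comfortably below the tolerances they are tested at.

## Known limitations

* Re-employment after ill-health retirement is not modelled; retirement
  burden is an upper bound.
* Short-term (< 30-day) and self-reported absence, and presenteeism, are
  out of scope of the metric.
* No age-standardisation and no multiple-testing correction of the
  chi-squared comparisons.
* The one-day-per-spell sensitivity to the end-date convention noted
  above.
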