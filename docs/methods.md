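# Methods

This note documents the models, algorithmic choices and numerical
conventions behind `fnmdlink`, and what the synthetic benchmark does and
does not demonstrate.

## The matching model

Linkage is deterministic: a pair of records (one from the local
registry, one from the mortality file) matches when every compared field
is within a fixed edit-distance budget. No probabilistic weights are
estimated; the thresholds are part of the model.

**Distance.** All string comparisons use the restricted
Damerau-Levenshtein distance (optimal string alignment, OSA): unit-cost
insertions, deletions, substitutions and adjacent transpositions, with
the restriction that no substring is edited twice. OSA is what standard
implementations compute and what the four-operation definition
describes; at the small per-field budgets used here (≤ 2) it coincides
with the unrestricted variant in practice. One consequence worth
knowing: OSA is not a true metric. The triangle inequality fails
(`d(ca,ac)=1`, `d(ac,abc)=1`, but `d(ca,abc)=3`), and a composition of
k single edits can cost up to 2k, not k. The test suite asserts the
properties OSA does satisfy (symmetry, identity of indiscernibles,
equality with an independent recursive oracle) and documents the
counterexample explicitly.

**Per-field distances.**

* First name: minimum of the local cleaned first name against the three
  mortality-side variants (first element; whole name; whole name +
  first middle name). The minimum-over-variants construction absorbs
  both directions of the compound-name convention mismatch.
* Surname: minimum over the local birth and current surnames against
  the mortality surname (which is a birth surname), skipping missing
  ones. A record with neither surname is a data error.
* Birth date: DLD between the two repaired 8-digit `YYYYMMDD` strings.
  Separators are excluded — after repair they could never differ and
  would only dilute the distance. A day/month transposition that
  survives repair (e.g. a true inversion of day 05 and month 03, which
  no validity test can detect) typically costs 2 and is rejected at the
  default budget; this is a genuine limit of the method, not of the
  implementation.
* Sex: 0 if equal, 1 if both present and different. A missing sex on
  either side scores 0: absence of evidence is not allowed to consume
  the small total budget. This is a package decision — the scoring of
  missing sex is not otherwise specified — and is the permissive choice
  (it can only add candidate matches, never remove true ones).
* City: minimum over the local raw and abbreviation-expanded city
  against the mortality city; undefined when either side lacks a city.
  City distance never participates in validation, only in selection
  tie-breaking.

**Thresholds.** Defaults are first name ≤ 2, surname ≤ 1, date ≤ 1,
sex ≤ 1, total ≤ 2, where the total is the sum of the four validated
fields. These are the values learned on stratified hospital samples in
the study this package operationalises; they are configuration, not
constants, and the constructor enforces total ≤ sum of the per-field
maxima.

**Selection.** A local record may validate against several mortality
records. The selected pair minimises total distance, then city distance
(undefined sorts last). Remaining ties are all flagged `ambiguous=True`
and the first in (death date, mortality id) order is marked selected so
output stays deterministic. The selection rule is a reconstruction: the
source study names city distance as the tie-breaking option but does
not publish its exact procedure, so ambiguity is surfaced rather than
silently resolved. Death-date plausibility (death after last encounter)
was considered and not used. Many-to-one matches (several local records
selecting the same mortality record) are allowed — registries contain
duplicates.

**Direct strategy.** The reference strategy lowercases and strips
accents (the mortality file is accent-free at source), then joins on
exact equality of preferred surname, first name, raw birth date string
and sex. Deliberately no date repair, no non-letter removal, no
variants: the gap between the two strategies measures the value of the
advanced cleaning.

## Cleaning conventions

* `normalize_text`: NFKD decomposition, combining marks dropped, a
  small ligature map (œ→oe, æ→ae, ß→ss), then everything outside a–z
  removed. Empty input maps to empty output.
* Date repair order: day+month `00` → January 1; day-only `00` → day 1
  of the stated month (the joint case is the documented one; the
  partial case follows the same fallback logic); valid dates kept;
  invalid dates kept with day/month swapped when the swap is valid;
  otherwise January 1. The repaired value always passes a calendar
  validator, leap years included.
* District suppression: a trailing token of digits plus optional
  `e`/`eme`/`ème`/`er` suffix and an optional "arrondissement" word (or
  common abbreviation) is stripped before normalisation. Only one
  printed example of the real-world pattern exists, so the regex is the
  package's generalisation of it.
* Abbreviation expansion is driven by a packaged, editable two-column
  text resource (`data/abbreviations.txt`) seeded with the usual French
  toponym abbreviations (st→saint, ste→sainte, sr→sur, ss→sous, ...).
* Blocking keys: the repaired date, and first-4-of-first-name +
  first-4-of-preferred-surname. Names shorter than 4 letters contribute
  their full length rather than being discarded.

## Engine

The mortality file is streamed in chunks (default 100,000 rows); each
chunk is blocked and scored against the in-memory local registry, and
only validated pairs — a small fraction — are retained across chunks.
Peak memory is therefore governed by the local registry and the chunk
size, not the mortality file. Chunks are independent and are dispatched
to parallel workers (joblib); `workers="auto"` uses available cores
minus one, minimum one. Because a mortality record lives in exactly one
chunk, the candidate union over chunks equals whole-file blocking, and
the final sort by (local id, mortality id) makes the pair file
byte-identical for any worker count and chunk size — determinism is
tested, not assumed.

## Evaluation

Sensitivity uses registry-recorded deaths inside the death window
(default 2001-01-01 to 2020-12-31) as gold positives; a record counts as
detected when at least one selected link carries an in-window death
date. Specificity uses patients provably alive at the index date
(default 2016-01-01, encounters on both sides); only links to deaths
*before* the index date are false positives, because the mortality file
legitimately contains the later deaths of people alive at the index
date.

Stratified estimates: strata are sex × country-of-birth group, sexes
weighted ½ each, the born-abroad fraction taken from census data (the
packaged 2012 counts give 4.5% for Nantes, 4.3% for Rennes, 8.4% for
Lille). The point estimate is Σ wₛ pₛ with variance Σ wₛ² pₛ(1−pₛ)/nₛ
and a Wald 95% interval clipped to [0, 1]. Wald on the weighted
estimator is the package's choice of interval; the exact variance
formula behind the published intervals is not stated anywhere, so ours
is documented here and labelled in the report. When a stratum is absent
from the data its weight is renormalised over the observed strata.

McNemar's test compares paired per-record outcomes of two strategies:
the continuity-corrected statistic (|b−c|−1)²/(b+c) is reported, with
the p-value from the exact binomial when the discordant total is below
25 and from the chi-square approximation otherwise (statsmodels
backend). Zero discordant pairs yields p = 1 with a degenerate flag.

## The synthetic generator

The generator emulates the relationship between a hospital extract and
a national mortality file:

* a cohort of n persons split across vital status × sex × birth-origin
  strata, counts derived from the configured rates by hierarchical
  largest-remainder rounding (vital, then sex, then origin), so the
  requested design is met exactly and deterministically;
* every deceased member gains a mortality-file counterpart (minus a
  reporting-loss rate) whose fields pass through the error model;
* background deaths of unrelated persons and optional decoys sharing
  one blocking key (same birth date, or same 4+4 name key) with a
  cohort member stress candidate generation and specificity;
* living members get encounter dates straddling the index date, so the
  specificity gold standard is well-founded.

Error model defaults (all synthetic design choices, documented as such,
with no claim to measured frequencies): per-field typo rate 0.025 on
surname, first name and date; sex miscoding 0.01; married-name rate
0.30 for women, with the birth surname missing from the local record
for 0.15 of those; day/month inversion 0.02 (applied only when the day
exceeds 12, i.e. when the inversion is detectable and repairable — an
inversion of two small numbers is indistinguishable from a correct
date); day and month recorded `00` 0.01; compound given name 0.08
(stored whole locally, split into first + middle in the mortality
file); middle-name presence 0.60; district suffixes on half of big-city
births; accents kept locally for 0.80 of records (the mortality side is
always accent-stripped); reporting loss 0.02; decoys 0.05 per member;
background 2.0 records per member. These were fixed from back-of-
envelope arithmetic so that the direct strategy loses roughly ten
sensitivity points to the distance strategy, the qualitative regime the
method was designed for, and they produce exactly that (93–94% vs
79–80% on the 10,000-patient benchmark).

A deliberate structural property: generated identities are **pairwise
distinguishable at the default thresholds** — a new person is redrawn
(rejection sampling, via the production blocking and validation code)
until no previously generated person, cohort or background, validates
against it in either orientation. This is what makes the error-free run
a clean calibration point: sensitivity and specificity are then 1.0 by
construction, so any deviation indicates a pipeline defect. It is also
the main way the synthetic data is *easier* than reality: real
registries contain homonyms born the same day, so real-world
specificity is below the synthetic one, and published specificities
(98–99.9%) should not be read off this benchmark. Other simplifications:
names are drawn uniformly from ~300-entry pools (no frequency skew, no
regional structure), typos are uniform single edits (no keyboard
adjacency or phonetic structure), and foreign-born records differ only
by birthplace (no transliteration variability), which is why the
benchmark does not reproduce the published sensitivity deficit for
patients born abroad.

## Problem sizes and numerical conventions

* The oracle-equivalence test compares the DP implementation with an
  independent memoised recursive oracle exhaustively over all string
  pairs of length ≤ 5 on a 3-letter alphabet (~132,000 ordered pairs;
  every distinct suffix pair is computed once) and on 10,000 random
  pairs of length ≤ 12 over the full alphabet.
* The engine/brute-force identity check runs 500 locals × ~2,000
  mortality records; the determinism check covers worker counts {1, 4}
  × two chunk sizes.
* The benchmark cohort is 10,000 locals (≈ 25,000 mortality records
  under the default model); the threshold sweep re-validates the
  candidate set scored once at the widest total budget (per-field maxima
  are fixed during the sweep, so a pair validated at a lower total is
  validated at every higher one — sweeping is exact, not approximate).
* Weight sums are checked to 1e-9; confidence bounds are clipped to
  [0, 1]; all randomness flows from a single `numpy` `default_rng`
  seed, and every output file is fully sorted before writing.

## Known limitations

* The OSA restriction makes composed corruptions occasionally cost more
  than their edit count (see above); with per-field budgets ≤ 2 this is
  rare but real.
* Undetectable day/month inversions (both values ≤ 12) cost 2 on the
  date field and are rejected at the default budget.
* A missing sex scores 0, so a file with no sex column loses one
  discriminating field silently (it is logged in the run summary
  counts, not warned per record).
* The selection rule beyond "minimal total, then city" is a
  deterministic reconstruction; downstream users who care about
  ambiguous pairs should filter on the `ambiguous` flag rather than
  trust `selected` alone.
* The evaluation assumes the gold standard is error-free; real
  registry-recorded deaths over-represent in-hospital deaths, which
  inflates measured sensitivity relative to all deaths.
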