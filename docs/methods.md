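# Methods

## Problem setting

Acute-geriatric discharge letters summarize a patient's stay: diagnoses,
assessment results at admission and discharge, assistive devices, and a
recommendation where the patient should go next (home, another clinic,
rehabilitation, nursing home, short-term care). For quality management
one wants cohort-level answers — which indications dominate, whether
patients improve during the stay, where they are discharged to — without
the letters ever leaving the hospital network. briefminer answers these
questions with deterministic, auditable text rules rather than learned
models: no training data is needed, every extraction is traceable to a
matched keyword and its edit distance, and the whole corpus runs in
seconds on one CPU.

## Extraction model

**Fuzzy keyword search.** Letters are processed line by line. A keyword
specification is a term plus an edit-distance budget; a line matches
when some token (for single-word terms) or sliding token window (for
multi-word terms such as "Timed up and go") is within that budget of
the term under Levenshtein distance. The distance is the standard
Wagner–Fischer dynamic programme; matching is case-insensitive after
NFKC normalization (which also repairs PDF-extraction artifacts such as
ligatures and non-breaking spaces). The default budget scales with term
length — 1 edit for ≤ 6 characters, 2 for 7–12, 3 above — because a
fixed absolute budget over-matches short German words; any keyword can
override it. Token comparisons are memoised, since the vocabulary of a
single clinic's letters is small and highly repetitive.

**Validated numeric extraction.** Numeric fields are read only from
lines already located by their keyword. A number pattern is a template
with a single `xx` placeholder ("`xx/100`", "`xx Jahre`", "`xx s`")
compiled to an anchored regular expression; German decimal commas are
converted. Each metric carries an inclusive validity interval and any
value outside it is discarded *before* any further processing — a
mistyped "450/100" Barthel value becomes missing rather than an
outlier, and can never shift the admission/discharge pairing.

**Pipeline order.** Per letter: deceased check and age extraction run
on the *raw* letter, because the birth date ("`* dd.mm.yyyy`") sits in
the letterhead; only then are boilerplate lines (configured letterhead
phrases, page markers, and — when at least two page markers are present
— lines repeated verbatim across pages) removed, and the remaining
fields extracted from the cleaned text. A failure in any stage records
a missing value; a letter is never dropped.

Field-specific conventions:

- **Age**: a direct "Alter: xx Jahre" statement wins; otherwise
  treatment year (first full date not preceded by `*`, i.e. the letter
  date) minus the birth year. Plausibility interval [40, 115] years —
  a geriatric cohort — rejects transcription errors.
- **Gender**: majority vote over patient tokens. Each token is compared
  against the inflected feminine forms ("Patientin", "Patientinnen")
  and masculine forms ("Patient", "Patienten") at edit budget 1; the
  strictly nearer side wins the token and exact ties abstain. Comparing
  against full inflected forms (rather than prefix matching) keeps
  "Patientin" from being counted as masculine, and the majority vote
  absorbs single typos. The source letters only encode binary gender;
  the extractor reflects that limitation.
- **Assessments**: all keyword hits for a metric are collected in
  document order; the first valid value is the admission value, the
  last valid value of a later hit the discharge value. Letters list
  assessment blocks chronologically, which this convention relies on;
  explicit "bei Aufnahme" / "bei Entlassung" anchors on the value line
  override it when present. A single hit yields an admission value only.
- **Devices**: the line hit by the device keyword ("Hilfsmittel") is
  split on commas after the colon; empty items are dropped.
- **Diagnoses**: the block of lines following the "Diagnosen" header,
  up to a blank line or the next section header.
- **Allocation**: allocation keywords (Häuslichkeit, Klinik,
  Rehabilitation, Seniorenheim/Pflegeheim, Kurzzeitpflege) are searched
  on recommendation-bearing lines (lines hit by a cue such as
  "empfehlen", "Entlassung", "Verlegung"; the whole letter serves as
  fallback when no cue line exists). Multiple hits resolve by a fixed
  precedence — clinic > short-term care > rehabilitation > nursing
  home > home — chosen so the most care-intensive recommendation wins;
  all raw hits are kept in the record for audit. Deceased letters carry
  no allocation.

**Diagnosis categories.** Five indication categories (fall-related /
alterstraumatological, stroke, decompensated heart failure,
neurodegenerative with escalation, multifactorial frailty) are defined
by term lists: full keywords are fuzzy-matched at token level, subwords
are exact case-insensitive substrings — no fuzz on subwords, to control
false positives. A letter may realize several categories; its sorted
category set is its *cluster*. Ambiguous abbreviations (e.g. "HWI",
which can mean urinary-tract infection or posterior-wall infarction)
are deliberately absent from the default lists and are flagged in the
audit log when encountered. The shipped lists are a documented,
configurable default, not a canonical vocabulary; per-letter agreement
with any particular clinic's internal lists is not claimed.

## Cohort statistics

- **Improvement** is reported relative to each metric's scale: for
  bounded, higher-is-better scales (Barthel, Tinetti) it is
  (discharge − admission) / scale width. The timed up-and-go has no
  scale ceiling, so its improvement is relative to the admission time,
  (admission − discharge) / admission, which keeps the sign convention
  (positive = better) without inventing a ceiling. Improvements exist
  only where both values were extracted.
- **Five-number summaries** use the midpoint median (mean of the
  central pair for even n) and linear interpolation for quartiles
  (numpy's default).
- **Shares**: allocation shares are over letters with an extractable
  allocation (deceased and unknown excluded, so the five shares sum to
  100); cluster shares are over all letters including the reserved
  "uncategorized" cluster. Category shares are reported under two
  denominators: share of all category *assignments* (which sums to 100
  under multi-assignment and is the headline figure) and share of
  *letters* carrying the category.
- **Rounding** is half-up (commercial rounding) to one decimal wherever
  a percentage is reported.

## Synthetic corpus and calibrated preset

The generator emulates the letters' semi-structured layout: a clinic
letterhead (boilerplate), a letter date, a name line with the birth
date "`* dd.mm.yyyy`", gendered narrative sentences, a diagnosis block
whose phrases realize exactly the letter's assigned category set, an
admission and a discharge assessment block, a comma-separated device
list, and a closing recommendation sentence realizing the allocation.
Three layout templates are cycled deterministically so extraction logic
cannot overfit a single template. Duplicates are byte-identical copies
under new file names. A fixed seed yields a byte-identical corpus.

The `paper_default` preset is *count-calibrated*: wherever the target
cohort is described by a percentage, the preset fixes integer counts so
the statistic is exact and seed-independent (the seed only permutes
which letter carries which values). Its composition: 393 files, 21
exact duplicates (372 unique); 274 female / 98 male; 3 deceased letters
(without allocation, with admission-only assessments); allocations
151/66/78/11/63 over the 369 non-deceased letters (shares 40.9 / 17.9 /
21.1 / 3.0 / 17.1 %); the three dominant clusters fixed at 106
({sturz, multifaktor}), 52 ({sturz, neurodegenerativ, multifaktor}) and
48 ({sturz, kardial, multifaktor}) letters (28.5 / 14.0 / 12.9 %);
3 uncategorized letters; the remaining 163 letters carry singleton and
pair category sets (13 {multifaktor}, 19 {sturz}, 8 {neurodegenerativ},
12 {kardial}, 22 {schlaganfall}, 30 {neurodegenerativ, multifaktor},
25 {kardial, multifaktor}, 14 {sturz, kardial}, 12 {sturz,
neurodegenerativ}, 8 {sturz, schlaganfall}), chosen by integer search
so the per-category assignment shares come out at 35.9 / 33.9 / 13.4 /
13.0 / 3.9 % (counts 274/259/102/99/30 over 764 assignments). Those
marginals sum to 100.1 %, which is only consistent with an
assignments denominator — over a letters denominator they are not
representable as integer counts, and the preset audit checks them only
to ±0.3 percentage points.

Ages are constructed, not merely sampled: a seeded normal draw
(mean 84.4, SD 6.6, clipped to [66, 103]) is deterministically adjusted
so the sum is exactly `round(84.4 · 372)` (hence the one-decimal mean
is 84.4 for every seed) and the sample SD lands in [6.55, 6.65). Half
the letters state the age directly ("Alter: xx Jahre"), half only via
birth-date arithmetic, so both extraction strategies are exercised.

Assessment pairs are built so the median relative improvement is
*exactly* 0.40 (Barthel), 0.25 (Tinetti) and 0.20 (TUG): each metric's
369 values consist of a below-median block, an at-median block wide
enough to cover the central rank, and an above-median block; the
Barthel distribution additionally contains its extremes −0.35 and
+0.80. Values live on each metric's natural grid (Barthel multiples of
5, integer Tinetti points, integer seconds).

**Typo injection** perturbs keyword occurrences only: for rate r, each
occurrence of a configured keyword receives ⌊r⌋ edits plus one more
with probability r − ⌊r⌋ (rate 1 ⇒ exactly one random substitution,
deletion or insertion per occurrence). Numbers and the birth-date line
are never edited — they are pattern-anchored, not keyword-matched.
Duplicates are copied after injection, so the duplicate count is
unaffected.

**What the generator does not emulate**: free-text narrative variety,
inconsistent section ordering, real abbreviation noise, OCR artifacts,
genuinely ambiguous gender references, and letters missing entire
sections. Passing the round-trip tests therefore demonstrates that the
pipeline's rules are internally consistent and typo-robust on the
documented layout family — not that they would transfer unchanged to
another clinic's letters, which the configuration layer exists to
accommodate.

## Numerical and degenerate-input choices

- Deduplication compares whitespace-normalized full text; exact
  matching keeps counts reproducible. It is idempotent, and
  |unique| + removed = |input| always.
- `extract_number` takes the first pattern occurrence on a line; an
  interval-rejected value yields missing for that line rather than a
  scan for later occurrences (patterns are anchored to their keyword's
  line, which carries one value in practice).
- Empty corpus: warning plus a summary of zeros/missings, exit 0.
- Empty letter: a record of missing values.
- TUG improvement is undefined (missing) for an admission time of 0.
- Median/quartile conventions as above; percentages half-up.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
393-file preset corpus (about 2 s per run); the Levenshtein
implementation is verified exhaustively against an independent
recursion oracle on all string pairs of length ≤ 4 over a three-letter
alphabet plus a seeded random sample up to length 8 cross-checked
against edlib, and the remaining invariants are property-tested with
hypothesis under fixed derandomized settings.

## Known limitations

- Only explicitly configured information is extracted; implicit
  statements ("kann wieder in die eigene Wohnung") are missed unless a
  keyword covers them.
- The admission/discharge pairing assumes chronological assessment
  blocks when no explicit anchors are present.
- Gender extraction is binary by construction of the source letters.
- Subword matching is exact; a typo inside a category subword is only
  caught if a fuzzy full keyword also covers the phrase.
- The five category lists are stand-ins; real deployments must curate
  them (the config file makes that a data change, not a code change).
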