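# Methods

This note documents the models, rules, and numerical conventions behind
`forumrx`, the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Problem setting

The package reconstructs a treatment-pattern comparison for
advanced/metastatic melanoma: a cohort of forum posters (2011–2017 first-line
initiation) whose lines of therapy are derived from free text, compared
against four EMR/claims-style comparator cohorts (Flatiron, McKesson,
MarketScan, PharMetrics+ in the bundled reference tables) after 4:1 frequency
matching on first-line year. Agreement is assessed by overlap of 95%
confidence intervals on per-line regimen proportions, not by formal tests of
equality.

## Text processing

**Cleaning.** URLs are removed, characters outside a fixed whitelist
(letters, digits, space, `. , ! ? ' - /`) are replaced by a space, and
whitespace is collapsed. Replacing (rather than deleting) non-whitelisted
characters keeps separators as token boundaries, so `ipi+nivo` remains two
detectable tokens. Cleaning is idempotent.

**Sentence splitting** breaks at `. ! ?` followed by whitespace, with an
abbreviation guard (`Dr.`, `e.g.`, …). Sentences are the unit of
classification and of negation/temporal scope: forum posts mix topics
sentence to sentence, and negation cues rarely project across a boundary.

**User ids** are the first 12 hex digits of SHA-1 over
`username ␟ forum` — deterministic, and distinct for the same handle on two
forums (each (username, forum) pair is treated as one patient; thread
structure and multi-user discussions of one patient are out of scope).

## Mention detection

The lexicon maps surface variants (brands, abbreviations, common
misspellings) to canonical generic names for the NCCN-era melanoma systemic
therapies: ipilimumab, nivolumab, pembrolizumab, vemurafenib, dabrafenib,
trametinib, cobimetinib, binimetinib, encorafenib, temozolomide, dacarbazine,
paclitaxel, carboplatin, interleukin-2, talimogene laherparepvec, and the
adjuvant-flagged interferon and docetaxel. Matching is case-insensitive
whole-token matching (two-token phrases first, leftmost-longest), plus fuzzy
matching at Levenshtein distance ≤ 1 restricted to tokens of ≥ 6 characters.
The length gate prevents three-letter abbreviations ("ipi") from fuzzy-firing;
the distance bound makes the typo tolerance auditable. Fuzzy ties are broken
to the alphabetically first canonical (never observed with the bundled
vocabulary, whose names are pairwise ≥ 2 edits apart). Tokens joined by `/`
split into separate mentions, so "ipi/nivo" contributes both drugs;
combination *detection* is timeline logic, not lexicon logic.

## Receipt classification

Sentences with mentions may or may not state that the poster received the
drug. Three standard text classifiers are compared on TF-IDF unigram
features: linear-kernel SVM (`LinearSVC`), multinomial naive Bayes, and KNN
with K = 5. The TF-IDF dialect is scikit-learn's default smoothed form,
idf(t) = ln((1+N)/(1+df(t))) + 1 with L2-normalized rows; the vocabulary is
fitted on the training fold only. The token pattern keeps single-character
tokens so that degenerate corpora featurize predictably.

Labels come from the synthetic generator (receipt vs non_receipt per
sentence). Training uses a stratified 80/20 split; if the training fold is
more imbalanced than 60/40 the majority class is downsampled to that bound.
Precision and recall treat receipt as the positive class; undefined ratios
(zero denominators) are reported as absent, never as zero. Model selection
maximizes precision + recall, ties broken by precision and then by the fixed
order (SVM, NB, KNN). With single-class labels — a noise-free corpus has no
non-receipt sentences — the pipeline's classifier gate disables itself and
passes every sentence through (training itself still refuses single-class
input).

## Negation and temporal resolution

**Negation** is a NegEx-style window rule: a cue (not, never, no, didn't,
declined, refused, denied, without, "no longer", …; editable list shipped as
package data) within the five tokens preceding the mention negates it, unless
a scope terminator (but, however, although, though, except, yet) intervenes.
"They said no to surgery but I started nivolumab" is therefore affirmative
for nivolumab.

**Temporal resolution** is total: every sentence yields
`(event_date, rule)`. Explicit month expressions ("in March 2014", "3/2014")
anchor to day 15 of the month; relative expressions (N days/weeks/months/
years ago, number words one–twelve, "last week/month/year") are subtracted
from the post date; otherwise the post date itself is used. Month-precision
truth uses day 15 throughout — forum language rarely carries day precision,
and the convention only affects intra-month ordering. Mentions dated more
than 30 days after their post ("I will start pembro next month") are intent,
not receipt, and are excluded; the 30-day slack tolerates date fuzziness.

The three filters (classifier verdict, negation, future-date) are
conjunctive, so their order cannot change the result.

## Lines of therapy

Per patient, surviving mentions become (event_date, drug) events,
de-duplicated at (drug, calendar month) granularity keeping the earliest
date, sorted with alphabetical tie-breaks so input order is irrelevant.
Lines are then derived with an explicit algorithm (claims-analytics
convention, since no published line definition is available to reproduce):

1. the first non-adjuvant event opens line 1;
2. drugs first seen within 28 days (`combo_window_days`, configurable) of
   the current line's start join its regimen;
3. a new non-regimen drug after the window closes the line and opens the
   next;
4. re-mentions of current-regimen drugs never advance lines, but a same-day
   event alongside a line-opening drug carries the old drug into the new
   combination (ipilimumab → ipilimumab+nivolumab keeps ipilimumab in
   line 2);
5. lines whose regimen would be exactly {interferon} or {docetaxel} are
   discarded (adjuvant monotherapy) with the remainder renumbered;
6. adjuvant drugs inside a genuine multi-drug window do count as combination
   members.

Absence of further mentions never closes a line (forums report starts far
more reliably than stops), so gap-based splitting is deliberately not
implemented. Lines beyond the third are computed but reported separately.

## Matching and comparison

Frequency matching selects, per first-line year y,
`min(pool(y), 4 × sm(y))` comparator patients uniformly at random (seeded);
index patients in years with an empty pool are reported dropped. Matched
counts are a function of the inputs only — the seed changes identities, never
counts.

Proportions use the source's line-N patient count as denominator and carry
Wald 95% half-widths, 100·1.96·√(p̂(1−p̂)/n), with p̂ unrounded and the
reported proportion and half-width rounded to one decimal. The Wald form
(which can extend below zero for small p̂) was verified against the bundled
reference tables: cells like 1.4% ± 2.7% imply a negative lower bound that
Wilson or Clopper–Pearson intervals cannot produce. Overlap is evaluated on
the *reported* (rounded) intervals as closed sets — touching endpoints count,
which is required to reproduce the reference annotation where one database
interval meets the social-media interval exactly at 7.6%. Regimen labels
compare as '+'-joined sorted canonical-name sets.

Two discrepancies in the bundled reference tables are knowingly left
unresolved rather than corrected: one half-width cell (first-line
vemurafenib, Flatiron: printed 1.2, recomputed 1.1496 from any numerator
consistent with the printed 10.2%) differs by 0.0504 points, an apparent
double-rounding artifact; and nine database cells whose intervals plainly
intersect the social-media interval lack the overlap annotation (e.g.
second-line temozolomide, McKesson: 0.8 ± 1.1 vs 3.5 ± 2.4). The acceptance
tests assert the published values cell by cell, so these appear as expected
failures; the headline property — every regimen × line row overlaps at least
one database — holds exactly (18/18).

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed to the
reference marginals: first-line year counts (40, 96, 140, 180, 127, 127,
107), P(second line) = 226/817 ≈ 0.277, P(third | second) = 73/226 ≈ 0.323,
and per-line regimen mixes anchored to the reference social-media columns
with the remainder spread over older agents (temozolomide, dacarbazine,
interleukin-2, carboplatin+paclitaxel). Regimens are gated by US approval
era (no pembrolizumab before 2014, no ipilimumab+nivolumab before 2015, …)
and renormalized per year; consecutive lines are redrawn until the new
regimen introduces at least one new drug, since a repeated regimen is
indistinguishable from continued therapy in mention data. Line gaps are
uniform 3–15 months; 10% of patients carry an interferon/docetaxel decoy
exposure 6–24 months before first line, which the adjuvant rule must ignore.

Each truth line is described by 1–2 posts written 0–90 days after the start,
with the date phrased absolutely ("in March 2014") or relatively ("three
months ago") at the configured rate; relative phrasings are generated
consistently with the actual lag, so both resolve to the true start month.
Drug surfaces use brand names 30% of the time and carry one-edit typos at
the typo rate (single-token surfaces ≥ 6 characters only, so every injected
typo stays inside the matcher's tolerance). Noise processes, each with a
per-patient rate (defaults 0.1, relative-date phrasing 0.3): negated decoy
mentions that satisfy the negation grammar, non-receipt drug discussions,
and off-topic posts.

Sentence templates are a fixed, versioned list in the module. They are
deliberately not cleanly separable: oblique phrasings ("Next step is X",
"We settled on X") occur in both receipt and discussion contexts; proxy and
hedge sentences ("My sister started X", "I almost started X", "I was
supposed to start X and it fell through") flip receipt vocabulary with one
rare marker word; conversational filler (greetings, asides, with their own
spelling errors) dominates token counts without carrying label signal; and
discussion decoys are drawn from the era's regimen mix rather than uniformly,
so drug identity is not a class giveaway. These are the features of real
forum language that make receipt classification non-trivial; with them, the
classifier comparison reproduces the expected ranking (SVM ≥ NB > KNN) with
SVM precision/recall around 0.98–0.99 — well above the published 84%/84%,
as template-generated text remains far more regular than human prose. The
exact published percentages are a property of the unavailable curated corpus
and are not targets.

The generator emits a complete sentence-level label table keyed exactly as
the ingest stage keys sentences, replacing manual curation. All randomness
derives from one master seed through per-stage streams (CRC of the stage
name mixed into the seed sequence), making every artifact bit-reproducible
and every stage independently rerunnable.

**What passing synthetic tests shows — and does not.** Zero-noise recovery
(derived lines equal truth exactly) and noisy recovery (first-line regimen
proportions inside the truth's 95% Wald CI for ≥ 90% of regimens across 20
seeds at n = 1,000) validate the pipeline's internal consistency: its
filters, date arithmetic, and line rules invert the generator's rendering.
They do not establish performance on real forum text, whose ambiguity
(sarcasm, uncertainty, cross-post references, posters who are not the
patient) exceeds the template model; nor do they validate the forum
population against database populations — the generator draws both from the
same distributions by construction.

## Problem sizes and runtime conventions

Default experiment sizes were chosen to keep sampling error well below the
assertion margins while remaining quick to run: classifier experiments use
2,500 patients (≈ 5,500 labeled sentences, comfortably above the 5,000
minimum); recovery experiments use 1,000 patients × 20 seeds; distributional
convergence checks use 10,000 journeys against a 2-percentage-point
tolerance. The full test suite runs in under a minute on one CPU.

## Known limitations

- The bundled lexicon is a reconstruction from guideline-era drugs, not the
  original (unavailable) curated list with its observed misspellings.
- Temporal resolution handles single-sentence expressions only; cross-
  sentence temporal chains ("after that ended … the following spring") are
  out of scope.
- The 1,196 → 817 social-media attrition rule of the emulated study is
  unstated in its source; matching here retains patients per-database and
  reports drops explicitly instead.
- Hedge/uncertainty detection and sarcasm are unhandled, as in the emulated
  pipeline.
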