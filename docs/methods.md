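# Methods

## The screening model

`medcomplex` implements a deterministic, rule-based assessment of
medication-regimen complexity in four stages that mirror how a structured
medication review proceeds in practice:

1. **Structured input.** The analysed unit is a medication schedule in the
   repository's simplified dialect of the German nationally standardised
   plan: per drug a product identifier (PZN, a 7–8-digit code unique to
   each marketed product, stored as a zero-padded string because leading
   zeros are significant), brand name, active ingredient, dosage form,
   strength, a dosage-scheme string, unit, free-text instructions,
   indication and an as-needed (PRN) flag. The dialect deliberately covers
   only the analysed subset of the national format; barcode decoding and
   the full official schema are out of scope.
2. **Automated detection** of 38 of the 61 catalogued complexity factors.
3. **Personalisation**: key questions bound to findings, plus eight
   always-asked distinct questions and one open question.
4. **Optimisation measures** for confirmed problems, including five
   product-substitution algorithms.

Every stage is a pure function of its inputs; reports are byte-identical
across runs on identical inputs.

## The catalogue

The 61 factors, their categories (13 dosage form, 14 dosage scheme,
8 additional instructions, 10 patient, 5 product, 11 process), detection
mechanisms, question bank and measure registry are data, not code: one
versioned YAML file packaged with the library, so content can be revised
without touching the rule engine. All counts surfaced by `kb_stats` are
computed by enumerating the loaded records. `validate_kb` enforces the
cross-record invariants (exactly 61 factors; automated factors carry a
valid mechanism; in-tool factors carry at least one question and measure;
the nine out-of-scope factors carry neither; exactly 8 distinct questions,
1 open question, 5 distinct algorithm references; no dangling references).
Nine factors judged too vague for a single question (e.g. health literacy,
busy lifestyle) are recorded with `in_tool: false` and are reachable only
through the open question.

Device-specific variation (five inhaler types, eye drops vs. ointment,
three liquid-oral delivery modes) is encoded as subtypes under a single
parent factor, preserving the 61-count while keeping device-specific key
questions addressable.

## Detection rules

**PZN rules.** The row's PZN is looked up in the drug reference; the
product's form class maps to the corresponding dosage-form factor
(carrying the device subtype), with nasal and dermatological preparations
gated on prescription-only status. Product attributes drive three more
factors: a palatability flag on liquid oral forms (patient-unfriendly
liquid), a technique-training requirement (lack of training), and a
self-measurement linkage that fires only together with a free-text keyword
hit (complex self-performed measurements). Rows whose PZN cannot be
resolved skip PZN rules and are reported as warnings.

**Dosage-scheme rules.** The scheme grammar accepts 2–4 dash-separated
decimal tokens (German decimal commas normalised, fractions like `1/2`
accepted; 2–3 tokens right-padded with zero slots); anything else degrades
to an unstructured scheme that keeps the original text — the parser never
raises. Seven rules operate on the slot quadruple:

| rule | condition |
|---|---|
| tablet splitting | a slot dose with a non-zero fractional part, on a solid oral form |
| >2× daily | more than two non-zero slots |
| lunch-time dose | noon slot > 0 |
| multiple concurrent doses | any slot dose ≥ 2 |
| differing doses | ≥ 2 distinct non-zero slot values |
| variable dosing | unstructured non-empty scheme on a non-PRN row |
| lone drug at a time point | a slot where this row doses and no other structured row does |

The lone-drug rule requires at least two rows with structured schemes: a
one-drug plan trivially occupies its slots alone and flagging it would
contradict the intent of the factor (an administration time kept solely
for one drug). Variable dosing is suppressed on PRN rows to avoid
double-flagging intentionally dose-free as-needed entries, which have
their own factor and question.

**Schedule-level rules.** The total-number-of-drugs factor fires at a
configurable line count (default 5, the common polypharmacy convention;
the plan format itself defines no cut-off). Duplicate active ingredients
across rows with different PZNs fire the same-ingredient factor once per
row pair; ingredients come from the drug reference where the PZN resolves,
else from the row's `+`-separated ingredient list (combination products
list components and each is compared separately).

**Keyword rules.** Matching is case-insensitive and word-boundary-based
(`seafood` never matches *eat* or *food*); multi-word phrases match across
whitespace runs. The meal-dependent list (*meal, food, eat, breakfast,
lunch, dinner*) is the published one; the other twelve keyword factors ship
repo-curated default lists, marked `provenance: repo-default` in the
lexicon files and freely editable. English and German lexicons are
included; frequency-style factors (once weekly, every-two-days, fixed
interval, PRN) additionally scan unstructured scheme text, where
prescribers often write intervals. The PRN factor also fires on the row's
PRN flag alone, since the national plan has a dedicated as-needed section.
Once-weekly administration is keyword-driven, not inferred from scheme
arithmetic.

Each automated factor fires at most once per row (schedule-level factors
once per schedule, pair factors once per pair), and every finding carries
typed evidence (matched phrase and span, slot pattern, product attribute,
line count, ingredient pair) matching its factor's mechanism.

## Interview semantics

Key questions instantiate once per (question, row) so the interviewer can
reference the concrete drug; device subtypes select the matching variant
(with the generic variant as fallback for unknown subtypes). Answer
polarity is stored per question part, because the transcribed phrasings mix
problem-affirming ("Do you have problems …?" — yes confirms) and
competence-affirming ("Do you always succeed …?" — no confirms) forms; a
global yes-means-problem rule would mis-score the latter. Multi-part
questions (e.g. the two PRN knowledge checks) confirm on any problematic
part. Numeric predicates are thresholded; the breath-hold cut-off defaults
to < 5 s (a counselling convention — the question itself states none) and
the injection-site question treats more than one injection per site as
problematic; both are data in the KB and configurable. A distinct question
that confirms marks *all* factors it covers (the prescription-change
question spans six process factors; the schedule cannot tell them apart).
Unanswered questions resolve to not-confirmed with a warning; open-question
text is stored verbatim and never auto-mapped to a factor.

## Measures and substitution algorithms

Each confirmed factor instantiates its registered measures in a fixed
order: algorithm, recommendation for action, training material.
Recommendations carry one of three topics (suggest an aid / explain
administration / review the regimen); training materials are metadata
stubs (leaflet/video identifiers without content). Because the registry
ships exactly one stub per flagged measure type per factor, the original
deployment's material totals are intentionally not reproduced.

The registry contains exactly five algorithms. Four are reachable from
factors flagged for substitution in the catalogue — matching strength
(covering both tablet splitting and stacked concurrent doses), easier form
(crushing and swallowing problems), fixed-dose combination (polypharmacy),
prefilled injector (non-prefilled injections). The fifth,
extended-release frequency reduction, is attached to the
more-than-twice-daily factor as a repo-curated mapping so that every
registered algorithm is reachable; the allocation is data and
configurable. All algorithms filter the curated `equivalence_group` of the
drug reference — an explicit field rather than inferred ATC matching,
because no general substitution-equivalence rule is defensible from
product data alone — and therefore can only ever propose products present
in the reference. Suggestions are advisory; the tool never modifies a
schedule (the "apply" step exists only as a test helper and in the
acceptance script's reduction check).

## The drug reference

The commercial national product database is replaced by a flat synthetic
fixture (59 records, CSV) spanning every form class, every device subtype,
and one scenario per algorithm (half/double strengths, a liquid and an
orodispersible sibling, an extended-release sibling, a fixed-dose
combination with matching component strengths, a vial/pen pair). PZNs,
brand names and groupings are fabricated; attribute flags
(`prescription_only`, `palatability_issue`, `requires_technique_training`,
`self_measurement_linked`) are encoded explicitly per record.

## Synthetic schedules and what passing tests show

The generator plants requested factors on dedicated rows: a product whose
attributes trigger the PZN rule, a scheme constructed for the scheme rule,
a designated lexicon phrase for the keyword rule (each phrase verified to
hit exactly its own factor's list). Background rows use trigger-free
solid-oral products with a neutral morning/evening scheme, and noise text
comes from a pool verified to contain no lexicon phrase, so ground truth
stays exact rather than probabilistic. Structural side effects of
composing rows — a planted noon dose leaving a drug alone at noon, a row
count crossing the polypharmacy threshold — are derived by the generator
from its own slot matrix and product table and included in the ground
truth; the correctness of the rules themselves is guarded independently by
the 625-scheme enumeration oracle. Output is fully determined by the seed.

The default regression corpus is 50 schedules with 2–5 injected factors
each, round-robin over the 38 automated factors so each is exercised at
least once; detection recovers the planted truth exactly (precision =
recall = 1 by set equality). This is exact *by construction* — generator
and detector share the dialect — so it validates the rule plumbing, not
real-world robustness: misspellings, non-standard abbreviations,
incomplete plans and unlisted self-medication are explicitly outside what
these tests can show, and no spelling correction or NLP beyond
word-boundary matching is attempted. Sound-alike/look-alike drug-name
detection is likewise out of scope.

## Numerical and design choices

* Slot doses are compared exactly; half-unit doses (0.5, 1.5) are
  representable without error in binary floating point, and strength
  matching in the algorithms uses a 1e-9 tolerance.
* Deterministic orderings throughout: findings by (first row, catalogue
  position), alternatives by (strength, PZN), measures by (factor order,
  measure type).
* Degenerate inputs: an empty schedule is rejected; an unparseable scheme
  degrades to unstructured; unknown PZNs, unknown equivalence groups and
  unanswered questions degrade to warnings/empty results rather than
  errors.
* Reports embed the configuration, input digests and the schedule itself,
  and omit timestamps unless requested, so a report alone reproduces the
  run.
* Test and acceptance problem sizes — 50 suite schedules, 625 enumerated
  schemes, six reduction scenarios — are the package's chosen regression
  scope and run in seconds.
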