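# medcomplex

Rule-based screening of **medication-regimen complexity** from structured
medication plans, with patient-preference triage and alternative-drug
suggestion — a clinical-decision-support library and CLI for pharmacists,
physicians and medication-safety researchers.

Complexity of drug treatment — split tablets, inhaler technique, meal
coordination, many daily dosing time points — is a known driver of
non-adherence. `medcomplex` analyses a patient's medication schedule (the
German nationally standardised plan dialect: one row per drug with PZN,
brand, ingredient, form, strength, the morning–noon–evening–night dosage
quadruple, unit, free-text instructions, indication and an as-needed flag)
against a catalogue of **61 complexity factors** in six categories (dosage
form, dosage scheme, additional instructions, patient, product, process):

* **38 factors are detected automatically**, via four rule families:
  PZN lookup in a drug-reference table (dosage forms and product
  attributes), the parsed dosage scheme (e.g. a fractional slot dose ⇒
  tablet splitting; >2 non-zero slots ⇒ frequent dosing), the schedule
  line count (polypharmacy, default threshold 5), and case-insensitive
  word-boundary keyword matching in free text (e.g. *meal, food, eat,
  breakfast, lunch, dinner* for meal-dependent administration).
* Every finding is personalised with a **key question** (device-specific
  where it matters — metered-dose inhaler vs. Elpenhaler vs. nebuliser);
  **8 distinct questions** cover 14 factors that cannot be read off a
  schedule (swallowing difficulties, cognitive impairment, …), for **52
  factors** addressable in total, and one open-ended question closes every
  interview. Nine factors are deliberately out of scope.
* Confirmed problems map to **optimisation measures**: recommendations for
  action (aid suggestion / explain administration / review regimen),
  training-material stubs, and **5 algorithms** that propose substitutable
  products — matching strength (whole units instead of halves or stacks),
  easier dosage form, extended-release for fewer time points, fixed-dose
  combinations, and prefilled injection devices.

The catalogue, question bank and measure registry live in one editable YAML
file (`src/medcomplex/data/knowledge_base.yaml`); the drug reference is a
synthetic offline fixture spanning every form class. A seeded generator
(`medcomplex.synth`) produces schedules with known planted factors so
detection can be verified exactly.

## Worked example

A three-drug plan: amlodipine 10 mg taken as half tablets, a salbutamol
metered-dose inhaler, and atorvastatin "take with dinner":

```bash
medcomplex analyze plan.xml --out report.json
# wrote report with 3 finding(s) to report.json
```

The report's findings (factor, rows, evidence):

```
tablet_splitting  [0]  fractional_dose (slots 0.5-0-0.5-0)
inhalers          [1]  form_class=inhaler, device metered_dose_inhaler
meal_dependent    [2]  matched keyword "dinner" in instructions
```

and 12 question instances: three key questions bound to the findings
(`q_tablet_splitting@0`, `q_inhaler_mdi@1`, `q_meal_dependent@2`), the
eight distinct questions, and the open question. Answering that splitting
is a problem, inhaler use is fine (breath-hold 8 s), and meals are no
issue:

```bash
medcomplex interview report.json --answers answers.json --out final.json
# confirmed 1 factor(s), planned 2 measure(s); wrote final.json
```

confirms only `tablet_splitting` and plans its two measures: the
strength-substitution algorithm — *"one unit of AmloBene 5 (5 mg) replaces
0.5 x 10 mg of AmloBene 10"* — and a tablet-splitting leaflet stub.
Re-running `analyze` on the amended plan no longer flags splitting.

`medcomplex kb-stats` prints the catalogue structure, counted by
enumeration at run time:

```
n_factors=61      n_automated=38    n_in_tool=52    n_not_considered=9
categories: dosage_form=13 dosage_scheme=14 additional_instructions=8
            patient=10 product=5 process=11
n_distinct_questions=8   n_algorithms=5
```

Other subcommands: `validate-kb` (integrity check of a catalogue file) and
`synth` (seeded schedules with ground truth, e.g.
`medcomplex synth --seed 9 --inject meal_dependent,tablet_splitting --out dir/`).

## Layout

```
src/medcomplex/
  knowledge_base.py   61-factor catalogue: loader, validator, stats
  schedule_io.py      plan dialect: XML/CSV readers/writers, scheme grammar
  drug_reference.py   PZN-keyed product table, equivalence-group filtering
  detection.py        the 38 automated rules, keyword lexicon
  interview.py        question instancing and answer resolution
  recommender.py      measure planning and the 5 substitution algorithms
  synth.py            seeded ground-truth schedule generator
  cli.py              analyze / interview / kb-stats / validate-kb / synth
  data/               knowledge base, lexicons (en/de), drug fixture, schemas
docs/methods.md       models, rules, parameters, limitations
```
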