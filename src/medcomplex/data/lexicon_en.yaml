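# Keyword lexicon, English. One entry per keyword-driven factor (plus the
# free-text half of the measurement factor). Matching is case-insensitive on
# word boundaries; multi-word phrases match across single whitespace runs.
#
# provenance: "paper" marks the one published list (meal keywords); every
# other list is a repo-curated default and freely editable.
# scan_scheme_text: frequency-style factors are also screened against the
# raw dosage-scheme text, where prescribers often write intervals.
language: en
factors:
  once_weekly:
    provenance: repo-default
    scan_scheme_text: true
    phrases: ["once weekly", "once a week", "weekly", "every week", "per week"]
  every_two_days_or_less:
    provenance: repo-default
    scan_scheme_text: true
    phrases: ["every other day", "every two days", "every 2 days",
              "every three days", "every 3 days", "alternate days"]
  fixed_dosing_interval:
    provenance: repo-default
    scan_scheme_text: true
    phrases: ["every 6 hours", "every 8 hours", "every 12 hours",
              "exact interval", "evenly spaced", "hours apart"]
  occasional_episodic:
    provenance: repo-default
    phrases: ["episodic", "short course", "until the pack is finished",
              "for a limited time", "course of treatment"]
  prn:
    provenance: repo-default
    scan_scheme_text: true
    phrases: ["as needed", "if necessary", "when required", "as required",
              "if needed", "on demand"]
  meal_dependent:
    provenance: paper
    phrases: ["meal", "food", "eat", "breakfast", "lunch", "dinner"]
  crushing_tablets:
    provenance: repo-default
    phrases: ["crush", "crushed", "crushing"]
  disintegrating_tablets:
    provenance: repo-default
    phrases: ["dissolve", "dissolved", "effervescent", "disperse in water"]
  fixed_times_of_day:
    provenance: repo-default
    phrases: ["fixed time", "always at the same time", "o'clock",
              "at 8 am", "at 8 pm", "exactly at"]
  advised_liquid:
    provenance: repo-default
    phrases: ["plenty of water", "full glass of water", "with milk",
              "with juice", "with yoghurt"]
  opening_capsules:
    provenance: repo-default
    phrases: ["open the capsule", "capsule may be opened", "sprinkle",
              "capsule contents"]
  increasing_doses:
    provenance: repo-default
    phrases: ["increase the dose", "increasing dose", "titrate up",
              "up-titration", "dose increase"]
  decreasing_doses:
    provenance: repo-default
    phrases: ["reduce the dose", "decreasing dose", "taper", "tapering",
              "dose reduction"]
  complex_measurements:
    provenance: repo-default
    phrases: ["blood glucose", "blood sugar", "inr", "coagulation",
              "according to measurement"]
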