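# Keyword lexicon, German. Parallel structure to lexicon_en.yaml; all lists
# are repo-curated defaults for German-language plan free text.
language: de
factors:
  once_weekly:
    provenance: repo-default
    scan_scheme_text: true
    phrases: ["wöchentlich", "einmal pro woche", "1x pro woche", "jede woche"]
  every_two_days_or_less:
    provenance: repo-default
    scan_scheme_text: true
    phrases: ["jeden zweiten tag", "alle zwei tage", "alle 2 tage",
              "alle drei tage", "alle 3 tage"]
  fixed_dosing_interval:
    provenance: repo-default
    scan_scheme_text: true
    phrases: ["alle 6 stunden", "alle 8 stunden", "alle 12 stunden",
              "im abstand von", "gleichmäßig verteilt"]
  occasional_episodic:
    provenance: repo-default
    phrases: ["episodisch", "kur", "bis packung aufgebraucht",
              "zeitlich begrenzt"]
  prn:
    provenance: repo-default
    scan_scheme_text: true
    phrases: ["bei bedarf", "nach bedarf", "falls nötig", "wenn erforderlich"]
  meal_dependent:
    provenance: repo-default
    phrases: ["mahlzeit", "essen", "nüchtern", "frühstück", "mittagessen",
              "abendessen"]
  crushing_tablets:
    provenance: repo-default
    phrases: ["mörsern", "zerkleinern", "zerstoßen"]
  disintegrating_tablets:
    provenance: repo-default
    phrases: ["auflösen", "aufgelöst", "brausetablette", "in wasser lösen"]
  fixed_times_of_day:
    provenance: repo-default
    phrases: ["feste uhrzeit", "immer zur gleichen zeit", "pünktlich um",
              "uhr"]
  advised_liquid:
    provenance: repo-default
    phrases: ["viel wasser", "großes glas wasser", "mit milch", "mit saft"]
  opening_capsules:
    provenance: repo-default
    phrases: ["kapsel öffnen", "kapsel kann geöffnet", "aufstreuen",
              "kapselinhalt"]
  increasing_doses:
    provenance: repo-default
    phrases: ["dosis steigern", "aufdosieren", "einschleichen",
              "dosiserhöhung"]
  decreasing_doses:
    provenance: repo-default
    phrases: ["dosis reduzieren", "ausschleichen", "abdosieren",
              "dosisreduktion"]
  complex_measurements:
    provenance: repo-default
    phrases: ["blutzucker", "gerinnung", "inr", "nach messwert"]
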