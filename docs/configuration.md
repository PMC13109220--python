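# Configuration file schema

`briefminer analyze --config FILE` layers a YAML (or JSON) file over the
shipped defaults: only the keys present in the file are overridden.
Unknown keys and malformed sections are rejected before any processing,
with an error naming the offending key.

## Keyword specifications

Wherever a keyword is expected, either a plain string (defaults apply)
or a mapping may be given:

```yaml
death_keywords:
  - verstorben                 # string form: default budget, whole word
  - {term: verstarb, max_distance: 1, whole_word: true, case_sensitive: false}
```

`max_distance` defaults to a length-scaled budget (1 for terms of ≤ 6
characters, 2 for 7–12, 3 above) and must be smaller than the term
length.

## Top-level keys

```yaml
metrics:                       # assessment metrics to extract
  barthel:
    keyword: Barthel-Index     # locates the value-bearing lines
    pattern: xx/100            # exactly one 'xx' numeric capture
    interval: [0, 100]         # values outside are rejected (required)
    scale: [0, 100]            # scale bounds for relative improvement
    higher_is_better: true     # false for time-based metrics (TUG)
    units: points

death_keywords: [verstorben, verstarb]

female_terms: [Patientin, Patientinnen]   # inflected forms, exact list
male_terms: [Patient, Patienten]
gender_max_distance: 1

device_keyword: Hilfsmittel
diagnosis_section_keyword: Diagnosen

age_keyword: Alter
age_pattern: xx Jahre
age_interval: [40, 115]

boilerplate_patterns:          # letterhead/footer lines to strip
  - {term: St. Aurelius Hospital, max_distance: 3}
  - {term: Seite, max_distance: 0}

allocation_cues: [Empfehlung, empfehlen, Entlassung, entlassen, Verlegung, verlegt]
allocation_keywords:           # labels: home, clinic, rehabilitation,
  home: [Häuslichkeit]         #   nursing_home, short_term_care
  clinic: [Klinik]

categories:                    # diagnosis categories
  sturz:
    keywords: [Sturz, Fraktur]        # fuzzy, token-level
    subwords: [sturz, fraktur, alterstraumatolog]  # exact substrings

ambiguous_abbreviations: [HWI] # never matched, flagged in audit.log
```

Partial overrides merge: overriding `allocation_keywords.home` leaves
the other labels at their defaults, while list-valued keys
(`female_terms`, `death_keywords`, ...) replace the default list
entirely. Defining `metrics` replaces the metric set, which is how a
deployment selects which assessments to extract.
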