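# briefminer

Rule-based information extraction from German geriatric discharge letters
(*Entlassbriefe*), built for quality management in hospital discharge
planning. Given a directory of plain-text letters, briefminer extracts,
per letter: a deceased flag, age, (binary) gender, assistive devices,
diagnoses, five diagnosis categories, the recommended post-discharge
allocation, and admission/discharge values of three standard geriatric
assessments — the Barthel index (0–100 activities of daily living),
the Tinetti test (0–28 balance and gait) and the timed up-and-go test
(seconds). It then aggregates the cohort: category and cluster
frequencies, allocation shares, and relative assessment-improvement
distributions.

The tool is deliberately *not* machine learning. Discharge letters are
protected health data that cannot leave the hospital, and in-hospital
compute is limited, so extraction relies on two simple, auditable
kernels:

- **Fuzzy keyword search** — every line is scanned for configured
  keywords under a Levenshtein edit-distance budget, so typing errors
  ("Bartel-Index") still match. Budgets scale with term length
  (1 edit for terms ≤ 6 characters, 2 up to 12, 3 above) and are
  overridable per keyword.
- **Validated numeric extraction** — numbers are pulled from
  keyword-bearing lines with anchored patterns ("`xx/100`",
  "`xx Jahre`", "`xx s`"; German decimal commas accepted), and every
  metric carries a validity interval (Barthel [0, 100], Tinetti
  [0, 28], TUG [3, 300] s) that rejects implausible values at the
  source.

Because real letters cannot be redistributed, the package ships a
synthetic-corpus generator whose letters mimic the semi-structured
layout of the originals (letterhead with birth date "`* dd.mm.yyyy`",
assessment blocks, comma-separated device lists, recommendation
sentences). Its calibrated `paper_default` preset fixes integer
ground-truth counts so that the cohort statistics of a freshly
generated corpus are deterministic and reproducible; a typo-injection
mode perturbs keyword occurrences for robustness testing.

## Worked example

```sh
briefminer generate --out corpus            # calibrated synthetic preset
briefminer analyze --input-dir corpus --out results
briefminer verify --corpus corpus --truth corpus/ground_truth.csv
```

The `generate` step writes 393 letter files (372 unique plus 21 exact
duplicates) with a `ground_truth.csv`. The `analyze` step prints

```
analyzed 372 letters (21 duplicates removed, 0 load errors) -> results
```

and writes `records.csv` (one row per letter), `audit.log` (every
matched keyword with its edit distance, every rejected number) and
`summary.json`, which for the preset contains among other things:

```json
{
  "n_letters": 372,
  "gender": {"female": 274, "male": 98, "unknown": 0},
  "age": {"mean": 84.4005, "sd": 6.6461, "n": 372},
  "allocation_share_percent": {
    "home": 40.9, "clinic": 17.9, "rehabilitation": 21.1,
    "nursing_home": 3.0, "short_term_care": 17.1
  },
  "n_uncategorized": 3
}
```

That reads: of 372 unique letters, 274 concern women and 98 men, the
mean age is 84.4 years, and of the letters with an extractable
allocation 40.9 % recommend discharge home, 17.9 % a clinic transfer,
21.1 % rehabilitation, 3.0 % a nursing home and 17.1 % short-term care.
The per-metric improvement summary reports, e.g. for the Barthel index,
`n: 369, min: -0.35, median: 0.40, max: 0.80, median_percent: 40.0` — a
median gain of 40 % of the 100-point scale between admission and
discharge, with individual courses ranging from a 35 % deterioration to
an 80 % gain. The `verify` step scores extraction against the
generator's ground truth field by field and ends with
`total mismatches: 0`.

The same pipeline runs on real letters exported as UTF-8 text (one file
per letter; PDF-to-text conversion is an external pre-step). All
keyword lists, patterns, intervals and category definitions are
overridable from a YAML config (`--config`); see
`docs/configuration.md`.

## Package layout

| Module | Role |
| --- | --- |
| `briefminer.matching` | Levenshtein distance, fuzzy keyword search, validated numeric extraction |
| `briefminer.corpus_io` | letter loading, boilerplate removal, deduplication |
| `briefminer.extraction` | per-letter pipeline: deceased, age, gender, devices, assessments, diagnoses, allocation |
| `briefminer.categorization` | diagnosis-category assignment and cluster keys |
| `briefminer.stats` | cohort summary: shares, five-number improvement summaries |
| `briefminer.synthetic` | ground-truthed corpus generator with the calibrated preset |
| `briefminer.cli` | `briefminer analyze / generate / verify` |

Methodological details and design rationale are in `docs/methods.md`.
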