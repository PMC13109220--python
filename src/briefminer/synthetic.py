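"""Synthetic German discharge-letter corpus with known ground truth.

Real geriatric discharge letters are protected health data, so the
pipeline is exercised on generated letters that emulate their
semi-structured layout: a clinic letterhead with the birth date in the
form "* dd.mm.yyyy", gendered patient references, a diagnosis block, two
assessment blocks ("bei Aufnahme" / "bei Entlassung") with values like
"Barthel-Index: xx/100", a comma-separated device list and a closing
recommendation sentence naming the post-discharge allocation.

The generator is count-driven: wherever the cohort report states a
percentage, the preset fixes integer counts (not sampling probabilities),
so the resulting corpus statistics are deterministic and identical for
every seed. The ``paper_default`` preset encodes the reference cohort
(393 files, 21 exact duplicates, 274/98 female/male, mean age 84.4,
median improvements 40/20/25 %, ...). A typo-injection mode perturbs
keyword occurrences for robustness testing; numbers and the birth-date
line are never edited.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .config import ALLOCATION_LABELS, AnalyzerConfig, default_config

__all__ = [
    "GeneratorConfig",
    "paper_default",
    "generate_corpus",
    "inject_typos",
    "typo_target_terms",
]

import random

_BIRTH_LINE = re.compile(r"\*\s*\d{2}\.\d{2}\.\d{4}")

_LETTER_DATE = "15.03.2024"
_TREATMENT_YEAR = 2024

_SURNAMES = ("Krüger", "Schäfer", "Lindemann", "Boldt", "Wegner", "Arning",
              "Janssen", "Thielmann")
_PHYSICIANS = ("Dr. med. A. Beispiel", "Dr. med. K. Tenbrink", "Dr. med. S. Morgner")

_DEVICE_POOL = ("Rollator", "Gehstützen", "Greifzange", "Toilettensitzerhöhung",
                "Duschhocker", "Rollstuhl")

#: two diagnosis-line variants per category; each realizes exactly its category
_DIAGNOSIS_PHRASES: dict[str, tuple[str, ...]] = {
    "sturz": (
        "Zustand nach Sturz mit pertrochantärer Femurfraktur",
        "Sturz mit Radiusfraktur links",
    ),
    "schlaganfall": (
        "Ischämischer Schlaganfall mit Hemiparese links",
        "Zustand nach Apoplex mit Hemiparese rechts",
    ),
    "kardial": (
        "Dekompensierte Herzinsuffizienz NYHA III",
        "Kardiale Dekompensation bei Herzinsuffizienz",
    ),
    "neurodegenerativ": (
        "Fortschreitende Demenz vom Alzheimer-Typ",
        "Parkinson-Syndrom mit Delir bei Exazerbation",
    ),
    "multifaktor": (
        "Gebrechlichkeit multifaktorieller Genese mit Sarkopenie",
        "Multifaktorielle Gangunsicherheit bei Frailty-Syndrom",
    ),
}

#: diagnoses that match no category (for the uncategorized letters)
_NEUTRAL_PHRASES = (
    "Akuter Harnwegsinfekt",
    "Ambulant erworbene Pneumonie",
    "Exsikkose bei reduzierter Trinkmenge",
)

_ALLOCATION_SENTENCES = {
    "home": "Wir empfehlen die Entlassung in die Häuslichkeit.",
    "clinic": "Wir empfehlen die Verlegung in die Klinik für Innere Medizin.",
    "rehabilitation": "Wir empfehlen die Entlassung in eine stationäre Rehabilitation.",
    "nursing_home": "Wir empfehlen die Entlassung in ein Seniorenheim.",
    "short_term_care": "Wir empfehlen die Entlassung in die Kurzzeitpflege.",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Composition of a synthetic corpus.

    Counts are over unique letters (``n_files - n_exact_duplicates``);
    duplicates are byte-identical copies of the first unique letters.
    """

    n_files: int
    n_exact_duplicates: int
    n_female: int
    n_male: int
    deceased_count: int
    allocation_counts: Mapping[str, int]
    cluster_counts: Mapping[tuple[str, ...], int]
    uncategorized_count: int
    age_mean: float = 84.4
    age_sd: float = 6.6
    age_bounds: tuple[int, int] = (66, 103)
    # per-metric trajectory rules; medians are hit exactly by construction
    barthel_median_points: int = 40
    barthel_min_points: int = -35
    barthel_max_points: int = 80
    tinetti_median_delta: int = 7
    tug_median: float = 0.20
    typo_rate: float = 0.0
    seed: int = 20240315

    @property
    def n_unique(self) -> int:
        return self.n_files - self.n_exact_duplicates


def validate(config: GeneratorConfig) -> None:
    """Reject unsatisfiable configurations, naming the violated invariant."""
    if not 0 <= config.n_exact_duplicates < config.n_files:
        raise ValueError("invariant violated: n_exact_duplicates < n_files")
    if config.n_female + config.n_male != config.n_unique:
        raise ValueError(
            "invariant violated: gender counts must sum to n_files - n_exact_duplicates"
        )
    if config.deceased_count > config.n_unique:
        raise ValueError("invariant violated: deceased_count <= unique letters")
    if sum(config.allocation_counts.values()) != config.n_unique - config.deceased_count:
        raise ValueError(
            "invariant violated: allocation counts must sum to unique letters - deceased"
        )
    unknown = set(config.allocation_counts) - set(ALLOCATION_LABELS)
    if unknown:
        raise ValueError(f"invariant violated: unknown allocation labels {sorted(unknown)}")
    if sum(config.cluster_counts.values()) + config.uncategorized_count != config.n_unique:
        raise ValueError(
            "invariant violated: cluster counts + uncategorized must sum to unique letters"
        )
    if config.typo_rate < 0:
        raise ValueError("invariant violated: typo_rate >= 0")


def paper_default(seed: int = 20240315, typo_rate: float = 0.0) -> GeneratorConfig:
    """The calibrated preset encoding the reference cohort.

    393 files with 21 exact duplicates (372 unique); 274 female / 98 male;
    mean age 84.4 (SD 6.6); 3 deceased letters without allocation; the
    369 allocations split 151/66/78/11/63 (home/clinic/rehabilitation/
    nursing home/short-term care), whose shares round half-up to
    40.9/17.9/21.1/3.0/17.1 %; the three largest diagnosis clusters fixed
    at 106/52/48 letters (28.5/14.0/12.9 %) with 3 uncategorized letters;
    the remaining 163 letters' category sets chosen so the per-category
    assignment shares reproduce 35.9/33.9/13.4/13.0/3.9 %; assessment
    pairs constructed so the median relative improvement is exactly 0.40
    (Barthel), 0.20 (timed up-and-go) and 0.25 (Tinetti), with Barthel
    extremes -0.35 and +0.80 present.
    """
    cluster_counts = {
        ("multifaktor", "sturz"): 106,
        ("multifaktor", "neurodegenerativ", "sturz"): 52,
        ("kardial", "multifaktor", "sturz"): 48,
        ("multifaktor",): 13,
        ("sturz",): 19,
        ("neurodegenerativ",): 8,
        ("kardial",): 12,
        ("schlaganfall",): 22,
        ("multifaktor", "neurodegenerativ"): 30,
        ("kardial", "multifaktor"): 25,
        ("kardial", "sturz"): 14,
        ("neurodegenerativ", "sturz"): 12,
        ("schlaganfall", "sturz"): 8,
    }
    return GeneratorConfig(
        n_files=393,
        n_exact_duplicates=21,
        n_female=274,
        n_male=98,
        deceased_count=3,
        allocation_counts={
            "home": 151,
            "clinic": 66,
            "rehabilitation": 78,
            "nursing_home": 11,
            "short_term_care": 63,
        },
        cluster_counts=cluster_counts,
        uncategorized_count=3,
        typo_rate=typo_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# deterministic constructions

def _construct_ages(config: GeneratorConfig, rng: random.Random) -> list[int]:
    """Integer ages whose mean rounds to the target and SD sits in band.

    Starts from a seeded normal draw, then deterministically adjusts: the
    sum is pinned to round(mean * n) (so the one-decimal mean is
    seed-invariant) and +-1 transfers between below-mean and above-mean
    entries steer the sample SD into [target - 0.05, target + 0.05).
    """
    n = config.n_unique
    lo, hi = config.age_bounds
    ages = [int(min(hi, max(lo, round(rng.gauss(config.age_mean, config.age_sd)))))
            for _ in range(n)]
    target_sum = round(config.age_mean * n)
    i = 0
    while sum(ages) != target_sum:
        idx = i % n
        i += 1
        if sum(ages) < target_sum and ages[idx] < hi:
            ages[idx] += 1
        elif sum(ages) > target_sum and ages[idx] > lo:
            ages[idx] -= 1
    sd_lo, sd_hi = config.age_sd - 0.05, config.age_sd + 0.05
    mean = target_sum / n
    for _ in range(200_000):
        sd = statistics.stdev(ages)
        if sd_lo <= sd < sd_hi:
            break
        if sd < sd_lo:  # widen: pull one low entry lower, one high entry higher
            i_low = min((i for i in range(n) if lo < ages[i] <= mean),
                        key=lambda i: ages[i], default=None)
            i_high = max((i for i in range(n) if mean <= ages[i] < hi),
                         key=lambda i: ages[i], default=None)
            if i_low is None or i_high is None:
                break
            ages[i_low] -= 1
            ages[i_high] += 1
        else:  # narrow: move the extremes toward the mean
            i_min = min(range(n), key=lambda i: ages[i])
            i_max = max(range(n), key=lambda i: ages[i])
            if ages[i_max] - ages[i_min] <= 2:
                break
            ages[i_min] += 1
            ages[i_max] -= 1
    return ages


def _median_block_counts(n: int) -> tuple[int, int, int]:
    """(below, at, above) sizes placing the median rank(s) in the at-block."""
    n_at = max(3, n // 8)
    n_below = (n - n_at) // 2
    n_above = n - n_at - n_below
    # central rank(s) must fall inside the at-block
    lo_rank = (n - 1) // 2
    hi_rank = n // 2
    assert n_below <= lo_rank and hi_rank < n_below + n_at
    return n_below, n_at, n_above


def _barthel_pairs(config: GeneratorConfig, n: int, rng: random.Random) -> list[tuple[int, int]]:
    at = config.barthel_median_points
    below_grid = [d for d in range(config.barthel_min_points, at, 5)]
    above_grid = [d for d in range(at + 5, config.barthel_max_points + 1, 5)]
    n_below, n_at, n_above = _median_block_counts(n)
    deltas = (
        [config.barthel_min_points]
        + [rng.choice(below_grid) for _ in range(n_below - 1)]
        + [at] * n_at
        + [config.barthel_max_points]
        + [rng.choice(above_grid) for _ in range(n_above - 1)]
    )
    pairs = []
    for d in deltas:
        a_lo, a_hi = max(0, -d), min(100, 100 - d)
        a = rng.choice(range(a_lo, a_hi + 1, 5))
        pairs.append((a, a + d))
    return pairs


def _tinetti_pairs(config: GeneratorConfig, n: int, rng: random.Random) -> list[tuple[int, int]]:
    at = config.tinetti_median_delta
    n_below, n_at, n_above = _median_block_counts(n)
    deltas = (
        [rng.choice(range(-3, at)) for _ in range(n_below)]
        + [at] * n_at
        + [rng.choice(range(at + 1, 15)) for _ in range(n_above)]
    )
    pairs = []
    for d in deltas:
        a_lo, a_hi = max(0, -d), min(28, 28 - d)
        a = rng.randint(a_lo, a_hi)
        pairs.append((a, a + d))
    return pairs


_TUG_AT_POOL = ((10, 8), (15, 12), (20, 16), (25, 20), (30, 24), (35, 28), (40, 32))
_TUG_BELOW_POOL = ((20, 22), (25, 26), (30, 33), (20, 19), (30, 27), (40, 34), (25, 22),
                   (35, 35), (28, 30), (24, 21), (32, 28), (18, 16), (45, 41), (22, 20))
_TUG_ABOVE_POOL = ((20, 10), (30, 18), (25, 15), (40, 28), (28, 14), (36, 24), (45, 27),
                   (24, 15), (50, 30), (30, 21), (32, 20), (40, 24), (26, 13), (44, 22))


def _tug_pairs(config: GeneratorConfig, n: int, rng: random.Random) -> list[tuple[int, int]]:
    n_below, n_at, n_above = _median_block_counts(n)
    pairs = [rng.choice(_TUG_BELOW_POOL) for _ in range(n_below)]
    pairs += [rng.choice(_TUG_AT_POOL) for _ in range(n_at)]
    pairs += [rng.choice(_TUG_ABOVE_POOL) for _ in range(n_above)]
    return pairs


# ---------------------------------------------------------------------------
# typo injection

def typo_target_terms(config: Optional[AnalyzerConfig] = None) -> tuple[str, ...]:
    """All full keyword terms the analyzer searches fuzzily.

    These are the occurrences ``inject_typos`` perturbs; numeric patterns
    and the birth-date field are not keywords and stay untouched.
    """
    cfg = config or default_config()
    terms: list[str] = []
    for m in cfg.metrics:
        terms.append(m.keyword.term)
    terms += [s.term for s in cfg.death_keywords]
    terms += list(cfg.female_terms) + list(cfg.male_terms)
    terms.append(cfg.device_keyword.term)
    terms.append(cfg.diagnosis_section_keyword.term)
    terms.append(cfg.age_keyword.term)
    terms += [s.term for s in cfg.allocation_cues]
    for specs in cfg.allocation_keywords.values():
        terms += [s.term for s in specs]
    for cdef in cfg.categories:
        terms += [s.term for s in cdef.keywords]
    # longest first so "Patientin" is consumed before "Patient"
    return tuple(sorted(set(terms), key=len, reverse=True))


_ALPHABET = "abcdefghijklmnopqrstuvwxyzäöü"


def _edit_once(word: str, rng: random.Random) -> str:
    positions = [i for i, c in enumerate(word) if c.isalpha()]
    if not positions:
        return word
    i = rng.choice(positions)
    op = rng.choice(("substitute", "delete", "insert"))
    if op == "substitute":
        repl = rng.choice(_ALPHABET)
        while repl == word[i].lower():
            repl = rng.choice(_ALPHABET)
        return word[:i] + repl + word[i + 1 :]
    if op == "delete":
        return word[:i] + word[i + 1 :]
    return word[:i] + rng.choice(_ALPHABET) + word[i:]


def inject_typos(
    text: str,
    rate: float,
    seed: int | random.Random,
    keywords: Sequence[str] | None = None,
) -> str:
    """Apply random single-character edits to keyword occurrences.

    ``rate`` is the expected number of edits per keyword occurrence (an
    integer rate applies exactly that many edits to every occurrence).
    Digits and the birth-date line are never touched. Deterministic for a
    given seed.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return text
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    terms = tuple(keywords) if keywords is not None else typo_target_terms()
    alternation = "|".join(
        r"\s+".join(re.escape(w) for w in term.split()) for term in terms
    )
    pattern = re.compile(rf"(?<![0-9A-Za-zÄÖÜäöüß])(?:{alternation})(?![0-9A-Za-zÄÖÜäöüß])",
                         re.IGNORECASE)
    out_lines = []
    for line in text.split("\n"):
        if _BIRTH_LINE.search(line):
            out_lines.append(line)
            continue
        matches = list(pattern.finditer(line))
        for m in reversed(matches):  # right-to-left keeps earlier spans valid
            n_edits = int(rate) + (1 if rng.random() < rate - int(rate) else 0)
            chunk = m.group(0)
            for _ in range(n_edits):
                chunk = _edit_once(chunk, rng)
            line = line[: m.start()] + chunk + line[m.end() :]
        out_lines.append(line)
    return "\n".join(out_lines)


# ---------------------------------------------------------------------------
# rendering

def _render_letter(row: dict, template: int, rng: random.Random) -> str:
    female = row["gender"] == "female"
    date_line = ("Bielefeld, den " + _LETTER_DATE, "Bielefeld, " + _LETTER_DATE,
                 "Datum: " + _LETTER_DATE)[template]
    initial = rng.choice("ABEGHKLMRSW")
    name = f"{initial}. {rng.choice(_SURNAMES)}"
    lines = [
        "St. Aurelius Hospital Bielefeld - Akutgeriatrie",
        date_line,
        f"{name}, geb. * {row['birth_date']}",
        "",
        "Sehr geehrte Frau Kollegin, sehr geehrter Herr Kollege,",
    ]
    if female:
        lines.append(
            "wir berichten über die Patientin, die sich vom 01.03.2024 bis zum "
            f"{_LETTER_DATE} in unserer stationären Behandlung befand."
        )
    else:
        lines.append(
            "wir berichten über den Patienten, der sich vom 01.03.2024 bis zum "
            f"{_LETTER_DATE} in unserer stationären Behandlung befand."
        )
    if row["age_direct"]:
        lines.append(f"Alter: {row['age']} Jahre.")
    if female:
        lines.append(
            "Bei Aufnahme präsentierte sich die Patientin in reduziertem Allgemeinzustand."
        )
    else:
        lines.append(
            "Bei Aufnahme präsentierte sich der Patient in reduziertem Allgemeinzustand."
        )
    lines += ["", "Diagnosen:"]
    for phrase in row["diagnosis_lines"]:
        lines.append(f"- {phrase}")
    lines.append("")
    adm_header = ("Assessment bei Aufnahme:", "Geriatrisches Assessment bei Aufnahme:",
                  "Befunde bei Aufnahme:")[template]
    dis_header = ("Assessment bei Entlassung:", "Geriatrisches Assessment bei Entlassung:",
                  "Befunde bei Entlassung:")[template]
    lines.append(adm_header)
    lines.append(f"Barthel-Index: {row['barthel_admission']}/100")
    lines.append(f"Tinetti-Test: {row['tinetti_admission']}/28")
    lines.append(f"Timed up and go: {row['tug_admission']} s")
    lines.append("")
    if row["barthel_discharge"] is not None:
        lines.append(dis_header)
        lines.append(f"Barthel-Index: {row['barthel_discharge']}/100")
        lines.append(f"Tinetti-Test: {row['tinetti_discharge']}/28")
        lines.append(f"Timed up and go: {row['tug_discharge']} s")
        lines.append("")
    if row["devices"]:
        lines.append("Hilfsmittel: " + ", ".join(row["devices"]))
        lines.append("")
    noun = "Die Patientin" if female else "Der Patient"
    gen = "der Patientin" if female else "des Patienten"
    if female:
        lines.append("Während des Aufenthalts wurde die Patientin physiotherapeutisch "
                     "und ergotherapeutisch behandelt.")
    else:
        lines.append("Während des Aufenthalts wurde der Patient physiotherapeutisch "
                     "und ergotherapeutisch behandelt.")
    if row["deceased"]:
        lines.append(f"{noun} ist am 14.03.2024 im Krankenhaus verstorben.")
        lines.append(f"Wir bedauern, den Verlauf {gen} nicht günstiger berichten zu können.")
    else:
        lines.append(f"{noun} zeigte sich im Verlauf zunehmend mobilisiert.")
        lines.append(_ALLOCATION_SENTENCES[row["allocation"]])
        lines.append(f"Wir danken für die Weiterbehandlung {gen}.")
    lines += ["", "Mit freundlichen Grüßen", rng.choice(_PHYSICIANS), "Seite 1 von 1"]
    return "\n".join(lines) + "\n"


def generate_corpus(
    config: GeneratorConfig,
    out_dir: str | Path,
    analyzer_config: Optional[AnalyzerConfig] = None,
) -> pd.DataFrame:
    """Write the corpus and return the per-letter ground-truth table.

    One ``.txt`` file per letter; duplicates are byte-identical copies of
    the first unique letters under new file names. The ground truth (one
    row per unique letter) is also written as ``ground_truth.csv`` next to
    the corpus, with a ``duplicates.csv`` mapping copies to originals.
    Fixed seed implies a byte-identical corpus.
    """
    validate(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)
    n = config.n_unique

    ages = _construct_ages(config, rng)
    rng.shuffle(ages)
    genders = ["female"] * config.n_female + ["male"] * config.n_male
    rng.shuffle(genders)
    category_sets: list[tuple[str, ...]] = []
    for cats, count in config.cluster_counts.items():
        category_sets += [tuple(sorted(cats))] * count
    category_sets += [()] * config.uncategorized_count
    rng.shuffle(category_sets)
    deceased_idx = set(rng.sample(range(n), config.deceased_count))
    allocations = [label for label in ALLOCATION_LABELS
                   for _ in range(config.allocation_counts.get(label, 0))]
    rng.shuffle(allocations)

    n_alive = n - config.deceased_count
    barthel = _barthel_pairs(config, n_alive, rng)
    tinetti = _tinetti_pairs(config, n_alive, rng)
    tug = _tug_pairs(config, n_alive, rng)
    for pairs in (barthel, tinetti, tug):
        rng.shuffle(pairs)

    rows: list[dict] = []
    alive_cursor = 0
    for i in range(n):
        letter_id = f"brief_{i + 1:03d}"
        age = ages[i]
        birth_year = _TREATMENT_YEAR - age
        birth_date = f"{rng.randint(1, 28):02d}.{rng.randint(1, 12):02d}.{birth_year}"
        deceased = i in deceased_idx
        if deceased:
            allocation = "unknown"
            b = (rng.choice(range(20, 61, 5)), None)
            t = (rng.randint(5, 18), None)
            g = (rng.choice((20, 25, 30, 35)), None)
        else:
            allocation = allocations[alive_cursor]
            b, t, g = barthel[alive_cursor], tinetti[alive_cursor], tug[alive_cursor]
            alive_cursor += 1
        cats = category_sets[i]
        diagnosis_lines = [
            _DIAGNOSIS_PHRASES[c][rng.randrange(len(_DIAGNOSIS_PHRASES[c]))] for c in cats
        ]
        if not cats:
            diagnosis_lines = list(rng.sample(_NEUTRAL_PHRASES, 2))
        n_devices = rng.randint(0, 3)
        devices = list(rng.sample(_DEVICE_POOL, n_devices)) if n_devices else []
        rows.append({
            "letter_id": letter_id,
            "file": f"{letter_id}.txt",
            "deceased": deceased,
            "age": age,
            "age_direct": i % 2 == 0,
            "birth_date": birth_date,
            "gender": genders[i],
            "diagnosis_lines": diagnosis_lines,
            "devices": devices,
            "categories": cats,
            "allocation": allocation,
            "barthel_admission": b[0], "barthel_discharge": b[1],
            "tinetti_admission": t[0], "tinetti_discharge": t[1],
            "tug_admission": g[0], "tug_discharge": g[1],
        })

    typo_rng = random.Random(config.seed + 1)
    texts: list[str] = []
    for i, row in enumerate(rows):
        text = _render_letter(row, template=i % 3, rng=rng)
        if config.typo_rate > 0:
            text = inject_typos(text, config.typo_rate, typo_rng,
                                typo_target_terms(analyzer_config))
        texts.append(text)
        (out_dir / row["file"]).write_text(text, encoding="utf-8")

    dup_rows = []
    for k in range(config.n_exact_duplicates):
        src = rows[k % n]
        dup_file = f"brief_{n + k + 1:03d}.txt"
        (out_dir / dup_file).write_text(texts[k % n], encoding="utf-8")
        dup_rows.append({"file": dup_file, "duplicate_of": src["letter_id"]})

    truth = pd.DataFrame([{
        **{k: v for k, v in row.items()
           if k not in ("devices", "categories", "diagnosis_lines")},
        "devices": ";".join(row["devices"]),
        "categories": ";".join(row["categories"]),
    } for row in rows])
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    pd.DataFrame(dup_rows).to_csv(out_dir / "duplicates.csv", index=False)
    return truth
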