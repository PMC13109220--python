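"""Per-letter extraction pipeline.

Processing order mirrors how the letters are structured: the deceased
check and age extraction run on the RAW letter first — the birth date
("* dd.mm.yyyy") sits in the letterhead, which the subsequent cleaning
step removes — then boilerplate is stripped and the remaining fields
(assessments, gender, devices, diagnoses, allocation) are extracted from
the cleaned text. Any stage failure is recorded as a missing value; a
letter is never aborted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .categorization import assign_categories
from .config import ALLOCATION_PRECEDENCE, AnalyzerConfig, MetricConfig
from .corpus_io import CleanLetter, RawLetter, strip_boilerplate
from .matching import (
    KeywordSpec,
    NumberPattern,
    extract_number,
    fuzzy_distance,
    search_lines,
    tokenize,
)

__all__ = [
    "AssessmentResult",
    "PatientRecord",
    "detect_deceased",
    "extract_age",
    "extract_gender",
    "extract_devices",
    "extract_assessment",
    "extract_allocation",
    "extract_diagnoses",
    "analyze_letter",
]

_DATE = re.compile(r"(\d{2})\.(\d{2})\.(\d{4})")
_BIRTH_DATE = re.compile(r"\*\s*(\d{2})\.(\d{2})\.(\d{4})")


@dataclass(frozen=True)
class AssessmentResult:
    """Admission/discharge values of one assessment metric."""

    name: str
    admission_value: Optional[float]
    discharge_value: Optional[float]
    scale_min: float
    scale_max: float
    higher_is_better: bool


@dataclass
class PatientRecord:
    """Everything extracted from one letter."""

    letter_id: str
    deceased: bool = False
    age: Optional[int] = None
    gender: str = "unknown"  # female | male | unknown
    devices: list[str] = field(default_factory=list)
    diagnoses: list[str] = field(default_factory=list)
    categories: set[str] = field(default_factory=set)
    allocation: str = "unknown"
    allocation_hits: list[str] = field(default_factory=list)
    assessments: list[AssessmentResult] = field(default_factory=list)
    audit: list[str] = field(default_factory=list)

    def assessment(self, name: str) -> Optional[AssessmentResult]:
        for a in self.assessments:
            if a.name == name:
                return a
        return None


def detect_deceased(letter: RawLetter, specs: Sequence[KeywordSpec]) -> bool:
    """True iff any configured death keyword hits the raw letter."""
    return any(search_lines(letter.lines, spec) for spec in specs)


def _treatment_year(lines: Sequence[str]) -> Optional[int]:
    """Year of the first full date NOT preceded by '*' (the letter date)."""
    for line in lines:
        for m in _DATE.finditer(line):
            prefix = line[max(0, m.start() - 2) : m.start()]
            if "*" in prefix:
                continue
            return int(m.group(3))
    return None


def extract_age(
    letter: RawLetter,
    treatment_year: Optional[int],
    age_keyword: KeywordSpec,
    age_pattern: NumberPattern,
    audit: list[str] | None = None,
) -> Optional[int]:
    """Age from a direct statement, else birth-year arithmetic.

    A direct "Alter: xx Jahre" statement wins; otherwise the birth year
    from the letterhead form "* dd.mm.yyyy" is subtracted from the
    treatment year (taken from the letter itself when not given).
    Implausible values are rejected by the pattern's interval.
    """
    for hit in search_lines(letter.lines, age_keyword):
        value = extract_number(hit.line_text, age_pattern)
        if value is not None:
            return int(value)
        if audit is not None:
            audit.append(f"age: keyword line without valid number: {hit.line_text!r}")
    if treatment_year is None:
        treatment_year = _treatment_year(letter.lines)
    if treatment_year is None:
        return None
    for line in letter.lines:
        m = _BIRTH_DATE.search(line)
        if m:
            age = treatment_year - int(m.group(3))
            lo, hi = age_pattern.valid_interval
            if lo <= age <= hi:
                return age
            if audit is not None:
                audit.append(f"age: birth-year value {age} outside [{lo}, {hi}], rejected")
            return None
    return None


def extract_gender(
    letter: CleanLetter,
    female_terms: Sequence[str],
    male_terms: Sequence[str],
    max_distance: int = 1,
) -> str:
    """Majority vote of feminine vs masculine patient tokens.

    Each token is compared against the inflected forms of both the
    feminine ("Patientin", ...) and masculine ("Patient", ...) keyword;
    the strictly nearer side within the edit budget wins the token, ties
    are discarded — this keeps the feminine form from being subsumed by
    its masculine prefix and survives single typos. Zero tokens or a tied
    vote yield "unknown". Binary by design of the source letters.
    """
    fem = [KeywordSpec(t, max_distance=max_distance) for t in female_terms]
    mal = [KeywordSpec(t, max_distance=max_distance) for t in male_terms]
    n_female = n_male = 0
    for line in letter.lines:
        for token in tokenize(line):
            df = min((d for s in fem if (d := fuzzy_distance(token, s)) is not None),
                     default=None)
            dm = min((d for s in mal if (d := fuzzy_distance(token, s)) is not None),
                     default=None)
            if df is None and dm is None:
                continue
            if dm is None or (df is not None and df < dm):
                n_female += 1
            elif df is None or dm < df:
                n_male += 1
            # equal distances: ambiguous token, no vote
    if n_female > n_male:
        return "female"
    if n_male > n_female:
        return "male"
    return "unknown"


def extract_devices(letter: CleanLetter, device_section_spec: KeywordSpec) -> list[str]:
    """Comma-separated assistive devices from the device keyword's line(s)."""
    devices: list[str] = []
    for hit in search_lines(letter.lines, device_section_spec):
        text = hit.line_text
        if ":" in text:
            text = text.split(":", 1)[1]
        else:
            idx = text.casefold().find(hit.matched_token.casefold())
            if idx >= 0:
                text = text[idx + len(hit.matched_token):]
        for item in text.split(","):
            item = item.strip().rstrip(".")
            if item:
                devices.append(item)
    return devices


def extract_assessment(
    letter: CleanLetter,
    metric: MetricConfig,
    audit: list[str] | None = None,
) -> AssessmentResult:
    """Pair admission/discharge values of a metric by document order.

    All keyword hits are collected in line order; the first valid value is
    the admission value, the last valid value of a later hit the discharge
    value. Interval rejection happens before pairing, so an implausible
    first number does not shift the roles. Letters list their assessment
    blocks chronologically, which this convention relies on; explicit
    "bei Aufnahme"/"bei Entlassung" anchors override it when present.
    """
    anchored: dict[str, float] = {}
    valid: list[float] = []
    admission_anchor = KeywordSpec("Aufnahme", max_distance=1)
    discharge_anchor = KeywordSpec("Entlassung", max_distance=1)
    hits = search_lines(letter.lines, metric.keyword)
    for hit in hits:
        value = extract_number(hit.line_text, metric.pattern)
        if value is None:
            if audit is not None:
                audit.append(
                    f"{metric.name}: no valid value on keyword line {hit.line_index}: "
                    f"{hit.line_text!r}"
                )
            continue
        valid.append(value)
        for anchor, role in ((admission_anchor, "admission"), (discharge_anchor, "discharge")):
            if search_lines([hit.line_text], anchor) and role not in anchored:
                anchored[role] = value
    admission = anchored.get("admission", valid[0] if valid else None)
    discharge = anchored.get("discharge")
    if discharge is None and len(valid) >= 2:
        discharge = valid[-1]
    return AssessmentResult(
        name=metric.name,
        admission_value=admission,
        discharge_value=discharge,
        scale_min=metric.scale_min,
        scale_max=metric.scale_max,
        higher_is_better=metric.higher_is_better,
    )


def extract_allocation(
    letter: CleanLetter,
    allocation_specs: Mapping[str, Sequence[KeywordSpec]],
    cues: Sequence[KeywordSpec] = (),
    audit: list[str] | None = None,
) -> tuple[str, list[str]]:
    """Post-discharge allocation from recommendation-bearing lines.

    Lines hit by a recommendation cue ("empfehlen", "Entlassung", ...)
    are searched for each allocation category's keywords; without any cue
    line the whole letter is searched. A single category hit yields that
    label; multiple hits resolve by precedence (clinic > short-term care >
    rehabilitation > nursing home > home); none yields "unknown". All raw
    hits are returned for the audit trail.
    """
    candidate_lines: list[str] = []
    if cues:
        cue_idx: set[int] = set()
        for cue in cues:
            for hit in search_lines(letter.lines, cue):
                cue_idx.add(hit.line_index)
        candidate_lines = [letter.lines[i] for i in sorted(cue_idx)]
    if not candidate_lines:
        candidate_lines = list(letter.lines)
    raw_hits: list[str] = []
    hit_labels: set[str] = set()
    for label, specs in allocation_specs.items():
        for spec in specs:
            found = search_lines(candidate_lines, spec)
            if found:
                hit_labels.add(label)
                raw_hits.append(f"{label}:{spec.term}")
                if audit is not None:
                    h = found[0]
                    audit.append(
                        f"allocation={label} keyword={spec.term!r} "
                        f"matched={h.matched_token!r} distance={h.distance}"
                    )
                break
    for label in ALLOCATION_PRECEDENCE:
        if label in hit_labels:
            return label, raw_hits
    return "unknown", raw_hits


def extract_diagnoses(letter: CleanLetter, section_keyword: KeywordSpec) -> list[str]:
    """Diagnosis lines: the block following the diagnosis section header.

    Lines after the header are collected until a blank line or a new
    section header (a line ending with ':'); leading list dashes are
    stripped.
    """
    hits = search_lines(letter.lines, section_keyword)
    if not hits:
        return []
    diagnoses: list[str] = []
    start = hits[0].line_index + 1
    for line in letter.lines[start:]:
        stripped = line.strip()
        if not stripped or stripped.endswith(":"):
            break
        diagnoses.append(stripped.lstrip("-").strip())
    return diagnoses


def analyze_letter(
    letter: RawLetter,
    config: AnalyzerConfig,
    treatment_year: Optional[int] = None,
) -> PatientRecord:
    """Run the full per-letter pipeline and populate a PatientRecord.

    Order: deceased check (raw) -> age (raw) -> boilerplate cleaning ->
    assessments -> gender -> devices -> diagnoses -> categories ->
    allocation (skipped for deceased letters).
    """
    record = PatientRecord(letter_id=letter.letter_id)
    try:
        record.deceased = detect_deceased(letter, config.death_keywords)
        record.age = extract_age(
            letter, treatment_year, config.age_keyword, config.age_pattern, record.audit
        )
        clean = strip_boilerplate(letter, config.boilerplate_patterns)
        record.audit.append(f"cleaning: removed {clean.removed_line_count} lines")
        for metric in config.metrics:
            record.assessments.append(extract_assessment(clean, metric, record.audit))
        record.gender = extract_gender(
            clean, config.female_terms, config.male_terms, config.gender_max_distance
        )
        record.devices = extract_devices(clean, config.device_keyword)
        record.diagnoses = extract_diagnoses(clean, config.diagnosis_section_keyword)
        record.categories = assign_categories(
            record.diagnoses,
            config.categories,
            config.ambiguous_abbreviations,
            record.audit,
        )
        if not record.deceased:
            record.allocation, record.allocation_hits = extract_allocation(
                clean, config.allocation_keywords, config.allocation_cues, record.audit
            )
    except Exception as exc:  # per-field failures must never abort a letter
        record.audit.append(f"error: {type(exc).__name__}: {exc}")
    return record
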