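"""End-to-end corpus analysis and round-trip verification."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import AnalyzerConfig, default_config
from .corpus_io import LoadError, deduplicate, load_corpus
from .extraction import PatientRecord, analyze_letter
from .stats import CohortSummary, summarize

__all__ = [
    "AnalysisResult",
    "analyze_corpus",
    "records_to_dataframe",
    "compare_to_truth",
    "KEYWORD_DERIVED_FIELDS",
]

#: record fields recovered purely through (fuzzy) keyword search
KEYWORD_DERIVED_FIELDS = ("deceased", "gender", "devices", "categories", "allocation")

_VALUE_FIELDS = (
    "barthel_admission", "barthel_discharge",
    "tinetti_admission", "tinetti_discharge",
    "tug_admission", "tug_discharge",
)


@dataclass
class AnalysisResult:
    records: list[PatientRecord]
    summary: CohortSummary
    n_duplicates_removed: int
    load_errors: list[LoadError]


def analyze_corpus(
    input_dir: str | Path,
    config: Optional[AnalyzerConfig] = None,
    treatment_year: Optional[int] = None,
    encoding: str = "utf-8",
) -> AnalysisResult:
    """Load, deduplicate and analyze every letter in a directory."""
    cfg = config or default_config()
    letters, errors = load_corpus(input_dir, encoding=encoding)
    unique, n_removed = deduplicate(letters)
    records = [analyze_letter(letter, cfg, treatment_year) for letter in unique]
    return AnalysisResult(
        records=records,
        summary=summarize(records),
        n_duplicates_removed=n_removed,
        load_errors=errors,
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def record_row(record: PatientRecord) -> dict[str, str]:
    """Flat per-letter row (CSV schema) from a record."""
    row = {
        "letter_id": record.letter_id,
        "deceased": str(record.deceased),
        "age": _fmt(record.age),
        "gender": record.gender,
        "devices": ";".join(record.devices),
        "categories": ";".join(sorted(record.categories)),
        "allocation": record.allocation,
    }
    for name in ("barthel", "tinetti", "tug"):
        a = record.assessment(name)
        row[f"{name}_admission"] = _fmt(a.admission_value if a else None)
        row[f"{name}_discharge"] = _fmt(a.discharge_value if a else None)
    return row


def records_to_dataframe(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([record_row(r) for r in records])


def compare_to_truth(
    records: Sequence[PatientRecord],
    truth: pd.DataFrame,
    fields: Sequence[str] | None = None,
) -> tuple[dict[str, float], list[str]]:
    """Per-field agreement between extracted records and generator truth.

    Returns ({field: fraction correct}, list of mismatch descriptions).
    Every unique letter must be matched by letter_id.
    """
    fields = tuple(fields) if fields is not None else (
        ("age",) + KEYWORD_DERIVED_FIELDS + _VALUE_FIELDS
    )
    by_id = {r.letter_id: record_row(r) for r in records}
    correct = {f: 0 for f in fields}
    mismatches: list[str] = []
    n = 0
    for _, trow in truth.iterrows():
        letter_id = str(trow["letter_id"])
        n += 1
        got = by_id.get(letter_id)
        if got is None:
            mismatches.append(f"{letter_id}: letter missing from records")
            continue
        for f in fields:
            want = "" if pd.isna(trow[f]) else _fmt(trow[f])
            if got[f] == want:
                correct[f] += 1
            else:
                mismatches.append(f"{letter_id}.{f}: expected {want!r}, got {got[f]!r}")
    accuracy = {f: (correct[f] / n if n else 0.0) for f in fields}
    return accuracy, mismatches
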