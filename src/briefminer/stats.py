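"""Cohort-level quality-management statistics.

Aggregates per-letter records into the reporting surfaces used for
discharge-management review: demographics, diagnosis-category and cluster
frequencies, allocation breakdown, and relative assessment-improvement
distributions. All percentages are rounded half-up to one decimal
(commercial rounding, standard in German reporting).
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np

from .categorization import CATEGORY_NAMES, UNCATEGORIZED, cluster_key
from .config import ALLOCATION_LABELS
from .extraction import AssessmentResult, PatientRecord

__all__ = [
    "ImprovementRecord",
    "CohortSummary",
    "relative_improvement",
    "five_number",
    "summarize",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (28.45 -> 28.5)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(numerator: float, denominator: float) -> float:
    return round_half_up(100.0 * numerator / denominator, 1) if denominator else 0.0


@dataclass(frozen=True)
class ImprovementRecord:
    """Relative improvement of one metric for one letter (positive = better)."""

    letter_id: str
    metric: str
    relative_improvement: float


def relative_improvement(a: AssessmentResult) -> Optional[float]:
    """Signed fraction of the metric's scale gained during the stay.

    Bounded, higher-is-better scales (Barthel 0-100, Tinetti 0-28):
    (discharge - admission) / scale width. The timed up-and-go has no
    scale ceiling, so its improvement is expressed relative to the
    admission time: (admission - discharge) / admission — a 20 s -> 16 s
    run is a 20 % improvement. Missing inputs yield None.
    """
    if a.admission_value is None or a.discharge_value is None:
        return None
    if a.higher_is_better:
        width = a.scale_max - a.scale_min
        if width <= 0:
            return None
        return (a.discharge_value - a.admission_value) / width
    if a.admission_value == 0:
        return None
    return (a.admission_value - a.discharge_value) / a.admission_value


def five_number(values: Sequence[float]) -> Optional[tuple[float, float, float, float, float]]:
    """(min, Q1, median, Q3, max) — midpoint median, linear quartiles.

    Quartiles use linear interpolation between order statistics (numpy's
    default), under which the median of an even-length sample is the mean
    of the central pair.
    """
    if not values:
        return None
    q = np.quantile(np.asarray(values, dtype=float), [0.0, 0.25, 0.5, 0.75, 1.0],
                    method="linear")
    return tuple(float(x) for x in q)  # type: ignore[return-value]


@dataclass
class CohortSummary:
    n_letters: int
    n_female: int
    n_male: int
    n_unknown_gender: int
    n_deceased: int
    age_mean: Optional[float]
    age_sd: Optional[float]
    n_with_age: int
    category_share: dict[str, float]         # percent of category assignments
    category_letter_share: dict[str, float]  # percent of letters carrying the category
    cluster_share: dict[str, float]          # percent of letters, incl. uncategorized
    n_uncategorized: int
    allocation_share: dict[str, float]       # percent of letters with extractable allocation
    allocation_counts: dict[str, int]
    improvements: dict[str, dict]            # per metric: n, five-number, median percent

    def to_dict(self) -> dict:
        return {
            "n_letters": self.n_letters,
            "gender": {
                "female": self.n_female,
                "male": self.n_male,
                "unknown": self.n_unknown_gender,
            },
            "n_deceased": self.n_deceased,
            "age": {"mean": self.age_mean, "sd": self.age_sd, "n": self.n_with_age},
            "category_share_percent": self.category_share,
            "category_letter_share_percent": self.category_letter_share,
            "cluster_share_percent": self.cluster_share,
            "n_uncategorized": self.n_uncategorized,
            "allocation_share_percent": self.allocation_share,
            "allocation_counts": self.allocation_counts,
            "improvements": self.improvements,
        }


def improvement_records(records: Iterable[PatientRecord]) -> list[ImprovementRecord]:
    out: list[ImprovementRecord] = []
    for rec in records:
        for a in rec.assessments:
            ri = relative_improvement(a)
            if ri is not None:
                out.append(ImprovementRecord(rec.letter_id, a.name, ri))
    return out


def summarize(records: Sequence[PatientRecord]) -> CohortSummary:
    """Aggregate deduplicated records into a cohort summary.

    Deceased letters are excluded from the allocation denominator (as are
    letters without an extractable allocation, so the five shares sum to
    100). Category shares come in two denominators: share of all category
    assignments and share of letters (multi-assignment makes the latter
    sum to more than 100).
    """
    n = len(records)
    if n == 0:
        warnings.warn("summarize() called with no records", stacklevel=2)
    n_female = sum(r.gender == "female" for r in records)
    n_male = sum(r.gender == "male" for r in records)
    ages = [r.age for r in records if r.age is not None]
    age_mean = statistics.mean(ages) if ages else None
    age_sd = statistics.stdev(ages) if len(ages) > 1 else None

    cat_counts = {name: sum(name in r.categories for r in records) for name in CATEGORY_NAMES}
    # include any non-default category names present in the records
    for r in records:
        for c in r.categories:
            if c not in cat_counts:
                cat_counts[c] = sum(c in rec.categories for rec in records)
    n_assignments = sum(cat_counts.values())
    category_share = {c: _pct(k, n_assignments) for c, k in cat_counts.items()}
    category_letter_share = {c: _pct(k, n) for c, k in cat_counts.items()}

    cluster_counts: dict[str, int] = {}
    for r in records:
        key = cluster_key(r.categories)
        cluster_counts[key] = cluster_counts.get(key, 0) + 1
    cluster_share = {k: _pct(v, n) for k, v in sorted(cluster_counts.items())}
    n_uncategorized = cluster_counts.get(UNCATEGORIZED, 0)

    allocated = [r for r in records if not r.deceased and r.allocation != "unknown"]
    allocation_counts = {
        label: sum(r.allocation == label for r in allocated) for label in ALLOCATION_LABELS
    }
    allocation_share = {
        label: _pct(k, len(allocated)) for label, k in allocation_counts.items()
    }

    improvements: dict[str, dict] = {}
    by_metric: dict[str, list[float]] = {}
    for imp in improvement_records(records):
        by_metric.setdefault(imp.metric, []).append(imp.relative_improvement)
    for metric, values in sorted(by_metric.items()):
        fn = five_number(values)
        assert fn is not None
        improvements[metric] = {
            "n": len(values),
            "min": fn[0],
            "q1": fn[1],
            "median": fn[2],
            "q3": fn[3],
            "max": fn[4],
            "median_percent": round_half_up(100.0 * fn[2], 1),
        }

    return CohortSummary(
        n_letters=n,
        n_female=n_female,
        n_male=n_male,
        n_unknown_gender=n - n_female - n_male,
        n_deceased=sum(r.deceased for r in records),
        age_mean=age_mean,
        age_sd=age_sd,
        n_with_age=len(ages),
        category_share=category_share,
        category_letter_share=category_letter_share,
        cluster_share=cluster_share,
        n_uncategorized=n_uncategorized,
        allocation_share=allocation_share,
        allocation_counts=allocation_counts,
        improvements=improvements,
    )
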