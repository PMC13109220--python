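"""Diagnosis-category assignment via keyword/subword lists.

Each of the five indication categories (fall-related/alterstraumatological,
stroke, decompensated heart failure, neurodegenerative with escalation,
multifactorial frailty) carries a list of full keywords (fuzzy-matched at
token level) and subwords (exact case-insensitive substrings — no fuzz, to
control false positives). A letter's diagnoses may realize several
categories; the set of assigned categories forms its cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .matching import KeywordSpec, normalize_text, search_lines

__all__ = [
    "CategoryDef",
    "CATEGORY_NAMES",
    "UNCATEGORIZED",
    "assign_categories",
    "cluster_key",
]

CATEGORY_NAMES = ("sturz", "schlaganfall", "kardial", "neurodegenerativ", "multifaktor")

#: reserved cluster key for letters matching no category
UNCATEGORIZED = "uncategorized"


@dataclass(frozen=True)
class CategoryDef:
    """A diagnosis category with its keyword and subword lists."""

    name: str
    keywords: tuple[KeywordSpec, ...] = ()
    subwords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.keywords and not self.subwords:
            raise ValueError(f"category {self.name!r} needs keywords or subwords")


def _subword_in(line: str, subword: str) -> bool:
    return normalize_text(subword).casefold() in normalize_text(line).casefold()


def assign_categories(
    diagnoses: Sequence[str],
    defs: Sequence[CategoryDef],
    ambiguous_abbreviations: Iterable[str] = (),
    audit: list[str] | None = None,
) -> set[str]:
    """Category names whose keywords/subwords occur in any diagnosis line.

    Multiple categories are allowed; the empty set means uncategorized.
    Assignment is monotone in the term lists: adding a term can only add
    assignments. Known-ambiguous abbreviations (e.g. "HWI") are never
    matched but flagged in the audit trail when seen.
    """
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("category names must be unique")
    assigned: set[str] = set()
    for cdef in defs:
        for spec in cdef.keywords:
            hits = search_lines(diagnoses, spec)
            if hits:
                if audit is not None:
                    h = hits[0]
                    audit.append(
                        f"category={cdef.name} keyword={spec.term!r} "
                        f"matched={h.matched_token!r} distance={h.distance}"
                    )
                assigned.add(cdef.name)
                break
        if cdef.name in assigned:
            continue
        for sub in cdef.subwords:
            if any(_subword_in(line, sub) for line in diagnoses):
                if audit is not None:
                    audit.append(f"category={cdef.name} subword={sub!r} matched")
                assigned.add(cdef.name)
                break
    if audit is not None:
        for abbr in ambiguous_abbreviations:
            for line in diagnoses:
                if any(tok == abbr for tok in line.split()):
                    audit.append(f"ambiguous-abbreviation={abbr!r} in {line!r} (not matched)")
    return assigned


def cluster_key(categories: Iterable[str]) -> str:
    """Canonical cluster label: sorted '+'-joined names, or the reserved key.

    Equal sets always map to the same key regardless of iteration order.
    """
    cats = sorted(set(categories))
    return "+".join(cats) if cats else UNCATEGORIZED
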