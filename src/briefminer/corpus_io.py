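"""Corpus loading, boilerplate removal and deduplication."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .matching import KeywordSpec, normalize_text, search_lines

__all__ = [
    "RawLetter",
    "CleanLetter",
    "LoadError",
    "load_corpus",
    "strip_boilerplate",
    "deduplicate",
]

import re

_PAGE_MARKER = re.compile(r"Seite\s+\d+(\s+von\s+\d+)?", re.IGNORECASE)


@dataclass(frozen=True)
class RawLetter:
    """A letter as an ordered list of text lines, before cleaning."""

    letter_id: str
    lines: tuple[str, ...]
    n_pages: int | None = None

    def text(self) -> str:
        return "\n".join(self.lines)


@dataclass(frozen=True)
class CleanLetter:
    """A letter after header/footer removal.

    ``lines`` is always a subsequence of the raw letter's lines.
    """

    letter_id: str
    lines: tuple[str, ...]
    removed_line_count: int


@dataclass(frozen=True)
class LoadError:
    path: str
    reason: str


def load_corpus(
    directory: str | Path,
    encoding: str = "utf-8",
    pattern: str = "*.txt",
) -> tuple[list[RawLetter], list[LoadError]]:
    """Load one letter per text file, in stable lexicographic name order.

    Unreadable files are recorded as :class:`LoadError` entries and the
    load continues; an empty directory yields an empty list with a warning.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"corpus directory does not exist: {directory}")
    letters: list[RawLetter] = []
    errors: list[LoadError] = []
    files = sorted(directory.glob(pattern), key=lambda p: p.name)
    for path in files:
        try:
            text = normalize_text(path.read_text(encoding=encoding))
        except (UnicodeDecodeError, OSError) as exc:
            errors.append(LoadError(str(path), f"{type(exc).__name__}: {exc}"))
            continue
        letters.append(RawLetter(letter_id=path.stem, lines=tuple(text.split("\n"))))
    if not files:
        warnings.warn(f"no files matching {pattern!r} in {directory}", stacklevel=2)
    return letters, errors


def strip_boilerplate(
    letter: RawLetter, boilerplate_patterns: Sequence[KeywordSpec]
) -> CleanLetter:
    """Remove header/footer lines (letterhead phrases, page markers).

    A line is dropped when any configured pattern hits it, or — as a
    heuristic for multi-page letters sharing a letterhead — when at least
    two page markers exist and the identical line repeats verbatim (a
    single-page letter may legitimately repeat a line, e.g. an unchanged
    assessment value). Line order is never changed.
    """
    drop: set[int] = set()
    for spec in boilerplate_patterns:
        for hit in search_lines(letter.lines, spec):
            drop.add(hit.line_index)
    n_markers = sum(bool(_PAGE_MARKER.search(line)) for line in letter.lines)
    if n_markers >= 2:
        seen: dict[str, int] = {}
        for idx, line in enumerate(letter.lines):
            key = " ".join(line.split())
            if not key:
                continue
            if key in seen:
                drop.add(seen[key])
                drop.add(idx)
            else:
                seen[key] = idx
    kept = tuple(l for i, l in enumerate(letter.lines) if i not in drop)
    return CleanLetter(
        letter_id=letter.letter_id,
        lines=kept,
        removed_line_count=len(letter.lines) - len(kept),
    )


def _content_key(letter: RawLetter) -> str:
    return " ".join(letter.text().split())


def deduplicate(letters: Iterable[RawLetter]) -> tuple[list[RawLetter], int]:
    """Drop letters whose whitespace-normalized text repeats an earlier one.

    First occurrence wins; returns the unique letters in input order and
    the number removed. Exact content matching keeps counts reproducible.
    """
    seen: set[str] = set()
    unique: list[RawLetter] = []
    n_in = 0
    for letter in letters:
        n_in += 1
        key = _content_key(letter)
        if key in seen:
            continue
        seen.add(key)
        unique.append(letter)
    return unique, n_in - len(unique)
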