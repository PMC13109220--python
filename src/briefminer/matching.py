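"""Fuzzy keyword search and validated numeric extraction.

These are the two kernel operations of the analyzer: every line of a
discharge letter is scanned for keywords under a Levenshtein edit-distance
budget (to tolerate typing errors in clinical free text), and numeric
values are pulled out of keyword-bearing lines with anchored patterns that
carry a per-metric validity interval, so implausible numbers are rejected
at the source.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

__all__ = [
    "KeywordSpec",
    "NumberPattern",
    "LineHit",
    "default_max_distance",
    "levenshtein",
    "fuzzy_equal",
    "search_lines",
    "extract_number",
    "normalize_text",
    "tokenize",
]

#: characters stripped from token edges (sentence punctuation, brackets);
#: internal hyphens and slashes are kept so "Barthel-Index" stays one token.
_EDGE_PUNCT = ".,;:!?()[]{}\"'«»„“”‚‘’"

_WORD_END = r"(?![0-9A-Za-zÄÖÜäöüß])"


def normalize_text(text: str) -> str:
    """NFKC-normalize and clean common PDF-extraction artifacts.

    Ligatures are decomposed and non-breaking/narrow spaces become plain
    spaces so that German umlaut text survives matching unchanged.
    """
    text = unicodedata.normalize("NFKC", text)
    return text.replace(" ", " ").replace(" ", " ").replace("‑", "-")


def tokenize(line: str) -> list[str]:
    """Whitespace tokens with edge punctuation stripped."""
    tokens = []
    for raw in line.split():
        tok = raw.strip(_EDGE_PUNCT)
        if tok:
            tokens.append(tok)
    return tokens


def default_max_distance(term: str) -> int:
    """Length-scaled edit budget: 1 for short terms, 2 mid, 3 for long.

    A fixed absolute budget over-matches short words ("Sturz" at distance 2
    would swallow half the lexicon), hence the scaling.
    """
    n = len(term)
    if n <= 6:
        return 1
    if n <= 12:
        return 2
    return 3


@dataclass(frozen=True)
class KeywordSpec:
    """A fuzzy-searchable term with an edit-distance budget."""

    term: str
    max_distance: Optional[int] = None
    whole_word: bool = True
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        term = self.term.strip()
        if not term:
            raise ValueError("KeywordSpec.term must be non-empty")
        object.__setattr__(self, "term", term)
        d = self.max_distance
        if d is None:
            d = default_max_distance(term)
        if not 0 <= d < len(term):
            raise ValueError(
                f"max_distance must satisfy 0 <= d < len(term); got {d} for {term!r}"
            )
        object.__setattr__(self, "max_distance", d)

    def normalized_term(self) -> str:
        t = normalize_text(self.term)
        return t if self.case_sensitive else t.casefold()


@dataclass(frozen=True)
class NumberPattern:
    """Numeric extraction pattern with a validity interval.

    ``pattern`` is a template in which the placeholder ``xx`` marks the one
    numeric capture, e.g. ``"xx/100"``, ``"xx Jahre"``, ``"xx s"``. Values
    outside ``valid_interval`` (inclusive) are rejected as transcription
    errors.
    """

    name: str
    pattern: str
    valid_interval: tuple[float, float]
    units: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.valid_interval
        if lo > hi:
            raise ValueError(f"{self.name}: interval min {lo} > max {hi}")
        if self.pattern.count("xx") != 1:
            raise ValueError(
                f"{self.name}: pattern must contain exactly one 'xx' capture, "
                f"got {self.pattern!r}"
            )


@dataclass(frozen=True)
class LineHit:
    """One keyword hit: the line, the matched token and its edit distance."""

    line_index: int
    line_text: str
    matched_token: str
    distance: int


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character edits transforming ``a`` into ``b``.

    Plain Wagner-Fischer two-row dynamic programme; quadratic in the string
    lengths, which is fine for the word/fragment comparisons done here.
    """
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@lru_cache(maxsize=1 << 18)
def _cached_distance(a: str, b: str) -> int:
    # token vocabularies repeat heavily across letters from one clinic,
    # so memoisation removes nearly all DP work on a corpus run
    return levenshtein(a, b)


def fuzzy_equal(word: str, spec: KeywordSpec) -> bool:
    """True iff ``word`` is within the spec's edit budget of its term."""
    return fuzzy_distance(word, spec) is not None


def fuzzy_distance(word: str, spec: KeywordSpec) -> Optional[int]:
    """Edit distance if within budget, else None."""
    w = normalize_text(word)
    if not spec.case_sensitive:
        w = w.casefold()
    t = spec.normalized_term()
    if w == t:
        return 0
    if abs(len(w) - len(t)) > spec.max_distance:
        return None
    d = _cached_distance(w, t)
    return d if d <= spec.max_distance else None


def _window_hits(tokens: list[str], spec: KeywordSpec) -> Optional[tuple[str, int]]:
    """Best (fragment, distance) over token windows matching a spec.

    Single-word terms compare token by token; multi-word terms compare a
    sliding window of the same token count (fragments, joined by a space).
    """
    n_words = len(spec.term.split())
    best: Optional[tuple[str, int]] = None
    if n_words == 1:
        candidates = tokens
    else:
        candidates = [
            " ".join(tokens[i : i + n_words])
            for i in range(len(tokens) - n_words + 1)
        ]
    for cand in candidates:
        d = fuzzy_distance(cand, spec)
        if d is not None and (best is None or d < best[1]):
            best = (cand, d)
            if d == 0:
                break
    return best


def _substring_hit(line: str, spec: KeywordSpec) -> Optional[tuple[str, int]]:
    """Character-window scan for whole_word=False specs."""
    text = normalize_text(line)
    if not spec.case_sensitive:
        text = text.casefold()
    t = spec.normalized_term()
    if t in text:
        return (spec.term, 0)
    best: Optional[tuple[str, int]] = None
    for width in range(max(1, len(t) - spec.max_distance), len(t) + spec.max_distance + 1):
        for i in range(0, len(text) - width + 1):
            window = text[i : i + width]
            d = _cached_distance(window, t)
            if d <= spec.max_distance and (best is None or d < best[1]):
                best = (window, d)
    return best


def search_lines(lines, spec: KeywordSpec) -> list[LineHit]:
    """All lines containing a token (or window) fuzzy-equal to the term.

    Accepts any iterable of lines (``CleanLetter.lines``, ``RawLetter.lines``
    or a plain list of strings). All matching lines are returned in line
    order, one hit per line with the best-matching token.
    """
    hits: list[LineHit] = []
    for idx, line in enumerate(lines):
        if spec.whole_word:
            found = _window_hits(tokenize(line), spec)
        else:
            found = _substring_hit(line, spec)
        if found is not None:
            hits.append(LineHit(idx, line, found[0], found[1]))
    return hits


_NUM_GROUP = r"(?<![\d,.])(\d+(?:,\d+)?)"


@lru_cache(maxsize=256)
def _compile_pattern(template: str) -> re.Pattern[str]:
    head, tail = template.split("xx")
    parts = []
    for piece in (head, tail):
        esc = re.escape(piece).replace(r"\ ", r"\s*").replace(" ", r"\s*")
        parts.append(esc)
    regex = parts[0] + _NUM_GROUP + parts[1]
    if template and template[-1].isalnum():
        regex += _WORD_END
    return re.compile(regex)


def extract_number(line: str, pattern: NumberPattern) -> Optional[float]:
    """First occurrence of the pattern on the line, interval-validated.

    German decimal commas are converted ("18,5" -> 18.5). A value outside
    the validity interval is rejected and yields ``None`` — missing is a
    value here, not an error.
    """
    m = _compile_pattern(pattern.pattern).search(normalize_text(line))
    if m is None:
        return None
    value = float(m.group(1).replace(",", "."))
    lo, hi = pattern.valid_interval
    if not lo <= value <= hi:
        return None
    return value
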