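"""Analyzer configuration: keyword lists, numeric patterns, categories.

Everything the extraction pipeline matches against lives here and is
overridable from a YAML/JSON file without code changes — the tool runs
inside restricted hospital environments where file-driven configuration
is the only practical customisation channel.

The shipped defaults target semi-structured German geriatric discharge
letters. The diagnosis-category term lists are a documented, configurable
default — not a claim about any particular clinic's lists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .categorization import CategoryDef
from .matching import KeywordSpec, NumberPattern

__all__ = [
    "MetricConfig",
    "AnalyzerConfig",
    "ConfigError",
    "default_config",
    "load_config",
    "ALLOCATION_LABELS",
    "ALLOCATION_PRECEDENCE",
]

#: post-discharge allocation labels (plus "unknown" for no/ambiguous hit)
ALLOCATION_LABELS = ("home", "clinic", "rehabilitation", "nursing_home", "short_term_care")

#: multi-hit letters resolve by this precedence (most care-intensive first)
ALLOCATION_PRECEDENCE = ("clinic", "short_term_care", "rehabilitation", "nursing_home", "home")


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


@dataclass(frozen=True)
class MetricConfig:
    """One assessment metric: its keyword, pattern, scale and direction."""

    name: str
    keyword: KeywordSpec
    pattern: NumberPattern
    scale_min: float
    scale_max: float
    higher_is_better: bool


@dataclass(frozen=True)
class AnalyzerConfig:
    metrics: tuple[MetricConfig, ...]
    death_keywords: tuple[KeywordSpec, ...]
    female_terms: tuple[str, ...]
    male_terms: tuple[str, ...]
    gender_max_distance: int
    device_keyword: KeywordSpec
    diagnosis_section_keyword: KeywordSpec
    age_keyword: KeywordSpec
    age_pattern: NumberPattern
    boilerplate_patterns: tuple[KeywordSpec, ...]
    allocation_cues: tuple[KeywordSpec, ...]
    allocation_keywords: Mapping[str, tuple[KeywordSpec, ...]]
    categories: tuple[CategoryDef, ...]
    ambiguous_abbreviations: tuple[str, ...] = ("HWI",)

    def metric(self, name: str) -> MetricConfig:
        for m in self.metrics:
            if m.name == name:
                return m
        raise KeyError(name)


def default_config() -> AnalyzerConfig:
    """The shipped defaults for German geriatric discharge letters."""
    metrics = (
        MetricConfig(
            name="barthel",
            keyword=KeywordSpec("Barthel-Index"),
            pattern=NumberPattern("barthel", "xx/100", (0, 100), units="points"),
            scale_min=0,
            scale_max=100,
            higher_is_better=True,
        ),
        MetricConfig(
            name="tinetti",
            keyword=KeywordSpec("Tinetti-Test"),
            pattern=NumberPattern("tinetti", "xx/28", (0, 28), units="points"),
            scale_min=0,
            scale_max=28,
            higher_is_better=True,
        ),
        MetricConfig(
            name="tug",
            keyword=KeywordSpec("Timed up and go"),
            pattern=NumberPattern("tug", "xx s", (3, 300), units="seconds"),
            scale_min=3,
            scale_max=300,
            higher_is_better=False,
        ),
    )
    allocation_keywords = {
        "home": (KeywordSpec("Häuslichkeit"), KeywordSpec("nach Hause", max_distance=2)),
        "clinic": (KeywordSpec("Klinik"),),
        "rehabilitation": (KeywordSpec("Rehabilitation"),),
        "nursing_home": (KeywordSpec("Seniorenheim"), KeywordSpec("Pflegeheim")),
        "short_term_care": (KeywordSpec("Kurzzeitpflege"),),
    }
    categories = (
        CategoryDef(
            "sturz",
            keywords=(KeywordSpec("Sturz"), KeywordSpec("Fraktur")),
            subwords=("sturz", "fraktur", "alterstraumatolog"),
        ),
        CategoryDef(
            "schlaganfall",
            keywords=(
                KeywordSpec("Schlaganfall"),
                KeywordSpec("Apoplex"),
                KeywordSpec("Insult"),
                KeywordSpec("Hemiparese"),
            ),
            subwords=("schlaganfall", "apoplex", "hemiparese"),
        ),
        CategoryDef(
            "kardial",
            keywords=(KeywordSpec("Herzinsuffizienz"), KeywordSpec("kardial")),
            subwords=("herzinsuffizienz", "kardial", "dekompensiert"),
        ),
        CategoryDef(
            "neurodegenerativ",
            keywords=(
                KeywordSpec("Demenz"),
                KeywordSpec("Parkinson"),
                KeywordSpec("Delir"),
            ),
            subwords=("demenz", "parkinson", "neurodegenerativ", "delir"),
        ),
        CategoryDef(
            "multifaktor",
            keywords=(
                KeywordSpec("Gebrechlichkeit"),
                KeywordSpec("Frailty"),
                KeywordSpec("Sarkopenie"),
            ),
            subwords=("gebrechlichkeit", "frailty", "multifaktoriell", "sarkopenie"),
        ),
    )
    return AnalyzerConfig(
        metrics=metrics,
        death_keywords=(KeywordSpec("verstorben"), KeywordSpec("verstarb")),
        female_terms=("Patientin", "Patientinnen"),
        male_terms=("Patient", "Patienten"),
        gender_max_distance=1,
        device_keyword=KeywordSpec("Hilfsmittel"),
        diagnosis_section_keyword=KeywordSpec("Diagnosen"),
        age_keyword=KeywordSpec("Alter"),
        age_pattern=NumberPattern("age", "xx Jahre", (40, 115), units="years"),
        boilerplate_patterns=(
            KeywordSpec("St. Aurelius Hospital", max_distance=3),
            KeywordSpec("Seite", max_distance=0),
            KeywordSpec("Telefon", max_distance=1),
            KeywordSpec("Telefax", max_distance=1),
        ),
        allocation_cues=(
            KeywordSpec("Empfehlung"),
            KeywordSpec("empfehlen"),
            KeywordSpec("Entlassung"),
            KeywordSpec("entlassen"),
            KeywordSpec("Verlegung"),
            KeywordSpec("verlegt"),
        ),
        allocation_keywords=allocation_keywords,
        categories=categories,
    )


# ---------------------------------------------------------------------------
# YAML/JSON config files (layered over the defaults)

def _keyword_from(obj: Any, where: str) -> KeywordSpec:
    if isinstance(obj, str):
        return KeywordSpec(obj)
    if isinstance(obj, Mapping):
        unknown = set(obj) - {"term", "max_distance", "whole_word", "case_sensitive"}
        if unknown:
            raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
        try:
            return KeywordSpec(**obj)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{where}: {exc}") from exc
    raise ConfigError(f"{where}: expected string or mapping, got {type(obj).__name__}")


def _keywords_from(obj: Any, where: str) -> tuple[KeywordSpec, ...]:
    if not isinstance(obj, list):
        raise ConfigError(f"{where}: expected a list")
    return tuple(_keyword_from(item, f"{where}[{i}]") for i, item in enumerate(obj))


def _metric_from(name: str, obj: Any) -> MetricConfig:
    where = f"metrics.{name}"
    if not isinstance(obj, Mapping):
        raise ConfigError(f"{where}: expected a mapping")
    required = {"keyword", "pattern", "interval", "scale", "higher_is_better"}
    missing = required - set(obj)
    if missing:
        raise ConfigError(f"{where}: missing required keys {sorted(missing)}")
    interval = obj["interval"]
    scale = obj["scale"]
    for key, val in (("interval", interval), ("scale", scale)):
        if not (isinstance(val, (list, tuple)) and len(val) == 2):
            raise ConfigError(f"{where}.{key}: expected [min, max]")
    try:
        pattern = NumberPattern(name, obj["pattern"], (float(interval[0]), float(interval[1])),
                                units=str(obj.get("units", "")))
    except ValueError as exc:
        raise ConfigError(f"{where}.pattern: {exc}") from exc
    return MetricConfig(
        name=name,
        keyword=_keyword_from(obj["keyword"], f"{where}.keyword"),
        pattern=pattern,
        scale_min=float(scale[0]),
        scale_max=float(scale[1]),
        higher_is_better=bool(obj["higher_is_better"]),
    )


_TOP_LEVEL_KEYS = {
    "metrics", "death_keywords", "female_terms", "male_terms", "gender_max_distance",
    "device_keyword", "diagnosis_section_keyword", "age_keyword", "age_pattern",
    "age_interval", "boilerplate_patterns", "allocation_cues", "allocation_keywords",
    "categories", "ambiguous_abbreviations",
}


def load_config(path: str | Path, base: AnalyzerConfig | None = None) -> AnalyzerConfig:
    """Load a YAML/JSON config file layered over ``base`` (the defaults).

    Only the keys present in the file are overridden. Schema violations
    raise :class:`ConfigError` naming the offending keys.
    """
    base = base or default_config()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return base
    if not isinstance(raw, Mapping):
        raise ConfigError("config file must contain a mapping at top level")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    updates: dict[str, Any] = {}
    if "metrics" in raw:
        if not isinstance(raw["metrics"], Mapping):
            raise ConfigError("metrics: expected a mapping of metric name -> spec")
        updates["metrics"] = tuple(
            _metric_from(name, spec) for name, spec in raw["metrics"].items()
        )
    for key in ("death_keywords", "boilerplate_patterns", "allocation_cues"):
        if key in raw:
            updates[key] = _keywords_from(raw[key], key)
    for key in ("female_terms", "male_terms", "ambiguous_abbreviations"):
        if key in raw:
            if not isinstance(raw[key], list):
                raise ConfigError(f"{key}: expected a list of strings")
            updates[key] = tuple(str(t) for t in raw[key])
    if "gender_max_distance" in raw:
        updates["gender_max_distance"] = int(raw["gender_max_distance"])
    for key in ("device_keyword", "diagnosis_section_keyword", "age_keyword"):
        if key in raw:
            updates[key] = _keyword_from(raw[key], key)
    if "age_pattern" in raw or "age_interval" in raw:
        pat = raw.get("age_pattern", base.age_pattern.pattern)
        iv = raw.get("age_interval", list(base.age_pattern.valid_interval))
        if not (isinstance(iv, (list, tuple)) and len(iv) == 2):
            raise ConfigError("age_interval: expected [min, max]")
        updates["age_pattern"] = NumberPattern("age", pat, (float(iv[0]), float(iv[1])),
                                               units="years")
    if "allocation_keywords" in raw:
        obj = raw["allocation_keywords"]
        if not isinstance(obj, Mapping):
            raise ConfigError("allocation_keywords: expected a mapping")
        unknown = set(obj) - set(ALLOCATION_LABELS)
        if unknown:
            raise ConfigError(f"allocation_keywords: unknown labels {sorted(unknown)}")
        merged = dict(base.allocation_keywords)
        for label, terms in obj.items():
            merged[label] = _keywords_from(terms, f"allocation_keywords.{label}")
        updates["allocation_keywords"] = merged
    if "categories" in raw:
        obj = raw["categories"]
        if not isinstance(obj, Mapping):
            raise ConfigError("categories: expected a mapping of category -> lists")
        defs = []
        for name, spec in obj.items():
            if not isinstance(spec, Mapping) or set(spec) - {"keywords", "subwords"}:
                raise ConfigError(
                    f"categories.{name}: expected keys 'keywords' and/or 'subwords'"
                )
            try:
                defs.append(
                    CategoryDef(
                        str(name),
                        keywords=_keywords_from(spec.get("keywords", []),
                                                f"categories.{name}.keywords"),
                        subwords=tuple(str(s) for s in spec.get("subwords", [])),
                    )
                )
            except ValueError as exc:
                raise ConfigError(f"categories.{name}: {exc}") from exc
        updates["categories"] = tuple(defs)
    return replace(base, **updates)
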