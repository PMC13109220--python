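"""Per-letter field extraction and pipeline order."""

import pytest

from briefminer.config import default_config
from briefminer.corpus_io import CleanLetter, RawLetter
from briefminer.extraction import (
    analyze_letter,
    detect_deceased,
    extract_age,
    extract_allocation,
    extract_assessment,
    extract_devices,
    extract_gender,
    extract_diagnoses,
)
from briefminer.matching import KeywordSpec


def clean(*lines):
    return CleanLetter("test", tuple(lines), removed_line_count=0)


def raw(*lines):
    return RawLetter("test", tuple(lines))


CFG = default_config()


class TestDeceased:
    def test_keyword_present(self):
        letter = raw("Die Patientin ist am 03.04. verstorben")
        assert detect_deceased(letter, CFG.death_keywords)

    def test_keyword_absent(self):
        assert not detect_deceased(raw("Entlassung in die Häuslichkeit"),
                                   CFG.death_keywords)

    def test_misspelling_within_budget(self):
        assert detect_deceased(raw("Der Patient ist leider verstorbn."),
                               CFG.death_keywords)


class TestAge:
    def _age(self, letter, year=None):
        return extract_age(letter, year, CFG.age_keyword, CFG.age_pattern)

    def test_direct_statement(self):
        assert self._age(raw("Alter: 87 Jahre")) == 87

    def test_birth_year_arithmetic(self):
        assert self._age(raw("* 01.02.1940"), 2024) == 84

    def test_implausible_birth_year_rejected(self):
        assert self._age(raw("* 01.02.1640"), 2024) is None

    def test_treatment_year_taken_from_letter_date(self):
        letter = raw("Bielefeld, den 15.03.2024", "M. Muster, geb. * 01.02.1940")
        assert self._age(letter) == 84

    def test_direct_statement_wins_over_birth_date(self):
        letter = raw("* 01.02.1940", "Alter: 83 Jahre")
        assert self._age(letter, 2024) == 83

    def test_no_strategy_available(self):
        assert self._age(raw("kein Altershinweis")) is None


class TestGender:
    def _gender(self, *lines):
        return extract_gender(clean(*lines), CFG.female_terms, CFG.male_terms,
                              CFG.gender_max_distance)

    def test_feminine_tokens_only(self):
        assert self._gender("die Patientin wurde aufgenommen",
                            "Die Patientin war mobil") == "female"

    def test_masculine_tokens_only(self):
        assert self._gender("der Patient wurde aufgenommen",
                            "des Patienten Befund") == "male"

    def test_no_tokens(self):
        assert self._gender("keine Erwähnung") == "unknown"

    def test_feminine_not_subsumed_by_masculine_prefix(self):
        # "Patientin" contains "Patient" as prefix but must count female
        assert self._gender("die Patientin") == "female"

    def test_majority_wins(self):
        assert self._gender("die Patientin", "die Patientin", "der Patient") == "female"


class TestDevices:
    def test_comma_separated_list(self):
        letter = clean("Hilfsmittel: Rollator, Gehstützen")
        assert extract_devices(letter, CFG.device_keyword) == ["Rollator", "Gehstützen"]

    def test_single_item(self):
        assert extract_devices(clean("Hilfsmittel: Rollator"),
                               CFG.device_keyword) == ["Rollator"]

    def test_no_device_line(self):
        assert extract_devices(clean("keine Zeile"), CFG.device_keyword) == []

    def test_empty_items_dropped(self):
        letter = clean("Hilfsmittel: Rollator, , Duschhocker.")
        assert extract_devices(letter, CFG.device_keyword) == ["Rollator", "Duschhocker"]


class TestAssessment:
    METRIC = CFG.metric("barthel")

    def test_document_order_pairing(self):
        letter = clean("Barthel-Index: 40/100", "Verlauf", "Barthel-Index: 80/100")
        a = extract_assessment(letter, self.METRIC)
        assert (a.admission_value, a.discharge_value) == (40, 80)

    def test_single_hit_is_admission_only(self):
        a = extract_assessment(clean("Tinetti-Test: 14/28"), CFG.metric("tinetti"))
        assert (a.admission_value, a.discharge_value) == (14, None)

    def test_interval_rejection_precedes_pairing(self):
        letter = clean("Barthel-Index: 450/100", "Barthel-Index: 80/100")
        a = extract_assessment(letter, self.METRIC)
        assert (a.admission_value, a.discharge_value) == (80, None)

    def test_no_hits_all_missing(self):
        a = extract_assessment(clean("nichts"), self.METRIC)
        assert (a.admission_value, a.discharge_value) == (None, None)

    def test_explicit_anchors_override_order(self):
        letter = clean("Barthel-Index bei Entlassung: 80/100",
                       "Barthel-Index bei Aufnahme: 40/100")
        a = extract_assessment(letter, self.METRIC)
        assert (a.admission_value, a.discharge_value) == (40, 80)


class TestAllocation:
    def _alloc(self, *lines):
        label, _ = extract_allocation(clean(*lines), CFG.allocation_keywords,
                                      CFG.allocation_cues)
        return label

    def test_home(self):
        assert self._alloc("Wir empfehlen die Entlassung in die Häuslichkeit.") == "home"

    def test_clinic(self):
        assert self._alloc("Verlegung in die Klinik für Kardiologie") == "clinic"

    def test_no_allocation_sentence(self):
        assert self._alloc("Der Verlauf war unauffällig.") == "unknown"

    def test_precedence_on_multiple_hits(self):
        label = self._alloc(
            "Wir empfehlen die Entlassung in die Häuslichkeit.",
            "Alternativ Verlegung in die Klinik für Geriatrie.",
        )
        assert label == "clinic"  # clinic outranks home

    def test_raw_hits_retained_for_audit(self):
        _, hits = extract_allocation(
            clean("Wir empfehlen die Entlassung in die Häuslichkeit."),
            CFG.allocation_keywords, CFG.allocation_cues)
        assert any(h.startswith("home:") for h in hits)


class TestDiagnosisSection:
    def test_block_after_header(self):
        letter = clean("Diagnosen:", "- Sturz mit Femurfraktur",
                       "- Demenz", "", "Hilfsmittel: Rollator")
        assert extract_diagnoses(letter, CFG.diagnosis_section_keyword) == [
            "Sturz mit Femurfraktur", "Demenz"]

    def test_no_header(self):
        assert extract_diagnoses(clean("keine Abschnitte"),
                                 CFG.diagnosis_section_keyword) == []


class TestAnalyzeLetter:
    def test_deceased_letter_has_no_allocation(self):
        letter = raw(
            "Bielefeld, den 15.03.2024",
            "M. Muster, geb. * 01.02.1940",
            "Die Patientin ist im Krankenhaus verstorben.",
            "Wir empfehlen die Entlassung in die Häuslichkeit.",
        )
        record = analyze_letter(letter, CFG)
        assert record.deceased
        assert record.allocation == "unknown"

    def test_empty_letter_yields_missing_values(self):
        record = analyze_letter(raw(""), CFG)
        assert record.age is None
        assert record.gender == "unknown"
        assert record.devices == []
        assert record.categories == set()
        assert record.allocation == "unknown"

    def test_age_survives_boilerplate_cleaning(self):
        """Pipeline order is observable: a birth date sitting only on a
        letterhead line that the cleaning step removes still yields an age,
        because age extraction runs on the raw letter."""
        letter = raw(
            "Bielefeld, den 15.03.2024",
            "St. Aurelius Hospital * 01.02.1940",
            "Die Patientin war mobil.",
        )
        record = analyze_letter(letter, CFG)
        assert record.age == 84
        # and the line is indeed stripped for the later stages
        from briefminer.corpus_io import strip_boilerplate
        assert len(strip_boilerplate(letter, CFG.boilerplate_patterns).lines) == 2

    def test_fully_populated_letter(self):
        letter = raw(
            "Bielefeld, den 15.03.2024",
            "F. Beispiel, geb. * 10.05.1938",
            "wir berichten über die Patientin, die bei uns behandelt wurde.",
            "",
            "Diagnosen:",
            "- Sturz mit pertrochantärer Femurfraktur",
            "",
            "Barthel-Index: 40/100",
            "Tinetti-Test: 14/28",
            "Timed up and go: 25 s",
            "",
            "Barthel-Index: 80/100",
            "Tinetti-Test: 21/28",
            "Timed up and go: 20 s",
            "",
            "Hilfsmittel: Rollator, Gehstützen",
            "Die Patientin zeigte sich mobil.",
            "Wir empfehlen die Entlassung in die Häuslichkeit.",
        )
        record = analyze_letter(letter, CFG)
        assert not record.deceased
        assert record.age == 86
        assert record.gender == "female"
        assert record.devices == ["Rollator", "Gehstützen"]
        assert record.categories == {"sturz"}
        assert record.allocation == "home"
        barthel = record.assessment("barthel")
        assert (barthel.admission_value, barthel.discharge_value) == (40, 80)
        tug = record.assessment("tug")
        assert (tug.admission_value, tug.discharge_value) == (25, 20)
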