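"""Synthetic corpus generator: determinism, preset arithmetic, typo injection."""

import dataclasses
import random
import statistics

import pytest

from briefminer.matching import levenshtein
from briefminer.stats import round_half_up
from briefminer.synthetic import (
    GeneratorConfig,
    _construct_ages,
    generate_corpus,
    inject_typos,
    paper_default,
    validate,
)


def small_config(**overrides):
    base = dict(
        n_files=8,
        n_exact_duplicates=2,
        n_female=4,
        n_male=2,
        deceased_count=1,
        allocation_counts={"home": 3, "clinic": 2},
        cluster_counts={("sturz",): 3, ("kardial", "multifaktor"): 2},
        uncategorized_count=1,
        seed=7,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


class TestValidation:
    def test_small_config_valid(self):
        validate(small_config())

    def test_duplicates_must_be_fewer_than_files(self):
        with pytest.raises(ValueError, match="n_exact_duplicates"):
            validate(small_config(n_exact_duplicates=8))

    def test_gender_counts_must_sum_to_unique(self):
        with pytest.raises(ValueError, match="gender counts"):
            validate(small_config(n_female=5))

    def test_allocation_counts_must_sum_to_alive(self):
        with pytest.raises(ValueError, match="allocation counts"):
            validate(small_config(allocation_counts={"home": 5, "clinic": 2}))

    def test_cluster_counts_must_cover_unique(self):
        with pytest.raises(ValueError, match="cluster counts"):
            validate(small_config(uncategorized_count=2))


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        generate_corpus(small_config(), d1)
        generate_corpus(small_config(), d2)
        files1 = sorted(p.name for p in d1.glob("*.txt"))
        assert files1 == sorted(p.name for p in d2.glob("*.txt"))
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_duplicates_are_byte_identical_copies(self, tmp_path):
        generate_corpus(small_config(), tmp_path)
        import pandas as pd
        dups = pd.read_csv(tmp_path / "duplicates.csv")
        assert len(dups) == 2
        for _, row in dups.iterrows():
            copy = (tmp_path / row["file"]).read_bytes()
            original = (tmp_path / f"{row['duplicate_of']}.txt").read_bytes()
            assert copy == original

    def test_count_constructed_statistics_are_seed_invariant(self, tmp_path):
        """A different seed permutes letters but leaves every count-based
        ground-truth statistic unchanged."""
        truth = generate_corpus(paper_default(seed=99), tmp_path / "other_seed")
        assert truth["gender"].value_counts().to_dict() == {"female": 274, "male": 98}
        assert round_half_up(truth["age"].mean(), 1) == 84.4
        alive = truth[~truth["deceased"]]
        assert alive["allocation"].value_counts().to_dict() == {
            "home": 151, "rehabilitation": 78, "clinic": 66,
            "short_term_care": 63, "nursing_home": 11,
        }


class TestPresetArithmetic:
    """The calibrated preset's counts round (half-up, one decimal) to the
    reference cohort percentages."""

    CFG = paper_default()

    def test_letter_counts(self):
        assert self.CFG.n_files == 393
        assert self.CFG.n_exact_duplicates == 21
        assert self.CFG.n_unique == 372

    def test_gender_counts(self):
        assert (self.CFG.n_female, self.CFG.n_male) == (274, 98)

    def test_allocation_shares(self):
        counts = self.CFG.allocation_counts
        denominator = sum(counts.values())
        assert denominator == 369  # unique letters minus the 3 deceased
        shares = {k: round_half_up(100 * v / denominator, 1) for k, v in counts.items()}
        assert shares == {"home": 40.9, "clinic": 17.9, "rehabilitation": 21.1,
                          "nursing_home": 3.0, "short_term_care": 17.1}

    def test_cluster_shares(self):
        counts = self.CFG.cluster_counts
        n = self.CFG.n_unique
        assert round_half_up(100 * counts[("multifaktor", "sturz")] / n, 1) == 28.5
        key3 = ("multifaktor", "neurodegenerativ", "sturz")
        assert round_half_up(100 * counts[key3] / n, 1) == 14.0
        assert round_half_up(100 * counts[("kardial", "multifaktor", "sturz")] / n, 1) == 12.9
        assert self.CFG.uncategorized_count == 3

    def test_category_marginals_within_band(self):
        """Per-category assignment shares approximate the reference
        marginals to within 0.3 percentage points."""
        marginals = {}
        for cats, count in self.CFG.cluster_counts.items():
            for cat in cats:
                marginals[cat] = marginals.get(cat, 0) + count
        total = sum(marginals.values())
        targets = {"multifaktor": 35.9, "sturz": 33.9, "neurodegenerativ": 13.4,
                   "kardial": 13.0, "schlaganfall": 3.9}
        for cat, target in targets.items():
            share = 100 * marginals[cat] / total
            assert abs(share - target) <= 0.3, (cat, share)

    def test_age_construction_hits_mean_and_sd_band(self):
        for seed in (1, 20240315):
            cfg = dataclasses.replace(self.CFG, seed=seed)
            ages = _construct_ages(cfg, random.Random(seed))
            assert round_half_up(statistics.mean(ages), 1) == 84.4
            assert 6.55 <= statistics.stdev(ages) < 6.65
            assert all(cfg.age_bounds[0] <= a <= cfg.age_bounds[1] for a in ages)


class TestInjectTypos:
    def test_rate_zero_is_identity(self):
        text = "Barthel-Index: 45/100\nHilfsmittel: Rollator"
        assert inject_typos(text, 0.0, seed=1) == text

    def test_rate_one_applies_exactly_one_edit_per_occurrence(self):
        text = "Barthel-Index: 45/100"
        edited = inject_typos(text, 1.0, seed=3, keywords=["Barthel-Index"])
        assert edited != text
        head, _, tail = edited.partition(":")
        assert levenshtein(head, "Barthel-Index") == 1
        assert tail == " 45/100"  # numbers are never edited

    def test_birth_date_line_never_edited(self):
        text = "Patientin M. Muster, geb. * 01.02.1940"
        assert inject_typos(text, 1.0, seed=5, keywords=["Patientin"]) == text

    def test_deterministic_given_seed(self):
        text = "Hilfsmittel: Rollator, Gehstützen\nTinetti-Test: 14/28"
        runs = {inject_typos(text, 1.0, seed=11) for _ in range(3)}
        assert len(runs) == 1

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            inject_typos("x", -0.5, seed=1)
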