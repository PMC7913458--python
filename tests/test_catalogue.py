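"""Catalogue curation and asymmetric prefix matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarestay.catalogue import (
    Catalogue,
    CatalogueEntry,
    DescriptionLookup,
    InvalidCodeError,
    chapter_of,
    consolidate_codes,
    flag_high_prevalence,
    match_diagnosis,
    merge_catalogues,
    normalize_code,
    read_catalogue,
    write_catalogue,
)

# strategy for canonical ICD-10-shaped codes
codes = st.builds(
    lambda letter, digits, tail: f"{letter}{digits:02d}{tail}",
    st.sampled_from("ABCDEQZ"),
    st.integers(0, 99),
    st.text(alphabet="0123456789", min_size=0, max_size=3),
)


class TestNormalizeCode:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("D57.1", "D571"),
            ("q05", "Q05"),
            ("E11.9", "E119"),
            ("  a92.4 ", "A924"),
        ],
    )
    def test_display_forms_canonicalized(self, raw, expected):
        assert normalize_code(raw) == expected

    @pytest.mark.parametrize("bad", ["", "   ", "57A", "D5", "D57123456", "Dxx", None])
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(InvalidCodeError):
            normalize_code(bad)

    @given(codes)
    @settings(max_examples=200, derandomize=True)
    def test_idempotent(self, code):
        once = normalize_code(code)
        assert normalize_code(once) == once


class TestMergeCatalogues:
    def test_mismatched_description_rejected(self, sickle_catalogue):
        """A mapping that mislabels a common-disease code must not enter."""
        lookup = DescriptionLookup(
            {"E119": "Type 2 diabetes mellitus without complications"}
        )
        merged, report = merge_catalogues(
            sickle_catalogue,
            [("E11.9", "Maturity Onset Diabetes of the Young")],
            lookup,
        )
        assert "E119" not in merged
        assert report.rejected == [
            (
                "E119",
                "Maturity Onset Diabetes of the Young",
                "Type 2 diabetes mellitus without complications",
            )
        ]

    def test_matching_description_added(self):
        base = Catalogue([CatalogueEntry("D57", "Sickle-cell disorders")])
        lookup = DescriptionLookup({"A924": "Rift Valley fever"})
        merged, report = merge_catalogues(base, [("A92.4", "Rift Valley fever")], lookup)
        assert "A924" in merged
        assert report.added == ["A924"]
        # comparison is case- and whitespace-insensitive
        merged2, _ = merge_catalogues(base, [("A92.4", "  rift valley  FEVER ")], lookup)
        assert "A924" in merged2

    def test_empty_candidates_identity(self, sickle_catalogue):
        merged, report = merge_catalogues(sickle_catalogue, [], DescriptionLookup({}))
        assert merged == sickle_catalogue
        assert not report.added and not report.rejected

    def test_uncovered_codes_reported_not_dropped_silently(self, sickle_catalogue):
        _, report = merge_catalogues(
            sickle_catalogue, [("G71.0", "Muscular dystrophy")], DescriptionLookup({})
        )
        assert report.uncovered == ["G710"]


class TestConsolidateCodes:
    children = {"Q05": {f"Q05{d}" for d in range(10)}}

    def test_complete_family_collapses_to_parent(self):
        cat = Catalogue(
            [CatalogueEntry(f"Q05{d}", "Spina bifida subtype") for d in range(10)]
        )
        out = consolidate_codes(cat, self.children)
        assert out.codes == {"Q05"}

    def test_incomplete_family_unchanged(self):
        cat = Catalogue(
            [CatalogueEntry("Q050", "x"), CatalogueEntry("Q051", "y")]
        )
        assert consolidate_codes(cat, self.children).codes == {"Q050", "Q051"}

    def test_empty_catalogue(self):
        assert len(consolidate_codes(Catalogue(), self.children)) == 0

    def test_idempotent_and_never_grows(self):
        cat = Catalogue(
            [CatalogueEntry(f"Q05{d}", "s") for d in range(10)]
            + [CatalogueEntry("D57", "sickle")]
        )
        once = consolidate_codes(cat, self.children)
        twice = consolidate_codes(once, self.children)
        assert once.codes == twice.codes
        assert len(once) <= len(cat)

    def test_coverage_preserved_for_specific_codes(self, rng):
        """Consolidation never changes which patient codes at child depth or
        deeper match.  (The bare 3-character parent code itself gains a match
        by design: replacing a complete child set by the parent is exactly
        what makes the shorter code matchable.)"""
        cat = Catalogue([CatalogueEntry(f"Q05{d}", "s") for d in range(10)])
        out = consolidate_codes(cat, self.children)
        for _ in range(500):
            code = "Q05" + "".join(
                rng.choice(list("0123456789"), size=rng.integers(1, 4))
            )
            assert (match_diagnosis(code, cat) is None) == (
                match_diagnosis(code, out) is None
            )

    def test_cascades_to_fixed_point(self):
        """5-char children collapse through the 4-char level up to 3 chars."""
        index = {
            "Q05": {f"Q05{d}" for d in range(10)},
            **{f"Q05{d}": {f"Q05{d}0", f"Q05{d}1"} for d in range(10)},
        }
        cat = Catalogue(
            [CatalogueEntry(f"Q05{d}{e}", "s") for d in range(10) for e in (0, 1)]
        )
        assert consolidate_codes(cat, index).codes == {"Q05"}


class TestMatchDiagnosis:
    def test_patient_code_truncates_to_catalogue_code(self, sickle_catalogue):
        assert match_diagnosis("D571", sickle_catalogue).code == "D57"

    def test_catalogue_code_never_truncates(self, sickle_catalogue):
        assert match_diagnosis("A92", sickle_catalogue) is None

    def test_exact_equality_matches(self, sickle_catalogue):
        assert match_diagnosis("Q05", sickle_catalogue).code == "Q05"

    def test_longest_prefix_wins(self):
        cat = Catalogue(
            [CatalogueEntry("D57", "broad"), CatalogueEntry("D571", "specific")]
        )
        assert match_diagnosis("D5712", cat).code == "D571"

    def test_adding_longer_code_never_unmatches(self, rng):
        cat = Catalogue([CatalogueEntry("D57", "broad")])
        extended = Catalogue(
            [CatalogueEntry("D57", "broad"), CatalogueEntry("D5712", "deep")]
        )
        for _ in range(300):
            code = "D" + "".join(rng.choice(list("0123456789"), size=rng.integers(2, 7)))
            if match_diagnosis(code, cat) is not None:
                assert match_diagnosis(code, extended) is not None


def brute_force_match(patient_code: str, catalogue: Catalogue):
    """Oracle: compare every truncation of the patient code against every
    catalogue code for equality; return the longest hit."""
    hits = [
        entry
        for entry in catalogue
        for length in range(1, len(patient_code) + 1)
        if patient_code[:length] == entry.code
    ]
    return max(hits, key=lambda e: len(e.code)) if hits else None


@given(st.data())
@settings(max_examples=300, derandomize=True)
def test_match_agrees_with_bruteforce_oracle(data):
    cat_codes = data.draw(st.sets(codes, min_size=1, max_size=8))
    catalogue = Catalogue([CatalogueEntry(normalize_code(c), "x") for c in cat_codes])
    patient = normalize_code(data.draw(codes))
    got = match_diagnosis(patient, catalogue)
    expected = brute_force_match(patient, catalogue)
    assert (got is None) == (expected is None)
    if got is not None:
        assert got.code == expected.code


class TestFlagHighPrevalence:
    def setup_method(self):
        self.cat = Catalogue(
            [CatalogueEntry("D57", "sickle"), CatalogueEntry("Q05", "spina")]
        )

    def test_inclusive_threshold(self):
        flagged = flag_high_prevalence(
            self.cat, {"D57": 100, "Q05": 10}, population_size=100_000
        )
        assert [e.code for e, _ in flagged] == ["D57"]
        # boundary: exactly 1/2000 is flagged
        flagged = flag_high_prevalence(self.cat, {"Q05": 50}, population_size=100_000)
        assert [e.code for e, _ in flagged] == ["Q05"]

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            flag_high_prevalence(self.cat, {"D57": -1}, population_size=1000)

    def test_report_only_never_removes(self):
        flag_high_prevalence(self.cat, {"D57": 999}, population_size=1000)
        assert "D57" in self.cat


class TestChapterOf:
    @pytest.mark.parametrize(
        "code,label_start",
        [
            ("D571", "Diseases of the blood"),
            ("Q05", "Congenital malformations"),
            ("A924", "Certain infectious and parasitic diseases"),
            ("C50", "Neoplasms"),
        ],
    )
    def test_standard_chapters(self, code, label_start):
        assert chapter_of(code).startswith(label_start)

    def test_gap_code_unclassified(self):
        assert chapter_of("D49") == "unclassified"


def test_catalogue_roundtrip(tmp_path, sickle_catalogue):
    path = tmp_path / "cat.csv"
    write_catalogue(sickle_catalogue, path)
    again = read_catalogue(path)
    assert again.codes == sickle_catalogue.codes
    assert again["D57"].label == "Sickle-cell disorders"


def test_catalogue_rejects_duplicate_codes():
    cat = Catalogue([CatalogueEntry("D57", "one")])
    with pytest.raises(ValueError):
        cat.add(CatalogueEntry("D57", "another"))


def test_prefix_violations_reported():
    cat = Catalogue([CatalogueEntry("D57", "a"), CatalogueEntry("D571", "b")])
    assert cat.prefix_violations() == [("D57", "D571")]
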