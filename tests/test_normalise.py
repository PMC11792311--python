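import pytest

from toxfindings.model import Category, ConfigurationError, EntityMention, Source
from toxfindings.normalise import (load_terminology, normalise_mention,
                                   parse_dose, postprocess)
from toxfindings.preprocess import preprocess_text


def mention(text, category, start=0):
    return EntityMention(category=category, start=start,
                         end=start + len(text), text=text)


class TestLoadTerminology:
    def test_empty_file_list_rejected(self):
        with pytest.raises(ConfigurationError):
            load_terminology([])

    def test_unknown_source_names_file_and_line(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("surface\tpreferred_term\tcode\tcategory\tsource\t"
                       "domain_code\nliver\tLiver\tL1\tSPECIMEN\tMESH\tLB\n")
        with pytest.raises(ConfigurationError, match=r"bad\.tsv:2"):
            load_terminology([bad])

    def test_unknown_category_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("surface\tpreferred_term\tcode\tcategory\tsource\t"
                       "domain_code\nliver\tLiver\tL1\tORGAN\tETOX\tLB\n")
        with pytest.raises(ConfigurationError, match="ORGAN"):
            load_terminology([bad])

    def test_missing_columns_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("surface\tpreferred_term\nliver\tLiver\n")
        with pytest.raises(ConfigurationError, match="missing columns"):
            load_terminology([bad])

    def test_packaged_store_is_self_consistent(self, store):
        assert store.self_check() == []


class TestNormaliseMention:
    @pytest.mark.parametrize("category, surface, preferred, controlled", [
        (Category.STUDY_TEST, "total white blood cell", "Leukocyte Count", True),
        (Category.STUDY_TEST, "absolute lymphocyte", "Lymphocyte Count", True),
        (Category.STUDY_TEST, "platelet counts", "Platelet Count", True),
        (Category.STUDY_TEST, "body weight gain", "Weight Gain", True),
        (Category.SEX, "males and females", "Both", False),
        (Category.SEX, "both sexes", "Both", False),
        (Category.FINDING, "histopathologic lesions", "lesions", False),
        (Category.FINDING, "increased M:E ratio", "increased M:E ratio", False),
        (Category.MANIFESTATION, "lower", "Decrease", False),
        (Category.MANIFESTATION, "elevated", "Increase", False),
    ])
    def test_lexicon_arrow_mappings(self, store, category, surface,
                                    preferred, controlled):
        m = normalise_mention(mention(surface, category), store)
        assert m.norm is not None
        assert m.norm.preferred_term == preferred
        assert m.norm.is_controlled is controlled

    def test_non_send_source_recorded(self, store):
        m = normalise_mention(
            mention("histopathologic lesions", Category.FINDING), store)
        assert m.norm.source == Source.ETOX

    def test_lemma_fallback_matches_plurals(self, store):
        m = normalise_mention(mention("reticulocyte counts",
                                      Category.STUDY_TEST), store)
        assert m.norm.preferred_term == "Reticulocyte Count"

    def test_unknown_surface_kept_without_norm(self, store):
        m = normalise_mention(mention("zymogen granules",
                                      Category.FINDING), store)
        assert m.norm is None

    def test_span_never_changes_and_idempotent(self, store):
        m0 = mention("platelet counts", Category.STUDY_TEST, start=17)
        m1 = normalise_mention(m0, store)
        m2 = normalise_mention(m1, store)
        assert (m1.start, m1.end, m1.text) == (m0.start, m0.end, m0.text)
        assert m1 == m2


class TestParseDose:
    @pytest.mark.parametrize("text, value, unit", [
        ("30 mg/kg", 30.0, "mg/kg"),
        ("20 mg/kg/day", 20.0, "mg/kg/day"),
        ("2.5 mg/kg", 2.5, "mg/kg"),
        ("100 ppm", 100.0, "ppm"),
        ("5 µg/kg", 5.0, "µg/kg"),
        ("12 mg/kg/day dose group", 12.0, "mg/kg/day"),
    ])
    def test_magnitude_and_canonical_unit(self, text, value, unit):
        m = parse_dose(mention(text, Category.DOSE))
        assert (m.norm.value, m.norm.unit) == (value, unit)

    def test_unitless_number_or_bare_unit_has_no_norm(self):
        assert parse_dose(mention("mg/kg", Category.DOSE)).norm is None


class TestPostprocess:
    def test_adjacent_same_category_fragments_merge(self, store):
        (sent,) = preprocess_text("body weight decreased")
        fragments = [mention("body", Category.STUDY_TEST, 0),
                     mention("weight", Category.STUDY_TEST, 5)]
        out = postprocess(fragments, sent, store)
        assert [m.text for m in out] == ["body weight"]
        assert out[0].norm.preferred_term == "Body Weight"

    def test_stoplisted_surface_removed(self, store):
        (sent,) = preprocess_text("albumin levels decreased")
        old = store.stoplist
        store.stoplist = {"albumin"}
        try:
            out = postprocess([mention("albumin", Category.STUDY_TEST)],
                              sent, store)
        finally:
            store.stoplist = old
        assert out == []

    def test_overlaps_resolved_longest_first(self, store):
        (sent,) = preprocess_text("12 mg/kg/day dose group")
        dose = mention("12 mg/kg/day", Category.DOSE, 0)
        group = mention("12 mg/kg/day dose group", Category.GROUP, 0)
        out = postprocess([dose, group], sent, store)
        assert [m.category for m in out] == [Category.GROUP]

    def test_category_priority_breaks_equal_length_ties(self, store):
        (sent,) = preprocess_text("30 mg/kg")
        dose = mention("30 mg/kg", Category.DOSE, 0)
        other = mention("30 mg/kg", Category.GROUP, 0)
        out = postprocess([other, dose], sent, store)
        assert [m.category for m in out] == [Category.DOSE]

    def test_output_sorted_by_start(self, store):
        (sent,) = preprocess_text("pale faeces in males")
        ms = [mention("males", Category.SEX, 15),
              mention("pale", Category.FINDING, 0),
              mention("faeces", Category.SPECIMEN, 5)]
        out = postprocess(ms, sent, store)
        assert [m.start for m in out] == sorted(m.start for m in out)
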