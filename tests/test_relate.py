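import logging
import random

import pytest

from toxfindings.model import Category, ConfigurationError, UNASSIGNED
from toxfindings.ner import tag_baseline
from toxfindings.normalise import normalise_all, postprocess
from toxfindings.preprocess import preprocess_text
from toxfindings.relate import (SentenceContext, assign_domain,
                                build_observations, detect_treatment_related,
                                load_triggers)

OBS_11 = ("A decrease in body weight gain was observed in females at the "
          "30 mg/kg dose.")
OBS_12_15 = ("There was a decrease in total white blood cell, absolute "
             "lymphocyte and platelet counts in males and females at the "
             "30 mg/kg dose, and a decrease in platelet count only for "
             "males at the 10 mg/kg dose.")


def analyse(text, store):
    (sent,) = preprocess_text(text)
    mentions = normalise_all(postprocess(tag_baseline(sent, store), sent,
                                         store), store)
    return sent, mentions


def observations_for(text, store, previous_text=None):
    prev_sent, prev_mentions = (None, [])
    if previous_text is not None:
        prev_sent, prev_mentions = analyse(previous_text, store)
        prev_sent.id = 0
    sent, mentions = analyse(text, store)
    sent.id = 0 if prev_sent is None else 1
    ctx = SentenceContext(current=sent, mentions=mentions,
                          previous=prev_sent,
                          previous_mentions=prev_mentions)
    return build_observations(ctx)


class TestWorkedExamples:
    def test_single_observation_with_all_modifiers(self, store):
        (obs,) = observations_for(OBS_11, store)
        assert obs.study_test == "Weight Gain"
        assert obs.manifestation == "Decrease"
        assert obs.sex == "Female"
        assert (obs.dose_value, obs.dose_unit) == (30.0, "mg/kg")
        assert obs.finding is None

    def test_coordination_shares_manifestation_sex_and_dose(self, store):
        obs = observations_for(OBS_12_15, store)
        assert len(obs) == 4
        assert [o.study_test for o in obs] == [
            "Leukocyte Count", "Lymphocyte Count", "Platelet Count",
            "Platelet Count"]
        for o in obs[:3]:
            assert (o.manifestation, o.sex, o.dose_value) \
                == ("Decrease", "Both", 30.0)
        assert (obs[3].manifestation, obs[3].sex, obs[3].dose_value) \
            == ("Decrease", "Male", 10.0)


class TestAttachmentRules:
    def test_lookback_inherits_dose_and_sex_from_previous_sentence(self, store):
        (obs,) = observations_for(
            "A decrease in albumin was also noted.", store,
            previous_text="Necrosis was observed in males at the 50 mg/kg "
                          "dose.")
        assert obs.sex == "Male"
        assert obs.dose_value == 50.0
        assert obs.sentence_ids == [0, 1]  # cites the previous sentence

    def test_no_lookback_beyond_one_sentence_without_mentions(self, store):
        (obs,) = observations_for("A decrease in albumin was also noted.",
                                  store,
                                  previous_text="The study went as planned.")
        assert obs.sex is None and obs.dose_value is None

    def test_zero_anchors_yield_no_observations(self, store):
        assert observations_for("Doses were given in the morning.",
                                store) == []

    def test_study_test_without_manifestation_is_dropped(self, store, caplog):
        with caplog.at_level(logging.WARNING):
            obs = observations_for("Albumin was measured weekly.", store)
        assert obs == []
        assert any("no manifestation" in r.message for r in caplog.records)

    def test_anchor_takes_nearest_following_manifestation(self, store):
        (obs,) = observations_for("Albumin showed a decrease in males.",
                                  store)
        assert obs.study_test == "Albumin"
        assert obs.manifestation == "Decrease"

    def test_specimen_binds_nearest_anchor(self, store):
        obs = observations_for(
            "Necrosis was observed in the liver of females.", store)
        assert [o.specimen for o in obs] == ["Liver"]

    def test_attachment_is_order_stable(self, store):
        sent, mentions = analyse(OBS_12_15, store)
        base = build_observations(SentenceContext(current=sent,
                                                  mentions=mentions))
        rng = random.Random(0)
        for _ in range(5):
            shuffled = list(mentions)
            rng.shuffle(shuffled)
            again = build_observations(SentenceContext(current=sent,
                                                       mentions=shuffled))
            assert [(o.study_test, o.sex, o.dose_value) for o in again] \
                == [(o.study_test, o.sex, o.dose_value) for o in base]

    def test_observation_count_equals_usable_anchor_count(self, store):
        sent, mentions = analyse(OBS_12_15, store)
        anchors = [m for m in mentions
                   if m.category in (Category.STUDY_TEST, Category.FINDING)]
        obs = build_observations(SentenceContext(current=sent,
                                                 mentions=mentions))
        assert len(obs) == len(anchors)


class TestTreatmentRelated:
    def sentence(self, text):
        (sent,) = preprocess_text(text)
        return sent

    def test_trigger_detected(self, triggers):
        assert detect_treatment_related(
            self.sentence("The decrease was attributable to treatment."),
            triggers)

    def test_negated_trigger_suppressed(self, triggers):
        assert not detect_treatment_related(
            self.sentence("These findings were not treatment-related."),
            triggers)

    def test_no_trigger(self, triggers):
        assert not detect_treatment_related(
            self.sentence("No triggers here."), triggers)

    def test_negation_window_is_three_tokens(self, triggers):
        assert detect_treatment_related(
            self.sentence("It was not clear but plainly very clearly "
                          "treatment-related."), triggers)

    def test_empty_trigger_list_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            detect_treatment_related(self.sentence("anything"), [])

    def test_default_trigger_file_has_printed_phrases(self, triggers):
        for phrase in ("treatment-related", "compound-related effect",
                       "attributable to treatment"):
            assert phrase in triggers


class TestAssignDomain:
    @pytest.mark.parametrize("text, domain", [
        ("A decrease in platelet count was seen in males.", "LB"),
        (OBS_11, "BW"),
    ])
    def test_domain_copied_from_anchor_entry(self, store, text, domain):
        (obs,) = observations_for(text, store)
        assert assign_domain(obs, store).domain_code == domain

    def test_unnormalised_anchor_gets_unassigned(self, store):
        (obs,) = observations_for(
            "Pale faeces were noted in males.", store)
        obs.finding = "some unknown finding"
        assert assign_domain(obs, store).domain_code == UNASSIGNED
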