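import math

import numpy as np
import pytest

from toxfindings.corpus_tools import (ADVERSE_OBSERVATION, CDOG, OUTSIDE,
                                      AnnotatedSentence, AnnotationDoc,
                                      average_group_alphas, corpus_stats,
                                      divide_into_sets, doc_from_spans,
                                      evaluate_classifier, evaluate_ner,
                                      expressions_to_entities, harmonise,
                                      krippendorff_alpha, round_half_up)
from toxfindings.model import Category, EntityMention, Relevance
from toxfindings.preprocess import preprocess_text
from toxfindings.synthgen import GenConfig, generate_corpus


def docs_from_matrix(matrix):
    """One AnnotationDoc per row; columns are token units (None = missing)."""
    docs = []
    n = len(matrix[0])
    spans = [(i, i + 1) for i in range(n)]
    for ci, row in enumerate(matrix):
        sent = AnnotatedSentence(text="x" * n, token_spans=spans,
                                 labels=list(row))
        docs.append(AnnotationDoc(annotator_id=f"coder{ci}",
                                  sentences=[sent]))
    return docs


def brute_force_alpha(matrix):
    """Nominal alpha by explicit pairable-value enumeration (no coincidence
    matrix): the independent oracle for the production implementation."""
    units = []
    for j in range(len(matrix[0])):
        vals = [row[j] for row in matrix if row[j] is not None]
        if len(vals) >= 2:
            units.append(vals)
    pooled = [v for u in units for v in u]
    n = len(pooled)
    if n < 2:
        return None
    d_o = sum(
        sum(1 for i in range(len(u)) for j in range(len(u))
            if i != j and u[i] != u[j]) / (len(u) - 1)
        for u in units) / n
    d_e = sum(1 for i in range(n) for j in range(n)
              if i != j and pooled[i] != pooled[j]) / (n * (n - 1))
    if d_e == 0:
        return None
    return 1 - d_o / d_e


class TestKrippendorffAlpha:
    def test_perfect_agreement_with_two_values_is_one(self):
        docs = docs_from_matrix([["r", "n", "r", "n"],
                                 ["r", "n", "r", "n"]])
        assert krippendorff_alpha(docs).alpha == pytest.approx(1.0)

    def test_hand_worked_four_unit_example(self):
        # units (r,r) (r,n) (n,n) (n,n): D_o = 1/4, D_e = 30/56
        docs = docs_from_matrix([["r", "r", "n", "n"],
                                 ["r", "n", "n", "n"]])
        alpha = krippendorff_alpha(docs).alpha
        assert alpha == pytest.approx(1 - (1 / 4) / (30 / 56), abs=1e-12)
        assert alpha == pytest.approx(0.533, abs=1e-3)

    def test_identical_single_value_is_flagged_undefined(self):
        docs = docs_from_matrix([["r", "r"], ["r", "r"]])
        result = krippendorff_alpha(docs)
        assert result.undefined and math.isnan(result.alpha)

    def test_units_with_fewer_than_two_codings_excluded(self):
        docs = docs_from_matrix([["r", None, "n"], ["r", "n", None]])
        assert krippendorff_alpha(docs).n_units == 1

    def test_category_binarisation_strict_per_label(self):
        full = [[ADVERSE_OBSERVATION, CDOG, OUTSIDE],
                [ADVERSE_OBSERVATION, OUTSIDE, OUTSIDE]]
        collapsed = [[ADVERSE_OBSERVATION, OUTSIDE, OUTSIDE],
                     [ADVERSE_OBSERVATION, OUTSIDE, OUTSIDE]]
        a = krippendorff_alpha(docs_from_matrix(full), ADVERSE_OBSERVATION)
        b = krippendorff_alpha(docs_from_matrix(collapsed))
        assert a.alpha == pytest.approx(b.alpha, abs=1e-12)

    def test_matches_brute_force_oracle_on_100_random_instances(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            n_coders = int(rng.integers(2, 6))
            n_units = int(rng.integers(2, 31))
            labels = ["a", "b", "c"][: int(rng.integers(2, 4))]
            matrix = [[(None if rng.random() < 0.15
                        else labels[int(rng.integers(len(labels)))])
                       for _ in range(n_units)] for _ in range(n_coders)]
            expected = brute_force_alpha(matrix)
            result = krippendorff_alpha(docs_from_matrix(matrix))
            if expected is None:
                assert result.undefined or result.n_units < 1
            else:
                assert result.alpha == pytest.approx(expected, abs=1e-12)
            checked += 1

    def test_invariant_under_relabeling_and_coder_permutation(self):
        matrix = [["a", "b", "a", None, "b"],
                  ["a", "a", "b", "b", "b"],
                  ["b", "b", "a", "b", None]]
        base = krippendorff_alpha(docs_from_matrix(matrix)).alpha
        swapped = [[{"a": "b", "b": "a", None: None}[v] for v in row]
                   for row in matrix]
        assert krippendorff_alpha(docs_from_matrix(swapped)).alpha \
            == pytest.approx(base, abs=1e-12)
        permuted = [matrix[2], matrix[0], matrix[1]]
        assert krippendorff_alpha(docs_from_matrix(permuted)).alpha \
            == pytest.approx(base, abs=1e-12)

    def test_single_annotator_rejected(self):
        with pytest.raises(ValueError):
            krippendorff_alpha(docs_from_matrix([["r", "n"]]))


class TestAverageGroupAlphas:
    @pytest.mark.parametrize("values, expected", [
        ((0.67, 0.76, 0.80, 0.70), 0.73),
        ((0.70, 0.75, 0.76, 0.75), 0.74),
        ((0.70, 0.78, 0.80, 0.74), 0.76),  # 0.755 rounds half-up
        ((0.5,), 0.5),
    ])
    def test_mean_with_half_up_rounding(self, values, expected):
        assert average_group_alphas(values) == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_group_alphas([])

    def test_half_up_not_bankers(self):
        assert round_half_up(0.755, 2) == 0.76
        assert round_half_up(0.125, 2) == 0.13


class TestDivideIntoSets:
    def test_near_equal_sizes_for_annotation_groups(self):
        sets = divide_into_sets(2933, 4, seed=0)
        assert sorted(len(s) for s in sets) == [733, 733, 733, 734]

    def test_sets_partition_the_indices(self):
        sets = divide_into_sets(100, 4, seed=1)
        flat = [i for s in sets for i in s]
        assert sorted(flat) == list(range(100))

    def test_seeded_reproducibility(self):
        assert divide_into_sets(50, 3, seed=9) == divide_into_sets(50, 3,
                                                                   seed=9)


class TestHarmonise:
    def test_two_of_three_agreeing_form_consensus(self):
        docs = docs_from_matrix([["r", "n"], ["r", "n"], ["n", "n"]])
        consensus, conflicts = harmonise(docs)
        assert consensus.sentences[0].labels == ["r", "n"]
        assert conflicts == []

    def test_total_disagreement_surfaces_all_tokens(self):
        docs = docs_from_matrix([["r", "r"], ["n", "n"]])
        consensus, conflicts = harmonise(docs)
        assert consensus.sentences[0].labels == [None, None]
        assert len(conflicts) == 2

    def test_two_two_split_is_a_conflict(self):
        docs = docs_from_matrix([["r"], ["r"], ["n"], ["n"]])
        _, conflicts = harmonise(docs)
        assert len(conflicts) == 1 and conflicts[0][2] == {"r": 2, "n": 2}

    def test_mismatched_coverage_rejected(self):
        a = docs_from_matrix([["r", "n"]])[0]
        b = docs_from_matrix([["r"]])[0]
        with pytest.raises(ValueError):
            harmonise([a, b])


class TestExpressionsToEntities:
    def test_adverse_observation_expression_standardised(self, store):
        text = "There was a slight increase in serum calcium this week."
        span_start = text.index("increase")
        span_end = text.index("calcium") + len("calcium")
        doc = doc_from_spans("a1", [text],
                             [[(span_start, span_end, ADVERSE_OBSERVATION)]])
        (pairs, flagged) = expressions_to_entities(doc, store)
        (_, mentions) = pairs[0]
        found = {(m.category, m.text) for m in mentions}
        assert (Category.MANIFESTATION, "increase") in found
        assert (Category.STUDY_TEST, "serum calcium") in found
        assert flagged == []

    def test_cdog_expression_yields_group_with_dose_value(self, store):
        text = "Effects were seen in the 12 mg/kg/day dose group."
        start = text.index("12")
        doc = doc_from_spans("a1", [text],
                             [[(start, start + len("12 mg/kg/day dose group"),
                                CDOG)]])
        (pairs, flagged) = expressions_to_entities(doc, store)
        (m,) = pairs[0][1]
        assert m.category == Category.GROUP
        assert m.norm.value == 12.0
        assert flagged == []

    def test_expression_without_lexicon_hits_is_flagged(self, store):
        text = "An unusual zymogen depletion was recorded."
        doc = doc_from_spans("a1", [text],
                             [[(3, 27, ADVERSE_OBSERVATION)]])
        (pairs, flagged) = expressions_to_entities(doc, store)
        assert pairs[0][1] == []
        assert len(flagged) == 1


class TestCorpusStats:
    def build(self, n, seed=0):
        corpus = generate_corpus(GenConfig(n_sentences=n, seed=seed,
                                           relevant_fraction=0.4))
        pairs = []
        for gs in corpus.sentences:
            sents = preprocess_text(gs.text)
            tokens = [t for s in sents for t in s.tokens]
            sent = sents[0]
            sent.tokens = tokens
            sent.relevance = gs.relevance
            pairs.append((sent, gs.entities))
        return pairs

    def test_counts_match_generator_ground_truth(self):
        stats = corpus_stats(self.build(10))
        assert stats["relevant_sentences"] == 4
        assert stats["non_relevant_sentences"] == 6
        assert stats["sentences"] == 10
        assert stats["tokens"] > 0

    def test_empty_corpus_all_zeros(self):
        stats = corpus_stats([])
        assert all(v == 0 for v in stats.values())


def m(cat, start, end):
    return EntityMention(category=cat, start=start, end=end,
                         text="x" * (end - start))


class TestEvaluateNER:
    def test_identical_predictions_score_one(self):
        gold = [("t" * 30, [m(Category.DOSE, 0, 5),
                            m(Category.SEX, 10, 15)])]
        metrics = evaluate_ner(gold, gold)
        assert metrics.micro == {"precision": 1.0, "recall": 1.0,
                                 "f1": 1.0, "support": 2}

    def test_boundary_off_by_one_counts_fp_and_fn(self):
        gold = [("t" * 30, [m(Category.DOSE, 0, 5)])]
        pred = [("t" * 30, [m(Category.DOSE, 0, 6)])]
        metrics = evaluate_ner(pred, gold)
        assert metrics.per_label["DOSE"] == {
            "precision": 0.0, "recall": 0.0, "f1": 0.0, "support": 1}

    def test_partial_recall_arithmetic(self):
        gold = [("t" * 30, [m(Category.SEX, 0, 4), m(Category.SEX, 10, 14)])]
        pred = [("t" * 30, [m(Category.SEX, 0, 4)])]
        metrics = evaluate_ner(pred, gold)
        assert metrics.micro["precision"] == 1.0
        assert metrics.micro["recall"] == 0.5
        assert metrics.micro["f1"] == pytest.approx(2 / 3)

    def test_text_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_ner([("abc", [])], [("abd", [])])

    def test_matches_set_intersection_oracle_on_random_mentions(self):
        rng = np.random.default_rng(7)
        cats = list(Category)
        for _ in range(20):
            def random_mentions():
                out = []
                for _ in range(int(rng.integers(0, 8))):
                    s = int(rng.integers(0, 40))
                    out.append(m(cats[int(rng.integers(len(cats)))],
                                 s, s + int(rng.integers(1, 6))))
                return out
            gold = [("t" * 50, random_mentions())]
            pred = [("t" * 50, random_mentions())]
            g = {(x.start, x.end, x.category) for x in gold[0][1]}
            p = {(x.start, x.end, x.category) for x in pred[0][1]}
            tp, fp, fn = len(g & p), len(p - g), len(g - p)
            metrics = evaluate_ner(pred, gold)
            expected_p = tp / (tp + fp) if tp + fp else 0.0
            expected_r = tp / (tp + fn) if tp + fn else 0.0
            assert metrics.micro["precision"] == pytest.approx(expected_p)
            assert metrics.micro["recall"] == pytest.approx(expected_r)


class TestEvaluateClassifier:
    def test_19_errors_in_440_give_432_percent(self):
        gold = ["r"] * 440
        pred = ["n"] * 19 + ["r"] * 421
        metrics = evaluate_classifier(pred, gold)
        assert metrics.error_rate_percent == 4.32

    def test_all_correct_is_zero_error(self):
        metrics = evaluate_classifier(["r", "n"], ["r", "n"])
        assert metrics.error_rate_percent == 0.0
        assert metrics.accuracy == 1.0

    def test_one_error_in_three(self):
        metrics = evaluate_classifier(["r", "r", "n"], ["r", "r", "r"])
        assert metrics.error_rate_percent == 33.33

    def test_accuracy_and_error_rate_are_complementary(self):
        gold = ["r", "n"] * 20
        pred = ["r"] * 40
        metrics = evaluate_classifier(pred, gold)
        assert metrics.accuracy * 100 + metrics.error_rate_percent \
            == pytest.approx(100.0, abs=0.005)

    def test_confusion_matrix_consistent_with_counts(self):
        gold = ["r", "r", "n", "n"]
        pred = ["r", "n", "n", "n"]
        metrics = evaluate_classifier(pred, gold)
        assert sum(sum(row) for row in metrics.confusion) == 4
        assert metrics.per_label["r"]["recall"] == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_classifier(["r"], ["r", "n"])
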