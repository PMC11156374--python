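import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from speechmarkers.features import (
    EmbeddingTable,
    FeatureConfig,
    LexiconEntry,
    extract_features,
    features_from_tags,
    lexical_property_means,
    person_ratios,
    semantic_variability,
    word_class_ratios,
)
from speechmarkers.tagging import TaggedToken


def tok(surface, pos, person="none", i=0):
    return TaggedToken(surface, pos, person, index=i)


class TestWordClassRatios:
    def test_example_sentence(self, example_sentence_1_tags):
        assert word_class_ratios(example_sentence_1_tags) == (0.125, 0.25)

    def test_no_nouns(self):
        assert word_class_ratios([tok("voy", "VERB", "first")]) == (0.0, 1.0)

    def test_counts_on_synthetic_stream(self):
        stream = (
            [tok("n", "NOUN", i=i) for i in range(60)]
            + [tok("va", "VERB", "third", i=i) for i in range(60, 110)]
            + [tok("de", "ADP", i=i) for i in range(110, 200)]
        )
        assert word_class_ratios(stream) == (0.30, 0.25)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            word_class_ratios([])


class TestPersonRatios:
    def test_example_sentence_1(self, example_sentence_1_tags):
        assert person_ratios(example_sentence_1_tags) == (0.5, 0.5)

    def test_example_sentence_2(self, example_sentence_2_tags):
        assert person_ratios(example_sentence_2_tags) == (0.5, 0.5)

    def test_all_first_person(self):
        stream = [tok("yo", "PRON", "first"), tok("voy", "VERB", "first")]
        assert person_ratios(stream) == (1.0, 0.0)

    def test_second_person_discarded(self):
        stream = [
            tok("voy", "VERB", "first"),
            tok("vas", "VERB", "second"),
            tok("va", "VERB", "third"),
        ]
        assert person_ratios(stream) == (0.5, 0.5)
        first, third = person_ratios(stream, include_second_in_denominator=True)
        assert (first, third) == (pytest.approx(1 / 3), pytest.approx(1 / 3))

    def test_no_markers_returns_missing_with_warning(self):
        with pytest.warns(UserWarning):
            assert person_ratios([tok("casa", "NOUN")]) == (None, None)

    @given(st.lists(st.sampled_from(["first", "second", "third", "none"]), min_size=1, max_size=40))
    def test_ratios_sum_to_one_when_defined(self, persons):
        stream = [
            tok("v", "VERB", p, i) if p != "none" else tok("n", "NOUN", "none", i)
            for i, p in enumerate(persons)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            first, third = person_ratios(stream)
        if first is not None:
            assert 0 <= first <= 1 and 0 <= third <= 1
            assert first + third == pytest.approx(1.0)


LEX = {
    "alta": LexiconEntry("alta", 1.0, 10, 4),
    "bajo": LexiconEntry("bajo", 3.0, 20, 4),
}


class TestLexicalPropertyMeans:
    def test_single_word(self):
        f, n, l, cov = lexical_property_means([tok("alta", "ADJ")], LEX)
        assert (f, n, l, cov) == (1.0, 10.0, 4.0, 1.0)

    def test_token_level_mean(self):
        stream = [tok("alta", "ADJ", i=0), tok("bajo", "ADJ", i=1)]
        f, *_ = lexical_property_means(stream, LEX)
        assert f == 2.0

    def test_oov_skipped_and_reported(self):
        stream = [tok("alta", "ADJ", i=0), tok("xxx", "NOUN", i=1), tok("bajo", "ADJ", i=2)]
        f, _, _, cov = lexical_property_means(stream, LEX)
        assert f == 2.0 and cov == pytest.approx(2 / 3)

    def test_repetitions_count_repeatedly(self):
        stream = [tok("alta", "ADJ", i=0), tok("alta", "ADJ", i=1), tok("bajo", "ADJ", i=2)]
        f, *_ = lexical_property_means(stream, LEX)
        assert f == pytest.approx(5 / 3)

    def test_zero_hits_names_participant(self):
        with pytest.raises(ValueError, match="p77"):
            lexical_property_means([tok("xxx", "NOUN")], LEX, participant_id="p77")


class TestSemanticVariability:
    def _table(self, vectors):
        return EmbeddingTable({f"w{i}": v for i, v in enumerate(vectors)})

    def _stream(self, n):
        return [tok(f"w{i}", "NOUN", i=i) for i in range(n)]

    def test_constant_distance_series_has_zero_variance(self):
        emb = self._table([(1, 0), (0, 1), (-1, 0)])
        var, cov = semantic_variability(self._stream(3), emb)
        assert var == pytest.approx(0.0, abs=1e-12) and cov == 1.0

    def test_hand_computed_two_point_series(self):
        emb = self._table([(1, 0), (0, 1), (1, 1)])
        var, _ = semantic_variability(self._stream(3), emb)
        assert var == pytest.approx(0.25, rel=1e-9)

    def test_fewer_than_three_words_is_missing(self):
        emb = self._table([(1, 0), (0, 1)])
        with pytest.warns(UserWarning):
            var, _ = semantic_variability(self._stream(2), emb)
        assert var is None

    def test_global_dedup_keeps_first_occurrence(self):
        emb = self._table([(1, 0), (0, 1), (1, 1)])
        stream = self._stream(3) + [tok("w0", "NOUN", i=3)]  # repeat ignored
        var, _ = semantic_variability(stream, emb)
        assert var == pytest.approx(0.25, rel=1e-9)

    def test_adjacent_dedup_keeps_later_reoccurrence(self):
        emb = self._table([(1, 0), (0, 1), (1, 1)])
        stream = self._stream(3) + [tok("w0", "NOUN", i=3)]
        var_adj, _ = semantic_variability(stream, emb, dedup="adjacent")
        var_glob, _ = semantic_variability(stream, emb, dedup="global")
        assert var_adj != pytest.approx(var_glob)

    def test_scaling_invariance_of_cosine_distance(self, rng):
        vecs = rng.normal(size=(8, 5))
        base = self._table(vecs)
        scaled = self._table(vecs * 37.5)
        v1, _ = semantic_variability(self._stream(8), base)
        v2, _ = semantic_variability(self._stream(8), scaled)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_population_variance_flag(self):
        emb = self._table([(1, 0), (0, 1), (1, 1)])
        var, _ = semantic_variability(self._stream(3), emb, ddof=0)
        assert var == pytest.approx(0.125, rel=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            EmbeddingTable({"a": (1, 0), "b": (1, 0, 0)})


class TestExtractFeatures:
    def test_deterministic_and_consistent_with_gold(self, default_cohort):
        p = default_cohort.participants[0]
        lex = default_cohort.lexicon
        t1 = p.transcript()
        f1 = extract_features(t1, lex.tag_lexicon, lex.entries, lex.embeddings)
        f2 = extract_features(p.transcript(), lex.tag_lexicon, lex.entries, lex.embeddings)
        assert f1 == f2
        gold = features_from_tags(
            p.gold, lex.entries, lex.embeddings,
            participant_id=p.participant_id, group=p.group,
        )
        assert f1.noun_ratio == pytest.approx(gold.noun_ratio)
        assert f1.first_person_ratio == pytest.approx(gold.first_person_ratio)
        assert f1.word_count == gold.word_count

    def test_single_repeated_word_yields_missing_variability(self):
        lex = {"casa": LexiconEntry("casa", 2.0, 12, 4)}
        emb = EmbeddingTable({"casa": np.array([1.0, 0.0])})
        stream = [tok("casa", "NOUN", i=i) for i in range(5)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = features_from_tags(stream, lex, emb)
        assert f.semantic_variability is None
        assert f.noun_ratio == 1.0 and f.word_count == 5

    def test_printed_sentences_through_full_pipeline(self):
        """Tokenize + tag the two printed example sentences end to end
        and recover the hand-counted person ratios (0.5, 0.5)."""
        from speechmarkers.corpus import clean_word_stream, tokenize
        from speechmarkers.tagging import core_lexicon, tag_stream

        for text in (
            "La señora se levanta primero, después voy yo.",
            "Mi hijo llega y entonces me deja las llaves y dice que si "
            "quiero me deja las puertas abiertas.",
        ):
            words, _ = clean_word_stream(tokenize(text))
            report = tag_stream(words, core_lexicon())
            assert report.coverage == 1.0
            assert person_ratios(report.tokens) == (0.5, 0.5)
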