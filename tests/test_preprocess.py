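"""Preprocessing pipeline: edit distance, spelling, entities, lemmas, invariants."""

import random

import edlib
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carestrat.preprocess import (
    PreprocessConfig,
    correct_spelling,
    default_dictionary,
    default_stopwords,
    edit_distance,
    lemmatize,
    preprocess,
    replace_entities,
    tokenize,
)

from .oracles import levenshtein_recursive


def _random_word(rng, max_len=8):
    return "".join(rng.choice("abcde") for _ in range(rng.randint(0, max_len)))


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("play", "play", 0), ("", "abc", 3), ("kitten", "sitting", 3)],
    )
    def test_known_pairs(self, a, b, expected):
        assert edit_distance(a, b) == expected
        assert levenshtein_recursive(a, b) == expected

    def test_agrees_with_recursive_oracle_on_random_pairs(self):
        rng = random.Random(0)
        for _ in range(50):
            a, b = _random_word(rng), _random_word(rng)
            assert edit_distance(a, b) == levenshtein_recursive(a, b)

    def test_agrees_with_edlib(self):
        rng = random.Random(1)
        for _ in range(50):
            a, b = _random_word(rng), _random_word(rng)
            if a and b:  # edlib requires non-empty inputs
                assert edit_distance(a, b) == edlib.align(a, b)["editDistance"]

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        a=st.text(alphabet="abcde", max_size=8),
        b=st.text(alphabet="abcde", max_size=8),
        c=st.text(alphabet="abcde", max_size=8),
    )
    def test_metric_axioms_hold(self, a, b, c):
        assert edit_distance(a, a) == 0
        assert edit_distance(a, b) == edit_distance(b, a)
        assert (edit_distance(a, b) == 0) == (a == b)
        assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)

    def test_metric_properties_on_random_triples(self):
        rng = random.Random(2)
        for _ in range(200):
            a, b, c = (_random_word(rng, 6) for _ in range(3))
            assert edit_distance(a, a) == 0
            assert edit_distance(a, b) == edit_distance(b, a)
            assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)


class TestSpellingCorrection:
    def test_dictionary_word_unchanged(self):
        config = PreprocessConfig(dictionary=frozenset({"music"}))
        assert correct_spelling("music", config) == "music"

    def test_close_misspelling_corrected(self):
        config = PreprocessConfig(dictionary=frozenset({"music", "muscle"}))
        assert correct_spelling("mussic", config) == "music"

    def test_no_candidate_within_bound(self):
        config = PreprocessConfig(dictionary=frozenset({"cat", "dog"}))
        assert correct_spelling("zzzzzz", config) == "zzzzzz"

    def test_tie_breaks_by_frequency_then_lexicographic(self):
        words = frozenset({"bat", "cat"})
        no_freq = PreprocessConfig(dictionary=words)
        assert correct_spelling("aat", no_freq) == "bat"  # lexicographic
        freq = PreprocessConfig(dictionary=words, token_frequencies={"cat": 5})
        assert correct_spelling("aat", freq) == "cat"  # frequency wins

    def test_placeholders_and_names_exempt(self):
        config = PreprocessConfig(dictionary=frozenset({"name"}))
        assert correct_spelling("[name]", config) == "[name]"
        assert correct_spelling("anna", config) == "anna"


class TestEntityReplacement:
    def test_name_example(self):
        assert replace_entities("Anna sings daily") == "[name] sings daily"

    def test_digit_rule(self):
        assert replace_entities("wake at 7") == "wake at [number]"

    def test_no_entities_unchanged(self):
        assert replace_entities("quiet room helps") == "quiet room helps"

    def test_attached_punctuation_preserved(self):
        assert replace_entities("Anna!") == "[name]!"


class TestLemmatize:
    @pytest.mark.parametrize(
        "token,lemma",
        [
            ("sung", "sing"),
            ("sing", "sing"),
            ("helping", "help"),
            ("dogs", "dog"),
            ("running", "run"),
            ("used", "use"),
            ("making", "make"),
            ("needed", "need"),
            ("speed", "speed"),
            ("activities", "activity"),
            ("children", "child"),
            ("[name]", "[name]"),
        ],
    )
    def test_known_forms(self, token, lemma):
        assert lemmatize(token) == lemma

    def test_strategy_keywords_are_fixed_points(self):
        # concept triggers match preprocessed tokens, so the four strategy
        # pools must survive lemmatization unchanged
        from carestrat.labels import ClassLabel
        from carestrat.vocab import CLASS_KEYWORDS

        for label, pool in CLASS_KEYWORDS.items():
            if label is ClassLabel.NONSTRAT:
                continue
            for word in pool:
                assert lemmatize(word) == word


class TestPipeline:
    def test_worked_example(self):
        config = PreprocessConfig(
            dictionary=frozenset({"loves", "drum", "love"}),
            stopword_list=frozenset({"her"}),
        )
        from carestrat.corpus import StrategyRecord
        from carestrat.labels import ClassLabel

        rec = StrategyRecord("r1", "Anna LOVES her drum!", ClassLabel.PREF)
        assert preprocess(rec, config).tokens == ("[name]", "love", "drum")

    def test_refusal_passthrough(self):
        assert preprocess("none").tokens == ("none",)

    def test_stopword_only_input_is_flagged_empty(self):
        seq = preprocess("it was so!")
        assert seq.empty
        assert seq.tokens == ()

    def test_output_invariants_on_generated_corpus(self, small_corpus):
        stop = default_stopwords()
        for rec in small_corpus[::5]:
            for tok in preprocess(rec).tokens:
                assert tok == tok.lower()
                assert any(ch.isalnum() for ch in tok) or tok in ("[name]", "[number]")
                assert tok not in stop

    def test_idempotent_on_own_output(self, small_corpus):
        config = PreprocessConfig()
        for rec in small_corpus[::7]:
            once = preprocess(rec, config).tokens
            twice = preprocess(" ".join(once), config).tokens
            assert twice == once


def test_tokenize_keeps_placeholders_whole():
    assert tokenize("[name] plays at [number]") == ["[name]", "plays", "at", "[number]"]


def test_bundled_stopword_list_has_127_words():
    stop = default_stopwords()
    assert len(stop) == 127
    assert "none" not in stop  # refusals must survive preprocessing


def test_bundled_dictionary_is_lowercase_words():
    assert all(w.isalpha() and w == w.lower() for w in default_dictionary())
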