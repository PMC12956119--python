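from __future__ import annotations

import math

import numpy as np
import pytest

from retell import (
    ContractError,
    content_similarity,
    match_events,
    sequence_similarity,
    story_similarity,
    within_story_thresholds,
)

from _oracle import (
    oracle_best_matches,
    oracle_remembered,
    oracle_story_similarity,
    oracle_thresholds,
)
from conftest import make_story, random_story

# hand-derived values for the 3-vs-2 worked example
TOY_CONTENT = 5.0 / 6.0
TOY_SEQUENCE = (1.5 / math.sqrt(3.0) + 1.0) / 2.0
TOY_COMBINED = TOY_CONTENT * TOY_SEQUENCE


class TestThresholds:
    def test_disjoint_sentences_have_zero_thresholds(self, lexical):
        theta = within_story_thresholds(["cat ran.", "dog sat.", "bird sang."], lexical)
        np.testing.assert_array_equal(theta, np.zeros(3))

    def test_toy_thresholds(self, toy_pair, lexical):
        a, _ = toy_pair
        np.testing.assert_allclose(
            within_story_thresholds(a.sentences, lexical), [0.2, 0.2, 0.0]
        )

    def test_duplicated_sentence_has_threshold_one(self, lexical):
        theta = within_story_thresholds(["cat ran.", "cat ran.", "dog sat."], lexical)
        np.testing.assert_allclose(theta[:2], [1.0, 1.0])

    def test_single_sentence_threshold_zero(self, lexical):
        np.testing.assert_array_equal(
            within_story_thresholds(["cat ran."], lexical), [0.0]
        )

    def test_global_mode_uses_story_maximum(self, toy_pair, lexical):
        a, _ = toy_pair
        theta = within_story_thresholds(a.sentences, lexical, threshold_mode="global")
        np.testing.assert_allclose(theta, [0.2, 0.2, 0.2])

    def test_empty_rejected(self, lexical):
        with pytest.raises(ContractError):
            within_story_thresholds([], lexical)


class TestMatchEvents:
    def test_self_comparison_all_remembered(self, lexical):
        s = make_story(["cat ran.", "dog sat.", "bird sang."])
        result = match_events(s, s, lexical)
        assert result.remembered.all()
        np.testing.assert_array_equal(result.best_index, [0, 1, 2])

    def test_toy_flags(self, toy_pair, lexical):
        a, b = toy_pair
        result = match_events(a, b, lexical)
        # A2's best match scores 0.2, which only ties its threshold: Forgotten
        np.testing.assert_array_equal(result.remembered, [True, False, True])

    def test_target_sentence_may_match_multiple(self, lexical):
        a = make_story(["big cat ran.", "cat ran far.", "dog slept."])
        b = make_story(["cat ran.", "mouse hid."])
        result = match_events(a, b, lexical)
        assert result.best_index[0] == result.best_index[1] == 0

    def test_empty_story_rejected(self, toy_pair, lexical):
        a, _ = toy_pair
        with pytest.raises(ContractError):
            match_events(a, make_story([]), lexical)


class TestContentSimilarity:
    def test_identical_stories(self, lexical):
        s = make_story(["cat ran.", "dog sat."])
        assert content_similarity(s, s, lexical) == (1.0, 1.0, 1.0)

    def test_toy_values(self, toy_pair, lexical):
        a, b = toy_pair
        cab, cba, c = content_similarity(a, b, lexical)
        assert cab == pytest.approx(2.0 / 3.0)
        assert cba == 1.0
        assert c == pytest.approx(TOY_CONTENT)

    def test_symmetrized_value_is_order_invariant(self, lexical):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = random_story(rng), random_story(rng)
            assert content_similarity(a, b, lexical)[2] == content_similarity(b, a, lexical)[2]


class TestSequenceSimilarity:
    def test_identical_stories(self, lexical):
        s = make_story(["cat ran.", "dog sat.", "bird sang."])
        assert sequence_similarity(s, s, lexical) == (1.0, 1.0, 1.0)

    def test_reversed_story(self, lexical):
        s = make_story(["cat ran.", "dog sat.", "bird sang.", "fish swam."])
        rev = make_story(list(reversed(s.sentences)))
        assert sequence_similarity(s, rev, lexical) == (-1.0, -1.0, -1.0)

    def test_toy_values(self, toy_pair, lexical):
        a, b = toy_pair
        sab, sba, s = sequence_similarity(a, b, lexical)
        assert sab == pytest.approx(1.5 / math.sqrt(3.0), abs=1e-12)
        assert sba == 1.0
        assert s == pytest.approx(TOY_SEQUENCE, abs=1e-12)

    def test_single_sentence_contributes_zero(self, lexical):
        one = make_story(["cat ran."])
        other = make_story(["cat ran.", "dog sat."])
        sab, _, _ = sequence_similarity(one, other, lexical)
        assert sab == 0.0

    def test_constant_mapping_contributes_zero(self, lexical):
        a = make_story(["cat ran.", "cat sat.", "cat slept."])
        b = make_story(["cat cat cat.", "mouse hid."])
        sab, _, _ = sequence_similarity(a, b, lexical)
        assert sab == 0.0


class TestStorySimilarity:
    def test_identity(self, lexical):
        s = make_story(["cat ran.", "dog sat.", "bird sang."])
        result = story_similarity(s, s, lexical)
        assert (result.content, result.sequence, result.combined) == (1.0, 1.0, 1.0)

    def test_reversal(self, lexical):
        s = make_story(["cat ran.", "dog sat.", "bird sang.", "fish swam."])
        rev = make_story(list(reversed(s.sentences)))
        result = story_similarity(s, rev, lexical)
        assert result.content == 1.0
        assert result.sequence == -1.0
        assert result.combined == -1.0

    def test_toy_combined(self, toy_pair, lexical):
        a, b = toy_pair
        result = story_similarity(a, b, lexical)
        assert result.combined == pytest.approx(TOY_COMBINED, abs=1e-12)
        assert result.combined == result.content * result.sequence

    def test_toy_against_oracle(self, toy_pair, lexical):
        a, b = toy_pair
        result = story_similarity(a, b, lexical)
        expected = oracle_story_similarity(a.sentences, b.sentences)
        for field, value in expected.items():
            assert getattr(result, field) == pytest.approx(value, abs=1e-9), field


class TestOracleEquivalence:
    """Exhaustive agreement with the naive double-loop reference."""

    def test_200_random_pairs(self, lexical):
        rng = np.random.default_rng(12345)
        for trial in range(200):
            a, b = random_story(rng), random_story(rng)
            theta = within_story_thresholds(a.sentences, lexical)
            np.testing.assert_allclose(
                theta, oracle_thresholds(a.sentences), atol=1e-12,
                err_msg=f"thresholds, trial {trial}",
            )
            result = match_events(a, b, lexical)
            idx, sims = oracle_best_matches(a.sentences, b.sentences)
            np.testing.assert_array_equal(result.best_index, idx)
            np.testing.assert_allclose(result.best_sim, sims, atol=1e-12)
            np.testing.assert_array_equal(
                result.remembered, oracle_remembered(a.sentences, b.sentences)
            )
            ours = story_similarity(a, b, lexical)
            expected = oracle_story_similarity(a.sentences, b.sentences)
            for field, value in expected.items():
                assert getattr(ours, field) == pytest.approx(value, abs=1e-9), (
                    f"{field}, trial {trial}"
                )


class TestInvariants:
    def test_symmetry_and_ranges_on_random_pairs(self, lexical):
        rng = np.random.default_rng(777)
        for _ in range(60):
            a, b = random_story(rng), random_story(rng)
            ab = story_similarity(a, b, lexical)
            ba = story_similarity(b, a, lexical)
            assert ab.content == ba.content
            assert ab.sequence == ba.sequence
            assert ab.combined == ba.combined
            assert 0.0 <= ab.content <= 1.0
            assert -1.0 <= ab.sequence <= 1.0
            assert -1.0 <= ab.combined <= 1.0

    def test_identity_for_distinct_sentence_stories(self, lexical):
        rng = np.random.default_rng(31)
        for _ in range(30):
            story = random_story(rng)
            # keep only stories whose sentences are pairwise non-identical sets
            theta = within_story_thresholds(story.sentences, lexical)
            if len(story.sentences) < 2 or np.any(theta >= 1.0):
                continue  # single-sentence stories carry no order information
            result = story_similarity(story, story, lexical)
            assert (result.content, result.sequence, result.combined) == (1.0, 1.0, 1.0)
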