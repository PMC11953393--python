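"""Semantic distance, surprise and triplet selection against closed forms
and brute-force oracles."""

import math

import numpy as np
import pytest

from semstory import ValidationError, make_lm_table, make_toy_lexicon
from semstory.text_metrics import (EmbeddingLexicon, MaskedLMTable,
                                   MissingWordError, SemanticScores,
                                   StoryTranscript, TripletCandidate,
                                   TripletShortfallError,
                                   aggregate_across_models, semantic_distance,
                                   select_triplets, surprise)


def make_story(targets=("a", "b", "c"), non_targets=("x", "y")):
    return StoryTranscript(tokens=list(targets) + list(non_targets),
                           target_words=list(targets), subject_id=0,
                           condition_label="CR", trial_id=0)


def lexicon_from(mapping):
    dim = len(next(iter(mapping.values())))
    return EmbeddingLexicon(vectors={w: np.array(v, float)
                                     for w, v in mapping.items()}, dimension=dim)


class TestSemanticDistance:
    def test_identical_directions_give_zero(self):
        lex = lexicon_from({w: [1, 0] for w in "abcxy"})
        assert semantic_distance(make_story(), lex) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_targets_give_one(self):
        vecs = {w: [1.0, 0.0] for w in "abc"}
        vecs.update({w: [0.0, 1.0] for w in "xy"})
        assert semantic_distance(make_story(), lexicon_from(vecs)) == pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self, rng):
        # independent oracle: two nested loops over all target/non-target pairs
        words = list("abcdefgh")
        vecs = {w: rng.standard_normal(5) for w in words}
        lex = lexicon_from(vecs)
        story = StoryTranscript(tokens=words, target_words=["a", "b", "c"])
        expected = 0.0
        non_targets = sorted(story.non_target_content_words)
        for t in ["a", "b", "c"]:
            for nt in non_targets:
                u, v = vecs[t], vecs[nt]
                expected += 1 - np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        expected /= 3 * len(non_targets)
        assert semantic_distance(story, lex) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_positive_rescaling(self, rng):
        vecs = {w: rng.standard_normal(4) for w in "abcxy"}
        base = semantic_distance(make_story(), lexicon_from(vecs))
        vecs["x"] = 7.3 * vecs["x"]
        vecs["a"] = 0.01 * vecs["a"]
        assert semantic_distance(make_story(), lexicon_from(vecs)) == pytest.approx(
            base, abs=1e-10)

    def test_rotating_non_target_away_increases_sd(self):
        vecs = {w: [1.0, 0.0] for w in "abc"}
        angles = np.linspace(0.1, np.pi, 8)
        values = []
        for ang in angles:
            vecs["x"] = [np.cos(ang), np.sin(ang)]
            vecs["y"] = [1.0, 0.0]
            values.append(semantic_distance(make_story(), lexicon_from(vecs)))
        assert np.all(np.diff(values) > 0)

    def test_oov_raises_with_word_named(self):
        lex = lexicon_from({w: [1, 0] for w in "abcx"})
        with pytest.raises(MissingWordError, match="y"):
            semantic_distance(make_story(), lex)
        # targets must resolve even when skipping OOV non-targets
        assert semantic_distance(make_story(), lex,
                                 skip_oov_non_targets=True) >= 0

    def test_zero_vector_is_an_error_not_nan(self):
        vecs = {w: [1.0, 0.0] for w in "abcy"}
        vecs["x"] = [0.0, 0.0]
        with pytest.raises(ValidationError):
            semantic_distance(make_story(), lexicon_from(vecs))


class TestSurprise:
    def _table(self, probs):
        story_id = make_story().story_id
        vocab_rest = 1.0
        dists = {}
        for i, p in enumerate(probs):
            word = ["a", "b", "c"][i]
            dists[(story_id, i)] = {word: p, "other": 1.0 - p}
        return MaskedLMTable(distributions=dists)

    def test_certainty_gives_zero(self):
        assert surprise(make_story(), self._table([1.0, 1.0, 1.0])) == pytest.approx(0.0)

    def test_uniform_distribution_gives_log_vocab(self):
        story = make_story()
        vocab = [f"w{i}" for i in range(97)] + ["a", "b", "c"]
        dists = {(story.story_id, i): {w: 1.0 / 100 for w in vocab}
                 for i in range(3)}
        table = MaskedLMTable(distributions=dists)
        assert surprise(story, table) == pytest.approx(math.log(100), abs=1e-12)

    def test_hand_computed_mixed_probabilities(self):
        # delta = -(ln 0.5 + ln 0.25 + ln 0.1) / 3, evaluated independently
        expected = -(math.log(0.5) + math.log(0.25) + math.log(0.1)) / 3
        assert surprise(make_story(), self._table([0.5, 0.25, 0.1])) == pytest.approx(
            expected, abs=1e-12)

    def test_strictly_decreasing_in_target_probability(self):
        values = [surprise(make_story(), self._table([p, 0.5, 0.5]))
                  for p in (0.1, 0.3, 0.6, 0.9)]
        assert np.all(np.diff(values) < 0)

    def test_zero_probability_errors_unless_floored(self):
        table = self._table([0.0, 0.5, 0.5])
        with pytest.raises((ValidationError, MissingWordError)):
            surprise(make_story(), table)
        floored = surprise(make_story(), table, probability_floor=1e-10)
        assert np.isfinite(floored)

    def test_missing_distribution_is_explicit(self):
        with pytest.raises(MissingWordError):
            surprise(make_story(), MaskedLMTable(distributions={}))


class TestAggregate:
    def _scores(self, model, sd_vals):
        import pandas as pd
        return SemanticScores(pd.DataFrame(
            {"story_id": [f"s{i}" for i in range(len(sd_vals))],
             "model": model, "SD": sd_vals, "delta": np.nan}))

    def test_single_model_is_identity(self):
        s = self._scores("m1", [0.2, 0.7])
        out = aggregate_across_models([s])
        assert list(out.table["SD"]) == pytest.approx([0.2, 0.7])

    def test_two_models_average(self):
        out = aggregate_across_models(
            [self._scores("m1", [0.2]), self._scores("m2", [0.4])])
        assert out.table["SD"].iloc[0] == pytest.approx(0.3)

    def test_matches_column_mean_oracle(self, rng):
        vals = rng.uniform(0, 2, size=(3, 10))
        scores = [self._scores(f"m{k}", vals[k]) for k in range(3)]
        out = aggregate_across_models(scores)
        assert np.allclose(out.table["SD"].to_numpy(), vals.mean(axis=0))

    def test_mismatched_story_sets_error(self):
        a = self._scores("m1", [0.1, 0.2])
        b = self._scores("m2", [0.1])
        with pytest.raises(ValidationError):
            aggregate_across_models([a, b])


class TestTripletSelection:
    def _cand(self, words, sims, freqs, cats=None):
        return TripletCandidate(words=tuple(words),
                                categories=tuple(cats or words),
                                similarities=tuple(sims),
                                frequencies=tuple(freqs))

    def test_perfect_candidate_selected_first(self):
        perfect = self._cand("abc", (0, 0, 0), (0.5, 0.5, 0.5))
        other = self._cand("def", (0.5, 0.5, 0.5), (0.9, 0.9, 0.9))
        assert select_triplets([other, perfect], 1) == [perfect]
        assert perfect.mse_score == 0.0

    def test_word_reuse_excluded_in_mse_then_input_order(self):
        first = self._cand("abc", (0, 0, 0), (0.5, 0.5, 0.5))
        shares_word = self._cand(("a", "d", "e"), (0, 0, 0), (0.5, 0.5, 0.5))
        fresh = self._cand("fgh", (0.1, 0, 0), (0.5, 0.5, 0.5))
        out = select_triplets([first, shares_word, fresh], 2)
        assert out == [first, fresh]

    def test_matches_exhaustive_greedy_oracle(self, rng):
        pool = []
        for i in range(30):
            words = tuple(f"w{i}_{j}" for j in range(3))
            pool.append(self._cand(words, tuple(rng.uniform(-1, 1, 3)),
                                   tuple(rng.uniform(0, 1, 3))))
        # oracle: independent greedy re-implementation
        remaining = sorted(pool, key=lambda c: (c.mse_score, pool.index(c)))
        expected, used = [], set()
        for cand in remaining:
            if not used & set(cand.words):
                expected.append(cand)
                used |= set(cand.words)
            if len(expected) == 5:
                break
        assert select_triplets(pool, 5) == expected

    def test_shortfall_reports_selectable_count(self):
        a = self._cand("abc", (0, 0, 0), (0.5, 0.5, 0.5))
        b = self._cand(("a", "d", "e"), (0, 0, 0), (0.5, 0.5, 0.5))
        with pytest.raises(TripletShortfallError) as err:
            select_triplets([a, b], 2)
        assert err.value.selectable == 1

    def test_category_constraint_enforced(self):
        with pytest.raises(ValidationError):
            self._cand("abc", (0, 0, 0), (0.5, 0.5, 0.5),
                       cats=("plant", "plant", "job"))


class TestToyGenerators:
    def test_orthogonal_clusters_have_cosine_distance_one(self):
        lex = make_toy_lexicon(["a", "b"], dimension=4,
                               cluster_spec={"a": 0, "b": 1}, seed=3, spread=0.0)
        u, v = lex["a"], lex["b"]
        cos = np.dot(u, v)
        # independent random directions in 4-d are not exactly orthogonal;
        # same-cluster words with zero spread are exactly aligned
        lex2 = make_toy_lexicon(["a", "b"], dimension=4,
                                cluster_spec={"a": 0, "b": 0}, seed=3, spread=0.0)
        assert np.dot(lex2["a"], lex2["b"]) == pytest.approx(1.0, abs=1e-12)
        assert -1 <= cos <= 1

    def test_cluster_structure_separates_cosines(self):
        words = [f"w{i}" for i in range(12)]
        spec = {w: i % 2 for i, w in enumerate(words)}
        lex = make_toy_lexicon(words, dimension=8, cluster_spec=spec, seed=0)
        within, between = [], []
        for i, a in enumerate(words):
            for b in words[i + 1:]:
                cos = float(np.dot(lex[a], lex[b]))
                (within if spec[a] == spec[b] else between).append(cos)
        assert min(within) > max(between)

    def test_all_pairwise_distances_in_range(self, rng):
        words = [f"w{i}" for i in range(50)]
        lex = make_toy_lexicon(words, dimension=6, seed=9)
        # exhaustive pairwise enumeration
        for i, a in enumerate(words):
            for b in words[i + 1:]:
                dist = 1 - np.dot(lex[a], lex[b])
                assert 0.0 <= dist <= 2.0

    def test_duplicate_words_rejected(self):
        with pytest.raises(ValidationError):
            make_toy_lexicon(["a", "a"], dimension=4)

    def test_lexicon_word2vec_roundtrip(self, tmp_path):
        lex = make_toy_lexicon(["alpha", "beta"], dimension=3, seed=1)
        path = tmp_path / "lex.txt"
        lex.write_word2vec(path)
        header = path.read_text().splitlines()[0]
        assert header == "2 3"
        back = EmbeddingLexicon.read_word2vec(path)
        assert np.allclose(back["alpha"], lex["alpha"], atol=1e-7)

    def test_lm_table_rows_sum_to_one_and_boost_is_modal(self):
        vocab = [f"w{i}" for i in range(30)]
        keys = [("story", i) for i in range(5)]
        table = make_lm_table(vocab, keys, concentration=2.0,
                              target_boost={("story", 0): "w7"}, seed=4)
        for key in keys:
            dist = table.distributions[key]
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
        boosted = table.distributions[("story", 0)]
        assert max(boosted, key=boosted.get) == "w7"

    def test_lm_concentration_zero_is_uniform(self):
        vocab = [f"w{i}" for i in range(10)]
        table = make_lm_table(vocab, [("s", 0)], concentration=0.0, seed=0)
        probs = list(table.distributions[("s", 0)].values())
        assert np.allclose(probs, 0.1, atol=1e-12)

    def test_lm_table_json_roundtrip(self, tmp_path):
        vocab = ["a", "b"]
        table = make_lm_table(vocab, [("s", 0)], seed=0)
        path = tmp_path / "lm.json"
        table.write_json(path)
        back = MaskedLMTable.read_json(path)
        assert back.distributions[("s", 0)] == pytest.approx(
            table.distributions[("s", 0)])

    def test_empty_vocab_rejected(self):
        with pytest.raises(ValidationError):
            make_lm_table([], [("s", 0)])


def test_sd_and_surprise_decorrelate_when_varied_independently(rng):
    """Target-context similarity and target probability varied independently
    produce near-zero sample correlation between SD and surprise."""
    n = 120
    sds, deltas = [], []
    for i in range(n):
        ang = rng.uniform(0, np.pi)
        vecs = {w: [1.0, 0.0] for w in "abc"}
        vecs["x"] = [np.cos(ang), np.sin(ang)]
        vecs["y"] = [np.cos(ang), np.sin(ang)]
        story = make_story()
        sds.append(semantic_distance(story, lexicon_from(vecs)))
        p = rng.uniform(0.05, 0.95)
        story_id = story.story_id
        dists = {(story_id, k): {["a", "b", "c"][k]: p, "other": 1 - p}
                 for k in range(3)}
        deltas.append(surprise(story, MaskedLMTable(distributions=dists)))
    r = np.corrcoef(sds, deltas)[0, 1]
    assert abs(r) < 0.2
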