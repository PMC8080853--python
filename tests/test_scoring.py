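"""Lexicon scoring, binning, user filtering and covariate reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectcast.lexicon import BASIC_EMOTIONS, Lexicon, tokenize
from affectcast.scoring import (
    UnscorableMessageError,
    aggregate_bins,
    filter_users,
    reduce_covariates,
    score_message,
)


class TestTokenize:
    def test_lowercases_and_splits(self):
        assert tokenize("Hello, WORLD!") == ["hello", "world"]

    def test_strips_mentions_keeps_hashtag_body(self):
        assert tokenize("@friend check #GoodVibes now") == ["check", "goodvibes", "now"]

    def test_empty_after_cleanup(self):
        assert tokenize("@a @b !!!") == []


class TestScoreMessage:
    def test_direct_ratio(self, lexicon, message_factory):
        # 10 tokens, 2 anger words -> anger score 0.2
        text = "angerw00 angerw01 " + " ".join(f"x{i}" for i in range(8))
        scores = score_message(message_factory(text=text), lexicon)
        assert scores[lexicon.categories.index("anger")] == pytest.approx(0.2)

    def test_no_lexicon_token_gives_zero_vector(self, lexicon, message_factory):
        scores = score_message(message_factory(text="plain words only here"), lexicon)
        assert np.all(scores == 0)

    def test_all_joy_hits_upper_bound(self, lexicon, message_factory):
        scores = score_message(message_factory(text="joyw00 joyw01 joyw02"), lexicon)
        assert scores[lexicon.categories.index("joy")] == pytest.approx(1.0)

    def test_multi_category_word_counts_once_per_category(self, lexicon, message_factory):
        scores = score_message(message_factory(text="bittersweet other"), lexicon)
        assert scores[lexicon.categories.index("joy")] == pytest.approx(0.5)
        assert scores[lexicon.categories.index("sadness")] == pytest.approx(0.5)

    def test_zero_token_message_raises(self, lexicon, message_factory):
        with pytest.raises(UnscorableMessageError):
            score_message(message_factory(text="@only @mentions"), lexicon)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(
        ["angerw00", "joyw03", "fearw01", "blank", "noise", "bittersweet"]
    ), min_size=1, max_size=30))
    def test_scores_are_probability_like(self, lexicon, words):
        from conftest import make_message

        scores = score_message(make_message(text=" ".join(words)), lexicon)
        assert np.all(scores >= 0) and np.all(scores <= 1)
        for i, cat in enumerate(lexicon.categories):
            carries = any(cat in lexicon.categories_of(w) for w in words)
            assert (scores[i] > 0) == carries


class TestAggregateBins:
    def test_weekly_mean_of_message_scores(self, lexicon, message_factory):
        # anger fractions 0.1 (1/10), 0.2 (2/10), 0.3 (3/10) -> bin mean 0.2
        msgs = []
        for day, k in ((0, 1), (2, 2), (4, 3)):
            toks = [f"angerw{i:02d}" for i in range(k)] + ["pad"] * (10 - k)
            msgs.append(message_factory(day=day, text=" ".join(toks)))
        bins = aggregate_bins(msgs, "weekly", lexicon)["u1"]
        assert len(bins) == 1
        assert bins[0].scores[lexicon.categories.index("anger")] == pytest.approx(0.2)
        assert bins[0].n_messages == 3

    def test_daily_gap_day_marked_empty(self, lexicon, message_factory):
        msgs = [
            message_factory(day=0, text="joyw00 ok"),
            message_factory(day=2, text="joyw01 ok"),
        ]
        bins = aggregate_bins(msgs, "daily", lexicon)["u1"]
        assert [b.bin_index for b in bins] == [0, 1, 2]
        assert not bins[0].empty and bins[1].empty and not bins[2].empty
        assert bins[1].n_messages == 0

    def test_single_message_bin_equals_message_vector(self, lexicon, message_factory):
        msg = message_factory(text="fearw00 fearw01 calm calm")
        bins = aggregate_bins([msg], "weekly", lexicon)["u1"]
        assert np.allclose(bins[0].scores, score_message(msg, lexicon))

    def test_permutation_invariance(self, lexicon, message_factory):
        msgs = [
            message_factory(day=d, hour=h, text=t)
            for d, h, t in [(0, 9, "angerw00 a b"), (1, 3, "joyw00 c"), (3, 22, "sad x")]
        ]
        fwd = aggregate_bins(msgs, "weekly", lexicon)["u1"]
        rev = aggregate_bins(msgs[::-1], "weekly", lexicon)["u1"]
        for a, b in zip(fwd, rev):
            assert np.allclose(a.scores, b.scores) and a.n_messages == b.n_messages

    def test_url_messages_dropped_by_default(self, lexicon, message_factory):
        msgs = [
            message_factory(day=0, text="joyw00 fine"),
            message_factory(day=0, text="look https://t.co/xyz joyw01"),
        ]
        bins = aggregate_bins(msgs, "weekly", lexicon)["u1"]
        assert bins[0].n_messages == 1
        kept = aggregate_bins(msgs, "weekly", lexicon, drop_urls=False)["u1"]
        assert kept[0].n_messages == 2

    def test_unknown_resolution_rejected(self, lexicon):
        with pytest.raises(ValueError, match="resolution"):
            aggregate_bins([], "hourly", lexicon)

    def test_embeddings_averaged(self, lexicon, message_factory):
        m1 = message_factory(day=0, text="a b")
        m2 = message_factory(day=1, text="c d")
        m1.embedding = np.array([1.0, 3.0])
        m2.embedding = np.array([3.0, 5.0])
        bins = aggregate_bins([m1, m2], "weekly", lexicon)["u1"]
        assert np.allclose(bins[0].covariates, [2.0, 4.0])


def _weeks(user, active, n_msgs=3):
    """BinScore stubs for the given active week indices."""
    from affectcast.scoring import BinScore

    return {
        user: [
            BinScore(user, w, np.zeros(2), None, n_msgs if w in active else 0,
                     empty=w not in active)
            for w in range(max(active) + 1)
        ]
    }


class TestFilterUsers:
    def test_twenty_consecutive_weeks_retained(self):
        bins = _weeks("u", set(range(20)))
        assert filter_users(bins) == {"u": range(0, 20)}

    def test_nineteen_weeks_dropped(self):
        assert filter_users(_weeks("u", set(range(19)))) == {}

    def test_gap_splitting_runs_drops_user(self):
        # runs of 9 (weeks 0..8) and 15 (10..24): max run 15 < 20
        active = set(range(25)) - {9}
        assert filter_users(_weeks("u", active)) == {}

    def test_first_qualifying_window_kept(self):
        bins = _weeks("u", set(range(45)))
        assert filter_users(bins)["u"] == range(0, 20)

    def test_low_message_week_breaks_run(self):
        from affectcast.scoring import BinScore

        bins = {
            "u": [
                BinScore("u", w, np.zeros(2), None, 2 if w == 10 else 5)
                for w in range(25)
            ]
        }
        assert filter_users(bins) == {}
        # monotone: relaxing the message threshold re-admits the user
        assert "u" in filter_users(bins, min_msgs_per_week=2)

    def test_monotone_in_week_threshold(self):
        bins = _weeks("u", set(range(18)))
        assert "u" not in filter_users(bins, min_contig_weeks=20)
        assert "u" in filter_users(bins, min_contig_weeks=15)


class TestReduceCovariates:
    def test_rank_one_matrix_recovered_exactly(self, rng):
        u = np.abs(rng.normal(size=50)) + 0.1
        v = np.abs(rng.normal(size=12)) + 0.1
        X = np.outer(u, v)
        reduced, reducer = reduce_covariates(X, k=1)
        recon = reduced @ reducer.nmf.components_ + reducer.offsets
        err = np.linalg.norm(recon - X) / np.linalg.norm(X)
        assert err < 1e-6

    def test_output_dimension_and_nonnegativity(self, rng):
        X = rng.normal(size=(200, 64))  # signed input, NMF needs the shift
        reduced, reducer = reduce_covariates(X, k=8, fit_subset_size=100)
        assert reduced.shape == (200, 8)
        assert np.all(reduced >= 0)
        assert reducer.transform(X[:5]).shape == (5, 8)

    def test_k_exceeding_dimension_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            reduce_covariates(rng.normal(size=(10, 4)), k=8)
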