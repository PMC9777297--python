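import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emodecode import (fsdd_scores, pool_top_features, rank_features,
                       select_top_k, topography_tally)
from emodecode.features import FeatureDescriptor
from emodecode.selection import RankedFeatures, mrmr_rank, ttest_scores


def two_class_data(rng, n_per_class=30, n_features=10, shift=None):
    shift = np.zeros(n_features) if shift is None else shift
    X0 = rng.standard_normal((n_per_class, n_features))
    X1 = rng.standard_normal((n_per_class, n_features)) + shift
    y = np.repeat([0, 1], n_per_class)
    return np.vstack([X0, X1]), y


class TestFSDD:
    def test_identical_distributions_score_zero(self):
        base = np.tile(np.arange(4, dtype=float)[:, None], (1, 3))
        X = np.vstack([base, base])  # class 1 duplicates class 0 exactly
        y = np.repeat([0, 1], 4)
        np.testing.assert_allclose(fsdd_scores(X, y), 0.0)

    def test_closed_form_two_unit_variance_classes(self):
        # |mu1 - mu2| = 2, var1 = var2 = 1 -> 2 / sqrt(2)
        base = np.array([-1.5, -0.5, 0.5, 1.5])  # mean 0, sample var 5/3
        base = base / np.sqrt(base.var(ddof=1))  # unit sample variance
        X = np.concatenate([base, base + 2.0])[:, None]
        y = np.repeat([0, 1], 4)
        assert fsdd_scores(X, y)[0] == pytest.approx(2 / np.sqrt(2))

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        X, _ = two_class_data(rng)
        with pytest.raises(ValueError):
            fsdd_scores(X, np.zeros(len(X)))

    @given(st.floats(0.1, 50.0), st.floats(-20.0, 20.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_rescaling_invariance(self, scale, offset):
        rng = np.random.default_rng(11)
        X, y = two_class_data(rng, shift=np.linspace(0, 2, 10))
        a = fsdd_scores(X, y)
        b = fsdd_scores(scale * X + offset, y)
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)

    def test_injected_shift_ranks_first(self):
        rng = np.random.default_rng(2)
        shift = np.zeros(10)
        shift[3] = 3.0
        X, y = two_class_data(rng, shift=shift)
        ranked = rank_features(X, y)
        assert ranked.indices[0] == 3


class TestTopK:
    def test_100_of_13671(self):
        rng = np.random.default_rng(3)
        X, y = two_class_data(rng, n_per_class=20, n_features=13671)
        ranked = rank_features(X, y, k=100)
        cols = select_top_k(ranked, 100)
        assert len(cols) == 100 and len(set(cols)) == 100

    def test_k_equals_n_is_identity_permutation(self):
        rng = np.random.default_rng(4)
        X, y = two_class_data(rng, n_features=12)
        ranked = rank_features(X, y)
        assert sorted(select_top_k(ranked, 12)) == list(range(12))

    def test_ties_break_by_ascending_column(self):
        ranked = RankedFeatures(indices=np.argsort(-np.zeros(5), kind="stable"),
                                scores=np.zeros(5))
        np.testing.assert_array_equal(select_top_k(ranked, 3), [0, 1, 2])
        # built through rank_features too: duplicated columns tie exactly
        rng = np.random.default_rng(5)
        col = rng.standard_normal(20)
        X = np.column_stack([col, col, col])
        y = np.repeat([0, 1], 10)
        ranked = rank_features(X, y)
        np.testing.assert_array_equal(ranked.indices, [0, 1, 2])

    def test_bad_k_rejected(self):
        rng = np.random.default_rng(6)
        X, y = two_class_data(rng, n_features=5)
        ranked = rank_features(X, y)
        with pytest.raises(ValueError):
            select_top_k(ranked, 0)
        with pytest.raises(ValueError):
            select_top_k(ranked, 6)


class TestBackends:
    def test_ttest_and_mrmr_find_the_signal(self):
        rng = np.random.default_rng(7)
        shift = np.zeros(12)
        shift[5] = 3.0
        X, y = two_class_data(rng, n_features=12, shift=shift)
        assert np.argmax(ttest_scores(X, y)) == 5
        indices, scores = mrmr_rank(X, y)
        assert indices[0] == 5
        assert np.all(np.diff(scores) <= 1e-12)
        assert sorted(indices) == list(range(12))

    def test_mrmr_penalises_redundant_copy(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal(60)
        y = np.repeat([0, 1], 30)
        signal = base + 2.0 * y
        weaker = rng.standard_normal(60) + 1.8 * y
        X = np.column_stack([signal, signal + 1e-3 * rng.standard_normal(60),
                             weaker])
        order = mrmr_rank(X, y)[0]
        # the near-duplicate of the best column must not come second
        assert order[1] == 2


class TestPooling:
    def make_rankings(self, n_participants, n_features, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_participants):
            scores = np.sort(rng.random(n_features))[::-1]
            out.append(RankedFeatures(indices=rng.permutation(n_features),
                                      scores=scores))
        return out

    def test_14_participants_top20_pool_280(self, montage63):
        desc = tuple(FeatureDescriptor("band_power", "alpha", channel=c)
                     for c in montage63.channel_names) * 6
        rankings = self.make_rankings(14, len(desc))
        pooled = pool_top_features(rankings, desc, top_n=20)
        assert len(pooled) == 280

    def test_single_participant_top1(self, montage63):
        desc = tuple(FeatureDescriptor("band_power", "alpha", channel=c)
                     for c in montage63.channel_names)
        rankings = self.make_rankings(1, len(desc), seed=1)
        pooled = pool_top_features(rankings, desc, top_n=1)
        assert len(pooled) == 1
        assert pooled[0] is desc[rankings[0].indices[0]]

    def test_tally_partitions_pool(self, montage63):
        desc = tuple(FeatureDescriptor("band_power", "alpha", channel=c)
                     for c in montage63.channel_names)
        faa_desc = (FeatureDescriptor("faa", "alpha", pair=("F3", "F4")),)
        pooled = list(desc) + list(faa_desc)
        tally = topography_tally(pooled, montage63)
        n_midline = len(montage63.channels_in("midline"))
        lateral = tally[tally["hemisphere"] != "midline"]["count"].sum()
        # lateral tally = pool size minus midline and pair-typed features
        assert lateral == len(pooled) - n_midline - len(faa_desc)
        assert tally["count"].sum() == len(pooled) - len(faa_desc)

    def test_unknown_channel_rejected(self, montage63):
        bad = (FeatureDescriptor("band_power", "alpha", channel="XX9"),)
        with pytest.raises(ValueError):
            topography_tally(bad, montage63)


class TestLeakage:
    def test_ranking_ignores_rows_outside_training_set(self):
        rng = np.random.default_rng(9)
        shift = np.linspace(0, 2, 8)
        X, y = two_class_data(rng, n_per_class=20, n_features=8, shift=shift)
        train = np.arange(0, 30)
        clean = rank_features(X[train], y[train])
        poisoned = X.copy()
        poisoned[30:] = np.nan
        dirty = rank_features(poisoned[train], y[train])
        np.testing.assert_array_equal(clean.indices, dirty.indices)
        np.testing.assert_array_equal(clean.scores, dirty.scores)
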