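"""Distances, triplet loss, the five miners and the batch sampler.

Every deterministic miner is checked against an independent brute-force
enumeration of its selection rule; the stochastic distance-weighted miner is
checked distributionally against the closed-form inverse-density weights.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mosqid.mining import (MinerConfig, PairSet, TripletSet,
                           identity_subset_stage, m_per_class_sample_batches,
                           mine_angular, mine_distance_weighted,
                           mine_multi_similarity, mine_pair_margin,
                           mine_triplet_margin, pairs_to_triplets,
                           pairwise_distances, triplet_margin_loss,
                           two_stage_mine)

from _oracles import (brute_angular_miner, brute_cosine_matrix,
                      brute_distance_matrix, brute_multi_similarity_miner,
                      brute_pair_margin_miner, brute_triplet_margin_miner,
                      inverse_density_weight)


def _batch(rng, n=10, dim=4, n_classes=3, unit=False):
    x = rng.normal(size=(n, dim))
    if unit:
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    labels = rng.integers(0, n_classes, size=n)
    return x, labels


class TestDistances:
    def test_three_four_five(self):
        d = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_identical_unit_vectors_cosine_one(self):
        v = np.array([[0.6, 0.8], [0.6, 0.8]])
        s = pairwise_distances(v, metric="cosine")
        assert s.values[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self, rng):
        x = rng.normal(size=(8, 16))
        np.testing.assert_allclose(pairwise_distances(x).values,
                                   brute_distance_matrix(x), atol=1e-9)
        np.testing.assert_allclose(
            pairwise_distances(x, metric="cosine").values,
            brute_cosine_matrix(x), atol=1e-9)

    def test_zero_vector_under_cosine_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            pairwise_distances(np.array([[0.0, 0.0], [1.0, 0.0]]),
                               metric="cosine")


class TestTripletLoss:
    def test_direct_formula(self):
        assert triplet_margin_loss(0.3, 0.2, 0.1) == pytest.approx(0.2)

    def test_hinge_clamps_to_zero(self):
        assert triplet_margin_loss(0.1, 0.5, 0.1) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            triplet_margin_loss(-0.1, 0.5, 0.1)

    def test_empty_batch_gives_zero(self):
        assert triplet_margin_loss(np.array([]), np.array([]), 0.1) == 0.0

    def test_monotonicity_in_both_distances(self):
        base = triplet_margin_loss(0.5, 0.3, 0.1)
        assert triplet_margin_loss(0.6, 0.3, 0.1) >= base
        assert triplet_margin_loss(0.5, 0.4, 0.1) <= base


class TestMinersAgainstBruteForce:
    """Exact agreement with independent enumeration on random batches."""

    def test_triplet_margin_miner(self, rng):
        for _ in range(30):
            x, labels = _batch(rng, n=int(rng.integers(4, 13)))
            got = mine_triplet_margin(x, labels,
                                      MinerConfig(kind="triplet_margin"))
            expect = brute_triplet_margin_miner(x, labels, 0.1)
            assert set(map(tuple, got.triplets)) == expect

    def test_multi_similarity_miner(self, rng):
        for _ in range(30):
            x, labels = _batch(rng, n=int(rng.integers(4, 13)))
            got = mine_multi_similarity(x, labels, epsilon=0.1)
            pos, neg = brute_multi_similarity_miner(x, labels, 0.1)
            assert set(map(tuple, got.positive_pairs)) == pos
            assert set(map(tuple, got.negative_pairs)) == neg

    def test_pair_margin_miner(self, rng):
        for _ in range(30):
            x, labels = _batch(rng, n=int(rng.integers(4, 13)))
            got = mine_pair_margin(x, labels, 0.2, 0.8)
            pos, neg = brute_pair_margin_miner(x, labels, 0.2, 0.8)
            assert set(map(tuple, got.positive_pairs)) == pos
            assert set(map(tuple, got.negative_pairs)) == neg

    def test_angular_miner(self, rng):
        for _ in range(30):
            x, labels = _batch(rng, n=int(rng.integers(4, 13)))
            got = mine_angular(x, labels, 20.0)
            expect = brute_angular_miner(x, labels, 20.0)
            assert set(map(tuple, got.triplets)) == expect


class TestMinerExamples:
    def test_margin_violation_selected(self):
        x = np.array([[0.0, 0.0], [0.3, 0.0], [0.35, 0.0]])
        labels = ["a", "a", "b"]
        got = mine_triplet_margin(x, labels)
        assert (0, 1, 2) in set(map(tuple, got.triplets))

    def test_single_label_batch_yields_nothing(self):
        got = mine_triplet_margin(np.random.default_rng(0).normal(size=(5, 2)),
                                  ["a"] * 5)
        assert len(got) == 0

    def test_multi_similarity_worked_example(self):
        # anchor 0; positives at sims 0.9 / 0.4; negatives at 0.5 / 0.2
        def vec(sim):
            return [sim, np.sqrt(1 - sim ** 2)]
        x = np.array([[1.0, 0.0], vec(0.9), vec(0.4), vec(0.5), vec(0.2)])
        labels = ["a", "a", "a", "b", "b"]
        got = mine_multi_similarity(x, labels, epsilon=0.1)
        pos0 = {p for a, p in got.positive_pairs if a == 0}
        neg0 = {n for a, n in got.negative_pairs if a == 0}
        assert pos0 == {2}   # 0.4 < 0.5 + 0.1; 0.9 is not
        assert neg0 == {3}   # 0.5 > 0.4 - 0.1; 0.2 is not

    def test_separated_clusters_mine_nothing(self):
        x = np.array([[1.0, 0.0], [0.999, 0.045], [-1.0, 0.0],
                      [-0.999, 0.045]])
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        got = mine_multi_similarity(x, ["a", "a", "b", "b"], epsilon=0.1)
        assert len(got) == 0

    def test_angular_far_negative_dropped(self):
        x = np.array([[0.0, 0.0], [0.0, 0.2], [0.0, 10.0]])
        got = mine_angular(x, ["a", "a", "b"], 20.0)
        assert (0, 1, 2) not in set(map(tuple, got.triplets))

    def test_angular_zero_threshold_keeps_all_valid(self, rng):
        x, labels = _batch(rng, n=8)
        got = mine_angular(x, labels, 0.0)
        expect = brute_angular_miner(x, labels, 0.0)
        assert set(map(tuple, got.triplets)) == expect


class TestDistanceWeighted:
    def test_requires_unit_norm(self, rng):
        x, labels = _batch(rng, n=6)
        with pytest.raises(ValueError, match="normalized"):
            mine_distance_weighted(x * 3.0, labels)

    def test_deterministic_given_seed(self, rng):
        x, labels = _batch(rng, n=10, unit=True)
        a = mine_distance_weighted(x, labels, seed=5)
        b = mine_distance_weighted(x, labels, seed=5)
        np.testing.assert_array_equal(a.triplets, b.triplets)

    def test_label_constraints(self, rng):
        x, labels = _batch(rng, n=12, unit=True)
        ts = mine_distance_weighted(x, labels, seed=1)
        for a, p, n in ts.triplets:
            assert labels[a] == labels[p] and a != p
            assert labels[a] != labels[n]

    def test_equidistant_negatives_sampled_uniformly(self):
        # anchor at e1 with two negatives at identical distance
        x = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                      [0.0, 1.0, 0.0], [0.0, -1.0, 0.0]])
        labels = ["a", "a", "b", "b"]
        picks = []
        for seed in range(400):
            ts = mine_distance_weighted(x, labels, seed=seed)
            for a, p, n in ts.triplets:
                if a == 0:
                    picks.append(n)
        frac = np.mean(np.asarray(picks) == 2)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / len(picks))

    def test_sampling_ratio_matches_inverse_density(self):
        """Two negatives at different distances: empirical pick ratio equals
        the closed-form inverse-density ratio within 3 standard errors."""
        d1, d2 = 0.8, 1.2
        # place negatives at exact chord distances d from the anchor e1
        def at_distance(d):
            c = 1 - d * d / 2.0   # cos(theta) for chord d on unit circle
            return [c, np.sqrt(1 - c * c)]
        x = np.array([[1.0, 0.0], [1.0, 0.0], at_distance(d1),
                      at_distance(d2)])
        labels = ["a", "a", "b", "b"]
        w1 = inverse_density_weight(d1, 2)
        w2 = inverse_density_weight(d2, 2)
        p_expect = w1 / (w1 + w2)
        picks = []
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            ts = mine_distance_weighted(x, labels, seed=int(rng.integers(2**31)))
            row = ts.triplets[ts.triplets[:, 0] == 0][0]
            picks.append(row[2])
        p_hat = np.mean(np.asarray(picks) == 2)
        se = np.sqrt(p_expect * (1 - p_expect) / len(picks))
        assert abs(p_hat - p_expect) < 3 * se


class TestSampler:
    def test_two_classes_per_batch_at_protocol_defaults(self):
        labels = np.repeat([f"c{i}" for i in range(5)], 20)
        batches = m_per_class_sample_batches(labels, 16, 8, seed=0)
        for batch in batches:
            classes = {labels[i] for i in batch}
            assert len(classes) == 2
            assert len(batch) == 16
            for c in classes:
                assert sum(labels[i] == c for i in batch) == 8

    def test_small_class_sampled_with_replacement(self):
        labels = np.array(["a"] * 5 + ["b"] * 20)
        batches = m_per_class_sample_batches(labels, 16, 8, seed=3,
                                             n_batches=5)
        saw_repeat = False
        for batch in batches:
            a_ids = [i for i in batch if labels[i] == "a"]
            if a_ids and len(set(a_ids)) < len(a_ids):
                saw_repeat = True
        assert saw_repeat

    def test_fixed_seed_reproduces_sequence(self):
        labels = np.repeat(list("abcd"), 10)
        b1 = m_per_class_sample_batches(labels, 8, 4, seed=2, n_batches=6)
        b2 = m_per_class_sample_batches(labels, 8, 4, seed=2, n_batches=6)
        for x, y in zip(b1, b2):
            np.testing.assert_array_equal(x, y)

    def test_indivisible_batch_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            m_per_class_sample_batches(np.array(["a", "b"]), 10, 4)


class TestTwoStage:
    def test_identity_subset_reproduces_plain_miner(self, rng):
        x, labels = _batch(rng, n=10)
        cfg = MinerConfig(kind="triplet_margin")
        plain = mine_triplet_margin(x, labels, cfg)
        staged = two_stage_mine(x, labels, cfg,
                                subset_stage=identity_subset_stage)
        assert set(map(tuple, plain.triplets)) == \
            set(map(tuple, staged.triplets))

    def test_subset_indices_map_back_to_full_batch(self, rng):
        x, labels = _batch(rng, n=12)
        cfg = MinerConfig(kind="triplet_margin")

        def drop_first_two(e, l):
            return np.arange(2, len(l))

        staged = two_stage_mine(x, labels, cfg, subset_stage=drop_first_two)
        assert len(staged) == len(mine_triplet_margin(x[2:], labels[2:], cfg))
        if len(staged):
            assert staged.triplets.min() >= 2


class TestPairConversion:
    def test_pairs_join_on_shared_anchor(self):
        pairs = PairSet(positive_pairs=[(0, 1), (2, 3)],
                        negative_pairs=[(0, 4), (0, 5), (9, 4)])
        ts = pairs_to_triplets(pairs)
        assert set(map(tuple, ts.triplets)) == {(0, 1, 4), (0, 1, 5)}


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_mined_tuples_always_satisfy_label_constraints(seed):
    rng = np.random.default_rng(seed)
    x, labels = _batch(rng, n=int(rng.integers(4, 13)))
    ts = mine_triplet_margin(x, labels, MinerConfig(kind="triplet_margin"))
    for a, p, n in ts.triplets:
        assert labels[a] == labels[p] and a != p and labels[a] != labels[n]
    ps = mine_multi_similarity(x, labels)
    for a, p in ps.positive_pairs:
        assert labels[a] == labels[p] and a != p
    for a, n in ps.negative_pairs:
        assert labels[a] != labels[n]
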