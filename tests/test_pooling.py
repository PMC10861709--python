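import numpy as np
import pytest

from rbp import nn
from rbp.pooling import (
    ContinuousScorer,
    RocketKernelSet,
    attention_pool,
    average_pool,
    compute_search_embedding,
    continuous_attention_pool,
    head_region_attention_pool,
    rocket_features,
    rocket_transform,
    sample_rocket_kernels,
    score_channels_linear,
)


def brute_force_rocket(signal, kernels):
    """Independent oracle: explicit dilated valid-mode convolution loops."""
    ppv, mx = [], []
    for i in range(kernels.num_kernels):
        w = kernels.weights[i]
        d = int(kernels.dilations[i])
        L = len(w)
        n_out = len(signal) - (L - 1) * d
        fmap = np.array(
            [
                sum(w[m] * signal[t + m * d] for m in range(L)) + kernels.biases[i]
                for t in range(n_out)
            ]
        )
        ppv.append((fmap > 0).mean())
        mx.append(fmap.max())
    return np.array(ppv + mx)


class TestRocketKernels:
    def test_receptive_field_bound(self, rng):
        ks = sample_rocket_kernels(200, 250, rng)
        assert np.all(ks.receptive_fields() <= 250)
        assert set(ks.lengths) <= {7, 9, 11}

    def test_weights_mean_centered(self, rng):
        ks = sample_rocket_kernels(50, 100, rng)
        for w in ks.weights:
            assert abs(w.mean()) < 1e-12

    def test_dilations_are_powers_of_two(self, rng):
        ks = sample_rocket_kernels(100, 250, rng)
        assert np.all(np.bitwise_and(ks.dilations, ks.dilations - 1) == 0)

    def test_same_seed_bitwise_identical(self):
        a = sample_rocket_kernels(30, 120, np.random.default_rng(9))
        b = sample_rocket_kernels(30, 120, np.random.default_rng(9))
        assert a.to_dict() == b.to_dict()

    def test_bound_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_rocket_kernels(10, 9, rng)


class TestRocketTransform:
    def test_zero_signal_positive_bias(self):
        ks = RocketKernelSet(
            np.array([7]),
            (np.zeros(7),),
            np.array([0.5]),
            np.array([1]),
            250,
        )
        feats = rocket_transform(np.zeros(100), ks)
        np.testing.assert_allclose(feats, [1.0, 0.5])

    def test_zero_signal_zero_bias_strict_positivity(self):
        ks = RocketKernelSet(
            np.array([7]), (np.zeros(7),), np.array([0.0]), np.array([1]), 250
        )
        np.testing.assert_allclose(rocket_transform(np.zeros(50), ks), [0.0, 0.0])

    def test_hand_convolution(self):
        # signal (1,-1,2), weights (1,1) -> feature map (0,1): PPV 0.5, max 1
        ks = RocketKernelSet(
            np.array([2]),
            (np.array([1.0, 1.0]),),
            np.array([0.0]),
            np.array([1]),
            250,
        )
        np.testing.assert_allclose(
            rocket_transform(np.array([1.0, -1.0, 2.0]), ks), [0.5, 1.0]
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            ks = sample_rocket_kernels(8, 60, rng)
            sig = rng.normal(size=80)
            np.testing.assert_array_equal(
                rocket_transform(sig, ks), brute_force_rocket(sig, ks)
            )

    def test_short_signal_rejected(self, rng):
        ks = sample_rocket_kernels(20, 250, rng)
        with pytest.raises(ValueError, match="shorter"):
            rocket_transform(np.zeros(10), ks)

    def test_features_constant_per_channel(self, rng):
        ks = sample_rocket_kernels(10, 60, rng)
        X = rng.normal(size=(4, 100))
        f1 = rocket_features(X, ks)
        f2 = np.stack([rocket_transform(x, ks) for x in X])
        np.testing.assert_array_equal(f1, f2)


class TestAveragePool:
    def test_single_channel_identity(self, rng):
        x = rng.normal(size=(1, 50))
        np.testing.assert_array_equal(average_pool(x), x[0])

    def test_antisymmetric_channels_cancel(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(
            average_pool(np.stack([x, -x])), np.zeros(50), atol=1e-15
        )

    def test_matches_timestep_loop(self, rng):
        X = rng.normal(size=(5, 30))
        expected = np.array([X[:, t].mean() for t in range(30)])
        np.testing.assert_allclose(average_pool(X), expected, atol=1e-15)


class TestLinearScoring:
    def test_zero_weights_zero_scores(self, rng):
        Z = rng.normal(size=(4, 10))
        np.testing.assert_array_equal(score_channels_linear(Z, np.zeros(10)), np.zeros(4))

    def test_unit_vector_selects_feature(self, rng):
        Z = rng.normal(size=(4, 10))
        e3 = np.eye(10)[3]
        np.testing.assert_array_equal(score_channels_linear(Z, e3), Z[:, 3])

    def test_matches_brute_force_dot(self, rng):
        Z = rng.normal(size=(3, 8))
        w = rng.normal(size=8)
        expected = [sum(w[d] * Z[k, d] for d in range(8)) for k in range(3)]
        np.testing.assert_allclose(score_channels_linear(Z, w), expected, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            score_channels_linear(rng.normal(size=(3, 8)), np.zeros(9))


class TestAttentionPool:
    def test_equal_scores_equal_average(self, rng):
        X = rng.normal(size=(6, 40))
        rep, a = attention_pool(X, np.full(6, 3.7))
        np.testing.assert_allclose(rep, average_pool(X), atol=1e-12)
        np.testing.assert_allclose(a, np.full(6, 1 / 6), atol=1e-12)

    def test_closed_form_softmax(self, rng):
        X = rng.normal(size=(2, 10))
        rep, a = attention_pool(X, np.array([np.log(2.0), 0.0]))
        np.testing.assert_allclose(a, [2 / 3, 1 / 3], atol=1e-12)
        np.testing.assert_allclose(rep, 2 / 3 * X[0] + 1 / 3 * X[1], atol=1e-12)

    def test_single_channel(self, rng):
        X = rng.normal(size=(1, 10))
        rep, a = attention_pool(X, np.array([0.42]))
        np.testing.assert_array_equal(a, [1.0])
        np.testing.assert_allclose(rep, X[0], atol=1e-15)

    def test_non_finite_score_rejected(self, rng):
        with pytest.raises(ValueError):
            attention_pool(rng.normal(size=(2, 5)), np.array([np.nan, 0.0]))

    def test_attention_sums_to_one_and_positive(self, rng):
        for _ in range(20):
            X = rng.normal(size=(5, 8))
            _, a = attention_pool(X, rng.normal(scale=5, size=5))
            assert abs(a.sum() - 1.0) < 1e-6
            assert np.all(a > 0)


class TestContinuousAttentionPool:
    def test_constant_scores_equal_average(self, rng):
        X = rng.normal(size=(4, 30))
        rep, _ = continuous_attention_pool(X, np.zeros_like(X))
        np.testing.assert_allclose(rep, average_pool(X), atol=1e-12)

    def test_columns_sum_to_one(self, rng):
        X = rng.normal(size=(4, 30))
        _, A = continuous_attention_pool(X, rng.normal(size=(4, 30)))
        np.testing.assert_allclose(A.sum(axis=0), np.ones(30), atol=1e-6)

    def test_attention_tracks_scored_channel(self, rng):
        X = rng.normal(size=(2, 20))
        S = np.zeros((2, 20))
        S[0, :10] = 10.0
        S[1, 10:] = 10.0
        rep, A = continuous_attention_pool(X, S)
        assert np.all(A[0, :10] > 0.95) and np.all(A[1, 10:] > 0.95)
        np.testing.assert_allclose(rep[:10], X[0, :10], atol=0.3)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            continuous_attention_pool(rng.normal(size=(2, 5)), rng.normal(size=(2, 6)))


class TestContinuousScorer:
    def test_output_shape_and_channel_independence(self, rng):
        scorer = ContinuousScorer(rng)
        scorer.set_training(False)
        X = rng.normal(size=(3, 64))
        S = scorer(X)
        assert S.shape == X.shape
        # identical channels get identical score rows
        X2 = np.vstack([X[0], X[0]])
        S2 = scorer(X2)
        np.testing.assert_allclose(S2[0], S2[1], atol=1e-12)

    def test_permuting_channels_permutes_scores(self, rng):
        scorer = ContinuousScorer(rng)
        scorer.set_training(False)
        X = rng.normal(size=(4, 64))
        perm = [2, 0, 3, 1]
        np.testing.assert_allclose(scorer(X[perm]), scorer(X)[perm], atol=1e-12)


class TestSearchEmbedding:
    def test_single_channel_degenerate_softmax(self, rng):
        Z = rng.normal(size=(6, 1))
        W1 = rng.normal(size=(4, 6))
        W2 = rng.normal(size=(4, 6))
        s = compute_search_embedding(Z, W1, W2)
        np.testing.assert_allclose(s, (W1 @ Z)[:, 0], atol=1e-12)

    def test_zero_gate_gives_row_means(self, rng):
        Z = rng.normal(size=(6, 3))
        W1 = rng.normal(size=(4, 6))
        s = compute_search_embedding(Z, W1, np.zeros((4, 6)))
        np.testing.assert_allclose(s, (W1 @ Z).mean(axis=1), atol=1e-12)

    def test_matches_explicit_loops(self, rng):
        Z = rng.normal(size=(5, 2))
        W1 = rng.normal(size=(3, 5))
        W2 = rng.normal(size=(3, 5))
        F1, F2 = W1 @ Z, W2 @ Z
        expected = np.zeros(3)
        for d in range(3):
            g = np.exp(F2[d] - F2[d].max())
            g = g / g.sum()
            expected[d] = sum(F1[d, c] * g[c] for c in range(2))
        np.testing.assert_allclose(
            compute_search_embedding(Z, W1, W2), expected, atol=1e-10
        )


class TestHeadRegionPool:
    def test_single_channel(self, rng):
        X = rng.normal(size=(1, 10))
        Z = rng.normal(size=(6, 1))
        W1 = rng.normal(size=(4, 6))
        s = rng.normal(size=4)
        rep, a = head_region_attention_pool(X, Z, s, W1)
        np.testing.assert_allclose(a, [1.0], atol=1e-12)
        np.testing.assert_allclose(rep, X[0], atol=1e-12)

    def test_identical_features_uniform_attention(self, rng):
        z = rng.normal(size=6)
        Z = np.stack([z, z, z], axis=1)
        X = rng.normal(size=(3, 10))
        W1 = rng.normal(size=(4, 6))
        rep, a = head_region_attention_pool(X, Z, rng.normal(size=4), W1)
        np.testing.assert_allclose(a, np.full(3, 1 / 3), atol=1e-10)
        np.testing.assert_allclose(rep, average_pool(X), atol=1e-10)

    def test_aligned_and_antialigned_embeddings(self, rng):
        # e_1 = s and e_2 = -s -> a = softmax(1, -1)
        W1 = np.eye(3)
        s = np.array([1.0, 2.0, 2.0])
        Z = np.stack([s, -s], axis=1)
        X = rng.normal(size=(2, 5))
        _, a = head_region_attention_pool(X, Z, s, W1)
        e2 = np.exp(2.0)
        np.testing.assert_allclose(a, [e2 / (e2 + 1), 1 / (e2 + 1)], atol=1e-9)

    def test_matches_explicit_loop_oracle(self, rng):
        for _ in range(5):
            C, F, d, T = 4, 7, 3, 12
            X = rng.normal(size=(C, T))
            Z = rng.normal(size=(F, C))
            W1 = rng.normal(size=(d, F))
            s = rng.normal(size=d)
            cos = np.array(
                [
                    np.dot(W1 @ Z[:, k], s)
                    / (np.linalg.norm(W1 @ Z[:, k]) * np.linalg.norm(s))
                    for k in range(C)
                ]
            )
            e = np.exp(cos - cos.max())
            a_expected = e / e.sum()
            rep_expected = a_expected @ X
            rep, a = head_region_attention_pool(X, Z, s, W1)
            np.testing.assert_allclose(a, a_expected, atol=1e-10)
            np.testing.assert_allclose(rep, rep_expected, atol=1e-10)

    def test_zero_norm_embedding_warns(self, rng, caplog):
        import logging

        X = rng.normal(size=(2, 5))
        Z = np.zeros((6, 2))
        W1 = rng.normal(size=(4, 6))
        with caplog.at_level(logging.WARNING, logger="rbp.pooling"):
            _, a = head_region_attention_pool(X, Z, rng.normal(size=4), W1)
        assert "zero-norm" in caplog.text
        np.testing.assert_allclose(a, [0.5, 0.5], atol=1e-12)


class TestPoolingInvariants:
    @pytest.mark.parametrize("n_channels", [2, 5, 9])
    def test_outputs_in_convex_hull(self, rng, n_channels):
        X = rng.normal(size=(n_channels, 25))
        reps = [average_pool(X)]
        reps.append(attention_pool(X, rng.normal(size=n_channels))[0])
        reps.append(
            continuous_attention_pool(X, rng.normal(size=X.shape))[0]
        )
        lo, hi = X.min(axis=0), X.max(axis=0)
        for rep in reps:
            assert np.all(rep >= lo - 1e-10) and np.all(rep <= hi + 1e-10)

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(6, 20))
        Z = rng.normal(size=(6, 14))  # rocket features per channel
        w = rng.normal(size=14)
        perm = rng.permutation(6)
        rep1, _ = attention_pool(X, score_channels_linear(Z, w))
        rep2, _ = attention_pool(X[perm], score_channels_linear(Z[perm], w))
        np.testing.assert_allclose(rep1, rep2, atol=1e-12)

    def test_equal_scores_scale_invariant(self, rng):
        # regression guard: no hidden temperature in the softmax
        X = rng.normal(size=(4, 15))
        for scale in (1.0, 100.0):
            rep, a = attention_pool(X, np.full(4, scale))
            np.testing.assert_allclose(a, np.full(4, 0.25), atol=1e-12)
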