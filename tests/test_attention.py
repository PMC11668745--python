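"""Attention mechanism, multi-head forward pass, training behavior."""

import numpy as np
import pytest

from fcnfusion.attention import (
    AttnConfig,
    SelfAttentionClassifier,
    attention_distribution,
    multi_head_forward,
    scaled_attention,
    train_and_extract,
)


def loop_forward(model, x):
    """Unvectorized reference forward pass (scalar/loop arithmetic)."""
    p = model.params
    H, dk, D = model.cfg.n_heads, model.cfg.d_k, model.cfg.model_width
    R = x.shape[0]
    T0 = x @ p["W_in"] + p["b_in"]
    heads = []
    weights = []
    for h in range(H):
        sl = slice(h * dk, (h + 1) * dk)
        Q, K, V = T0 @ p["W_q"][:, sl], T0 @ p["W_k"][:, sl], T0 @ p["W_v"][:, sl]
        W = np.zeros((R, R))
        for i in range(R):
            scores = np.array([Q[i] @ K[j] / np.sqrt(dk) for j in range(R)])
            e = np.exp(scores - scores.max())
            W[i] = e / e.sum()
        weights.append(W)
        heads.append(W @ V)
    O = np.concatenate(heads, axis=1)
    O2 = O @ p["W_o"] + p["b_o"]
    Hh = np.maximum(O2 @ p["W_1"] + p["b_1"], 0.0)
    pooled = Hh.mean(axis=0)
    return pooled @ p["W_2"] + p["b_2"], np.array(weights)


class TestScaledAttention:
    def test_zero_queries_give_uniform_rows(self):
        R = 5
        W, out = scaled_attention(np.zeros((R, 2)), np.ones((R, 2)),
                                  np.eye(R, 2), d_k=2)
        np.testing.assert_allclose(W, np.full((R, R), 1 / R))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        W, _ = scaled_attention(*rng.standard_normal((3, 6, 4)), d_k=4)
        np.testing.assert_allclose(W.sum(axis=-1), 1.0, atol=1e-12)

    def test_matches_scalar_hand_computation(self):
        Q, K, V = [[1.0], [0.0]], [[1.0], [0.0]], [[1.0], [2.0]]
        W, out = scaled_attention(Q, K, V, d_k=1)
        e = np.exp([1.0, 0.0])
        row0 = e / e.sum()                    # scores [1, 0]
        row1 = np.array([0.5, 0.5])           # scores [0, 0]
        np.testing.assert_allclose(W, [row0, row1], atol=1e-12)
        np.testing.assert_allclose(
            out, [[row0[0] + 2 * row0[1]], [1.5]], atol=1e-12
        )

    def test_invalid_dk_rejected(self):
        with pytest.raises(ValueError, match="d_k"):
            scaled_attention(np.ones((2, 1)), np.ones((2, 1)), np.ones((2, 1)), 0)


class TestMultiHead:
    def test_matches_loop_oracle(self):
        cfg = AttnConfig(n_heads=2, d_k=1, dropout=0.0, seed=5)
        model = SelfAttentionClassifier(3, cfg)
        x = np.random.default_rng(1).standard_normal((3, 3))
        logits, per_head = multi_head_forward(x, model)
        ref_logits, ref_weights = loop_forward(model, x)
        np.testing.assert_allclose(logits, ref_logits, atol=1e-10)
        np.testing.assert_allclose(per_head, ref_weights, atol=1e-10)

    def test_head_count_and_shapes(self):
        cfg = AttnConfig(n_heads=4, d_k=2, seed=0)
        model = SelfAttentionClassifier(6, cfg)
        _, per_head = multi_head_forward(np.eye(6), model)
        assert per_head.shape == (4, 6, 6)

    def test_permutation_equivariance_of_weights(self):
        # reordering tokens permutes attention weights conjugately
        cfg = AttnConfig(n_heads=3, d_k=2, dropout=0.0, seed=2)
        model = SelfAttentionClassifier(5, cfg)
        x = np.random.default_rng(3).standard_normal((5, 5))
        perm = np.array([3, 0, 4, 1, 2])
        _, W = multi_head_forward(x, model)
        _, Wp = multi_head_forward(x[perm], model)
        np.testing.assert_allclose(Wp, W[:, perm][:, :, perm], atol=1e-12)

    def test_shape_mismatch_rejected(self):
        model = SelfAttentionClassifier(4, AttnConfig(n_heads=2, d_k=2))
        with pytest.raises(ValueError, match="expected"):
            model.forward(np.ones((3, 3)))


class TestAttentionDistribution:
    def test_single_head_identity(self):
        W = np.random.default_rng(4).dirichlet(np.ones(4), size=4)
        np.testing.assert_array_equal(attention_distribution([W]), W)

    def test_uniform_heads_stay_uniform(self):
        W = np.full((3, 5, 5), 0.2)
        np.testing.assert_allclose(attention_distribution(W), 0.2)

    def test_mean_is_row_stochastic(self):
        rng = np.random.default_rng(5)
        heads = rng.dirichlet(np.ones(6), size=(8, 6))
        attnM = attention_distribution(heads)
        np.testing.assert_allclose(attnM.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_heads_rejected(self):
        with pytest.raises(ValueError, match="head"):
            attention_distribution(np.empty((0, 3, 3)))


class TestTraining:
    def test_separable_cohort_high_accuracy(self, separable_cv):
        cv_accuracy, matrices = separable_cv
        assert cv_accuracy >= 0.9
        assert len(matrices) == 30

    def test_extracted_matrices_row_stochastic(self, separable_cv):
        _, matrices = separable_cv
        for m in matrices:
            assert np.abs(m.values.sum(axis=1) - 1.0).max() < 1e-5
            assert m.values.min() >= 0.0

    def test_loss_decreases_on_separable_data(self, separable_inputs,
                                              separable_cohort):
        X = np.stack([cm.values for cm in separable_inputs])
        y = np.array([0 if ts.group == "A" else 1 for ts in separable_cohort])
        cfg = AttnConfig(n_heads=8, d_k=2, dropout=0.9, max_epochs=15,
                         patience=15, seed=9)
        model = SelfAttentionClassifier(X.shape[1], cfg)
        history = model.fit(X, y, rng=np.random.default_rng(9))
        assert min(history[1:]) < history[0]
        assert history[-1] < history[0]

    def test_fixed_seed_reproducible(self, separable_inputs, separable_cohort):
        groups = [ts.group for ts in separable_cohort]
        cfg = AttnConfig(n_heads=4, d_k=2, max_epochs=5, cv_folds=3, seed=17)
        acc1, mats1 = train_and_extract(separable_inputs, groups, cfg)
        acc2, mats2 = train_and_extract(separable_inputs, groups, cfg)
        assert acc1 == acc2
        for a, b in zip(mats1, mats2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_single_class_rejected(self, separable_inputs):
        cfg = AttnConfig(cv_folds=2)
        with pytest.raises(ValueError, match="two groups"):
            train_and_extract(separable_inputs, ["A"] * 30, cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            AttnConfig(dropout=1.0)
        with pytest.raises(ValueError):
            AttnConfig(cv_folds=1)

    def test_default_config_matches_reference_settings(self):
        cfg = AttnConfig()
        assert (cfg.n_heads, cfg.d_k) == (128, 2)
        assert cfg.model_width == 256
        assert (cfg.batch_size, cfg.dropout, cfg.learning_rate) == (8, 0.9, 0.01)
        assert cfg.cv_folds == 10
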