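"""Additive-attention tests, anchored by a naive straight-line oracle.

The oracle below re-derives each head's output with explicit per-token
loops and no shared code with the vectorized implementation: score each
query against w_q, softmax, pool the global query, modulate keys, score
against w_k, pool the global key, modulate values, affine transform,
residual to the query.
"""

import numpy as np
import pytest

from tweetformer.attention import (
    AttentionHeadParams,
    additive_pool,
    encoder_forward,
    ewma_update,
    head_forward,
    init_encoder_params,
    stack_heads,
    stacked_backward,
    stacked_forward,
)


def oracle_head(E, h: AttentionHeadParams, mask=None):
    """Independent per-token transcription of one attention head."""
    N = E.shape[0]
    d_h = h.d_h
    m = np.ones(N) if mask is None else np.asarray(mask, dtype=float)
    Q = [E[i] @ h.Wq_proj for i in range(N)]
    K = [E[i] @ h.Wk_proj for i in range(N)]
    V = [E[i] @ h.Wv_proj for i in range(N)]
    exps = [np.exp(h.w_q @ Q[i] / np.sqrt(d_h)) if m[i] else 0.0 for i in range(N)]
    alpha = [e / sum(exps) for e in exps]
    q_global = sum(alpha[i] * Q[i] for i in range(N))
    P = [q_global * K[i] for i in range(N)]
    exps2 = [np.exp(h.w_k @ P[i] / np.sqrt(d_h)) if m[i] else 0.0 for i in range(N)]
    beta = [e / sum(exps2) for e in exps2]
    k_global = sum(beta[i] * P[i] for i in range(N))
    out = np.empty((N, d_h))
    for i in range(N):
        u = k_global * V[i]
        r = h.Wr.T @ u + h.br
        out[i] = r + Q[i]
    return np.array(alpha), np.array(beta), out


def random_head(rng, d_model, d_h):
    return AttentionHeadParams(
        Wq_proj=rng.standard_normal((d_model, d_h)),
        Wk_proj=rng.standard_normal((d_model, d_h)),
        Wv_proj=rng.standard_normal((d_model, d_h)),
        w_q=rng.standard_normal(d_h),
        w_k=rng.standard_normal(d_h),
        Wr=rng.standard_normal((d_h, d_h)),
        br=rng.standard_normal(d_h),
    )


class TestAdditivePool:
    def test_singleton(self):
        x = np.array([[1.0, 2.0]])
        w, pooled = additive_pool(x, np.array([0.3, -0.4]))
        np.testing.assert_allclose(w, [1.0])
        np.testing.assert_allclose(pooled, x[0])

    def test_zero_scoring_vector_gives_uniform_mean(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 3))
        w, pooled = additive_pool(X, np.zeros(3))
        np.testing.assert_allclose(w, np.full(5, 0.2))
        np.testing.assert_allclose(pooled, X.mean(axis=0))

    def test_matches_handwritten_softmax_sum(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((3, 4))
        v = rng.standard_normal(4)
        w, pooled = additive_pool(X, v)
        logits = [v @ x / np.sqrt(4) for x in X]
        exps = [np.exp(l) for l in logits]
        expected_w = [e / sum(exps) for e in exps]
        np.testing.assert_allclose(w, expected_w, atol=1e-10)
        np.testing.assert_allclose(pooled, sum(wi * xi for wi, xi in zip(expected_w, X)), atol=1e-10)

    def test_masked_positions_excluded(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((4, 3))
        w, pooled = additive_pool(X, rng.standard_normal(3), mask=[1, 1, 0, 0])
        assert w[2] == w[3] == 0.0
        assert abs(w.sum() - 1.0) < 1e-12

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError, match="empty sequence"):
            additive_pool(np.ones((2, 2)), np.ones(2), mask=[0, 0])

    def test_logit_shift_invariance(self):
        """Adding a constant to every logit leaves the weights unchanged:
        score with w vs score with inputs shifted along a direction
        orthogonal contributions cancel in softmax."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 3))
        v = rng.standard_normal(3)
        w1, _ = additive_pool(X, v)
        shift = rng.standard_normal(3)
        # shifting all rows by the same vector adds a constant to all logits
        w2, _ = additive_pool(X + shift, v)
        np.testing.assert_allclose(w1, w2, atol=1e-10)


class TestHeadForward:
    def test_zero_input_zero_output(self):
        rng = np.random.default_rng(0)
        h = random_head(rng, 5, 3)
        h.br[:] = 0.0
        out = head_forward(np.zeros((4, 5)), h)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            N = int(rng.integers(1, 9))
            d_model = int(rng.integers(2, 7))
            d_h = int(rng.integers(1, 5))
            E = rng.standard_normal((N, d_model))
            h = random_head(rng, d_model, d_h)
            mask = None
            if N > 1 and rng.random() < 0.5:
                mask = np.ones(N)
                mask[int(rng.integers(1, N)) :] = 0.0
            _, _, expected = oracle_head(E, h, mask)
            got = head_forward(E, h, mask)
            np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        E = rng.standard_normal((5, 4))
        h = random_head(rng, 4, 3)
        perm = rng.permutation(5)
        np.testing.assert_allclose(head_forward(E, h)[perm], head_forward(E[perm], h), atol=1e-10)


class TestEncoderForward:
    def test_single_head_identity_projection_reduces_to_head(self):
        rng = np.random.default_rng(4)
        params = init_encoder_params(rng, d_model=3, n_heads=1, d_h=3, dtype=np.float64)
        params.output_projection[:] = np.eye(3)
        params.output_bias[:] = 0.0
        E = rng.standard_normal((4, 3))
        np.testing.assert_allclose(encoder_forward(E, params), head_forward(E, params.heads[0]), atol=1e-12)

    def test_output_shape_is_model_width(self):
        rng = np.random.default_rng(5)
        params = init_encoder_params(rng, d_model=6, n_heads=4, d_h=2, dtype=np.float64)
        for N in (1, 3, 10):
            assert encoder_forward(rng.standard_normal((N, 6)), params).shape == (N, 6)

    def test_alpha_beta_are_probability_vectors(self):
        rng = np.random.default_rng(6)
        params = init_encoder_params(rng, d_model=4, n_heads=3, d_h=2, dtype=np.float64)
        sp = stack_heads(params)
        E = rng.standard_normal((2, 7, 4))
        mask = np.array([[1] * 7, [1, 1, 1, 1, 0, 0, 0]], dtype=float)
        _, cache = stacked_forward(E, sp, mask)
        for probs in (cache["alpha"], cache["beta"]):
            assert np.all(probs >= 0)
            np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-12)
            assert np.all(probs[1, :, 4:] == 0.0)

    def test_operation_count_grows_linearly(self):
        rng = np.random.default_rng(7)
        params = init_encoder_params(rng, d_model=300, n_heads=16, d_h=32, dtype=np.float64)
        counts = {}
        for N in (64, 128):
            counter = {}
            encoder_forward(rng.standard_normal((N, 300)), params, counter=counter)
            counts[N] = counter["mults"]
        assert counts[128] / counts[64] <= 2.2


def test_gradients_match_finite_differences():
    rng = np.random.default_rng(11)
    params = init_encoder_params(rng, d_model=5, n_heads=2, d_h=3, dtype=np.float64)
    sp = stack_heads(params)
    B, T = 2, 4
    E = rng.standard_normal((B, T, 5))
    mask = np.array([[1, 1, 1, 1], [1, 1, 1, 0]], dtype=float)
    W = rng.standard_normal((B, T, 5))

    def loss():
        Y, _ = stacked_forward(E, sp, mask)
        return float((Y * W).sum())

    _, cache = stacked_forward(E, sp, mask)
    grads, dE = stacked_backward(cache, W.copy())
    eps = 1e-6
    for name in ("Wq", "Wk", "Wv", "wq", "wk", "Wr", "br", "Wout", "bout"):
        arr, g = sp[name], grads[name]
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = loss()
            arr[idx] = orig - eps
            lm = loss()
            arr[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - g[idx]) <= 1e-4 * max(1.0, abs(num), abs(g[idx]))
    idx = (1, 2, 3)
    orig = E[idx]
    E[idx] = orig + eps
    lp = loss()
    E[idx] = orig - eps
    lm = loss()
    E[idx] = orig
    assert abs((lp - lm) / (2 * eps) - dE[idx]) < 1e-6


class TestEwma:
    def test_first_step_from_zero_buffer(self):
        np.testing.assert_allclose(ewma_update(np.zeros(2), np.ones(2), 0.8), [0.2, 0.2])

    def test_fixed_point(self):
        g = np.array([0.3, -1.2])
        np.testing.assert_allclose(ewma_update(g.copy(), g, 0.8), g)

    def test_geometric_convergence_to_constant_gradient(self):
        g = np.array([2.0, -3.0])
        buf = np.zeros(2)
        for t in range(1, 51):
            buf = ewma_update(buf, g, 0.8)
            np.testing.assert_allclose(buf, g * (1 - 0.8**t), rtol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ewma_update(np.zeros(2), np.zeros(3), 0.8)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            ewma_update(np.zeros(2), np.zeros(2), 1.0)
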