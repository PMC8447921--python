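"""Model contracts: normalization, attention scoring, the full forward pass
against a hand-rolled scalar oracle, the loss, and gradient checks."""

import numpy as np
import pytest

from ardsight.autodiff import Tensor
from ardsight.features import N_ROWS, N_STEPS
from ardsight.model import (
    ModelConfig,
    ModelParams,
    attention_score,
    forward,
    forward_batch,
    load_checkpoint,
    multitask_loss,
    normalize,
    save_checkpoint,
)

TINY = ModelConfig(
    n_features=6, n_steps=5, hidden_size=3, attn_dim=4, penultimate_dim=4, seed=7
)


class TestNormalize:
    def test_v_equals_mu_returns_b(self, rng):
        mu = rng.normal(size=5)
        b = rng.normal(size=5)
        out = normalize(mu.copy(), mu, np.ones(5), rng.normal(size=5), b)
        np.testing.assert_allclose(out.data, b, atol=1e-12)

    def test_epsilon_in_denominator(self):
        out = normalize(
            np.array([2.0]), np.zeros(1), np.ones(1), np.ones(1), np.zeros(1)
        )
        assert out.data[0] == pytest.approx(2.0 / (1.0 + 1e-7))

    def test_matches_scalar_loop(self, rng):
        v, mu, a, b = (rng.normal(size=8) for _ in range(4))
        sigma = np.abs(rng.normal(size=8)) + 0.1
        out = normalize(v, mu, sigma, a, b)
        for i in range(8):  # elementwise hand evaluation
            expected = a[i] * ((v[i] - mu[i]) / (sigma[i] + 1e-7)) + b[i]
            assert out.data[i] == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            normalize(np.zeros(3), np.zeros(4), np.ones(4), np.ones(4), np.zeros(4))


def _scalar_score(l, h, params):
    """Independent scalar-loop evaluation of the attention scorer."""
    cfg = params.config
    lh = np.concatenate([l, h])
    mu = params["norm_attn_mu"].data
    sig = params["norm_attn_sigma"].data
    a = params["norm_attn_a"].data
    b = params["norm_attn_b"].data
    n = np.array(
        [a[i] * ((lh[i] - mu[i]) / (sig[i] + cfg.eps)) + b[i] for i in range(lh.size)]
    )
    B = params["attn_B"].data
    u = np.array([sum(n[i] * B[i, j] for i in range(n.size)) for j in range(B.shape[1])])
    slope = float(params["attn_slope"].data)
    p = np.array([x if x > 0 else slope * x for x in u])
    A = params["attn_A"].data
    v = np.array([sum(p[i] * A[i, j] for i in range(p.size)) for j in range(A.shape[1])])
    t = np.tanh(v)
    K = params["attn_K"].data[:, 0]
    return float(sum(t[i] * K[i] for i in range(t.size)))


class TestAttentionScore:
    def test_zero_K_gives_zero(self, rng):
        params = ModelParams(TINY)
        params["attn_K"].data[:] = 0.0
        l, h = rng.normal(size=3), rng.normal(size=3)
        assert attention_score(l, h, params).data == 0.0

    def test_identity_pathway_hand_checkable(self):
        cfg = ModelConfig(
            n_features=6, n_steps=5, hidden_size=3, attn_dim=6, penultimate_dim=4
        )
        params = ModelParams(cfg)
        params["attn_B"].data[:] = np.eye(6)
        params["attn_A"].data[:] = np.eye(6)
        params["attn_K"].data[:] = 0.0
        params["attn_K"].data[0, 0] = 1.0
        for name, val in (("mu", 0.0), ("sigma", 1.0), ("a", 1.0), ("b", 0.0)):
            params[f"norm_attn_{name}"].data[:] = val
        l = np.array([0.5, -1.0, 2.0])
        h = np.array([0.3, 0.0, -0.7])
        n0 = l[0] / (1.0 + cfg.eps)
        expected = np.tanh(n0 if n0 > 0 else 0.25 * n0)
        assert attention_score(l, h, params).data == pytest.approx(expected, rel=1e-12)

    def test_matches_scalar_loop_over_sequence(self, rng):
        params = ModelParams(TINY)
        l = rng.normal(size=3)
        for _ in range(3):
            h = rng.normal(size=3)
            expected = _scalar_score(l, h, params)
            assert attention_score(l, h, params).data == pytest.approx(expected, rel=1e-9)

    def test_dimension_mismatch(self, rng):
        params = ModelParams(TINY)
        with pytest.raises(ValueError):
            attention_score(rng.normal(size=4), rng.normal(size=3), params)


def _scalar_forward(mat, params):
    """Hand-rolled scalar recurrence oracle for the whole network."""
    cfg = params.config
    H = cfg.hidden_size
    T = cfg.n_steps

    def norm_in(v):
        mu = params["norm_in_mu"].data
        sig = params["norm_in_sigma"].data
        a = params["norm_in_a"].data
        b = params["norm_in_b"].data
        return a * (v - mu) / (sig + cfg.eps) + b

    def gru(seq, layer):
        h = np.zeros(H)
        out = []
        for x in seq:
            z = 1 / (1 + np.exp(-(
                x @ params[f"gru{layer}_Wxz"].data + params[f"gru{layer}_bxz"].data
                + h @ params[f"gru{layer}_Whz"].data + params[f"gru{layer}_bhz"].data
            )))
            r = 1 / (1 + np.exp(-(
                x @ params[f"gru{layer}_Wxr"].data + params[f"gru{layer}_bxr"].data
                + h @ params[f"gru{layer}_Whr"].data + params[f"gru{layer}_bhr"].data
            )))
            n = np.tanh(
                x @ params[f"gru{layer}_Wxn"].data + params[f"gru{layer}_bxn"].data
                + r * (h @ params[f"gru{layer}_Whn"].data + params[f"gru{layer}_bhn"].data)
            )
            h = (1 - z) * n + z * h
            out.append(h)
        return out

    seq = [norm_in(mat[:, t]) for t in range(T)]
    h1 = gru(seq, 0)
    h2 = gru(h1, 1)
    l = h2[-1]
    scores = np.array([_scalar_score(l, h, params) for h in h2])
    e = np.exp(scores - scores.max())
    w = e / e.sum()
    context = sum(w[t] * h2[t] for t in range(T))
    cat = np.concatenate([l, context])
    pre = cat @ params["cls_W1"].data + params["cls_b1"].data
    slope = float(params["cls_slope"].data)
    penult = np.where(pre > 0, pre, slope * pre)
    logits = penult @ params["cls_W2"].data + params["cls_b2"].data
    return logits, w, penult, context


class TestForward:
    def test_attention_weights_sum_to_one(self, rng):
        params = ModelParams(TINY)
        mat = rng.normal(size=(6, 5))
        _, w, _, _ = forward(mat, params)
        assert w.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(w >= 0)

    def test_identical_hidden_states_uniform_weights(self):
        # zeroed recurrence: h stays 0 at every step, so scores are equal
        params = ModelParams(ModelConfig(seed=3))
        for name, t in params.tensors.items():
            if name.startswith("gru"):
                t.data[:] = 0.0
        mat = np.random.default_rng(0).normal(size=(N_ROWS, N_STEPS))
        _, w, _, _ = forward(mat, params)
        np.testing.assert_allclose(w, np.full(N_STEPS, 1.0 / N_STEPS), atol=1e-12)

    def test_matches_scalar_recurrence_oracle(self, rng):
        params = ModelParams(TINY)
        mat = rng.normal(size=(6, 5))
        logits, w, penult, context = forward(mat, params)
        e_logits, e_w, e_penult, e_context = _scalar_forward(mat, params)
        np.testing.assert_allclose(logits, e_logits, rtol=1e-8)
        np.testing.assert_allclose(w, e_w, rtol=1e-8)
        np.testing.assert_allclose(penult, e_penult, rtol=1e-8)
        np.testing.assert_allclose(context, e_context, rtol=1e-8)

    def test_output_shapes_default_config(self, rng):
        params = ModelParams(ModelConfig(seed=0))
        logits, w, penult, context = forward(rng.normal(size=(N_ROWS, N_STEPS)), params)
        assert logits.shape == (7,)
        assert w.shape == (N_STEPS,)
        assert penult.shape == (64,)
        assert context.shape == (64,)

    def test_deterministic(self, rng):
        params = ModelParams(TINY)
        mat = rng.normal(size=(6, 5))
        a = forward(mat, params)
        b = forward(mat, params)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_malformed_matrix_errors(self, rng):
        params = ModelParams(TINY)
        with pytest.raises(ValueError):
            forward(rng.normal(size=(7, 5)), params)


class TestMultitaskLoss:
    def test_logit_zero_label_one_is_ln2(self):
        loss = multitask_loss(np.zeros(7), np.ones(7))
        assert loss.data == pytest.approx(np.log(2.0))

    def test_perfect_logits_near_zero(self):
        logits = np.where(np.arange(7) % 2 == 0, 50.0, -50.0)
        labels = (np.arange(7) % 2 == 0).astype(float)
        assert multitask_loss(logits, labels).data < 1e-8

    def test_masked_outcomes_excluded(self):
        logits = np.array([0.0, 100.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        labels = np.array([1.0, 0.0, 0, 0, 0, 0, 0])
        mask = np.array([1.0, 0, 0, 0, 0, 0, 0])
        assert multitask_loss(logits, labels, mask).data == pytest.approx(np.log(2.0))

    def test_matches_scalar_sum(self, rng):
        logits = rng.normal(size=(4, 7))
        labels = rng.integers(0, 2, size=(4, 7)).astype(float)
        mask = rng.integers(0, 2, size=(4, 7)).astype(float)
        mask[0, 0] = 1.0
        total, n = 0.0, 0
        for i in range(4):
            for j in range(7):
                if mask[i, j]:
                    p = 1 / (1 + np.exp(-logits[i, j]))
                    total += -(labels[i, j] * np.log(p) + (1 - labels[i, j]) * np.log(1 - p))
                    n += 1
        assert multitask_loss(logits, labels, mask).data == pytest.approx(total / n)

    def test_all_masked_errors(self):
        with pytest.raises(ValueError):
            multitask_loss(np.zeros(7), np.zeros(7), np.zeros(7))


class TestGradients:
    def test_end_to_end_finite_difference(self, rng):
        """Analytic gradients agree with central differences to 1e-4
        relative error (with an absolute floor below FD noise)."""
        params = ModelParams(TINY)
        mat = rng.normal(size=(2, 6, 5))
        labels = rng.integers(0, 2, size=(2, 7)).astype(float)

        def loss_value():
            out = forward_batch(mat, params)
            return float(multitask_loss(out["logits"], labels).data)

        out = forward_batch(mat, params)
        loss = multitask_loss(out["logits"], labels)
        loss.backward()
        eps = 1e-6
        for name, t in params.tensors.items():
            flat = t.data.reshape(-1)
            grad = np.zeros_like(flat) if t.grad is None else t.grad.reshape(-1)
            idx = np.linspace(0, flat.size - 1, min(flat.size, 6)).astype(int)
            for k in np.unique(idx):
                old = flat[k]
                flat[k] = old + eps
                fp = loss_value()
                flat[k] = old - eps
                fm = loss_value()
                flat[k] = old
                fd = (fp - fm) / (2 * eps)
                denom = max(abs(fd) + abs(grad[k]), 1e-4)
                assert abs(fd - grad[k]) / denom < 1e-4, (name, k, fd, grad[k])


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, rng):
        params = ModelParams(TINY)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, params)
        loaded = load_checkpoint(path)
        assert loaded.config == params.config
        mat = rng.normal(size=(6, 5))
        np.testing.assert_array_equal(forward(mat, params)[0], forward(mat, loaded)[0])


def test_architecture_dimensions():
    params = ModelParams(ModelConfig(seed=0))
    assert params["cls_W1"].shape == (128, 64)  # context + final hidden
    assert params["cls_W2"].shape == (64, 7)
    assert params["attn_B"].shape[0] == 128
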