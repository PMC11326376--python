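"""Attention, dual loss, forward passes, and the backprop engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histex import DataError, PatchSet, SpotPredictor, attention, dual_loss
from histex.model import (
    attention_backward,
    forward_direct,
    forward_full,
    load_checkpoint,
    save_checkpoint,
)
from histex import _nn


def brute_force_attention(fx, scale_dim):
    """Explicit per-row exp/normalize/mix, the independent oracle."""
    n, d = fx.shape
    out = np.zeros_like(fx, dtype=float)
    for i in range(n):
        logits = np.array([fx[i] @ fx[j] / np.sqrt(scale_dim) for j in range(n)])
        e = np.exp(logits - logits.max())
        w = e / e.sum()
        for j in range(n):
            out[i] += w[j] * fx[j]
    return out


class TestAttention:
    def test_single_spot_is_identity(self):
        fx = np.array([[1.5, -2.0, 3.0]])
        np.testing.assert_array_equal(attention(fx), fx)

    def test_zeros_give_uniform_weights_and_zero_output(self):
        fx = np.zeros((4, 3))
        out, w = attention(fx, return_weights=True)
        np.testing.assert_allclose(w, 0.25)
        np.testing.assert_array_equal(out, fx)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(1, 20)
            d = rng.integers(1, 10)
            fx = rng.normal(size=(n, d))
            np.testing.assert_allclose(attention(fx, scale_dim=d),
                                       brute_force_attention(fx, d), atol=1e-6)

    def test_rows_stochastic_and_convex_hull(self):
        rng = np.random.default_rng(1)
        fx = rng.normal(size=(7, 4))
        out, w = attention(fx, return_weights=True)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(w >= 0)
        # every output row lies inside the per-gene min/max of the inputs
        assert np.all(out <= fx.max(axis=0) + 1e-9)
        assert np.all(out >= fx.min(axis=0) - 1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        fx = rng.normal(size=(9, 5))
        perm = rng.permutation(9)
        np.testing.assert_allclose(attention(fx[perm]), attention(fx)[perm],
                                   atol=1e-12)

    def test_nonfinite_input_rejected(self):
        fx = np.array([[1.0, np.nan]])
        with pytest.raises(DataError, match="non-finite"):
            attention(fx)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        fx = rng.normal(size=(5, 3))
        y = rng.normal(size=(5, 3))
        scale = 3.0
        out, w = attention(fx, scale_dim=scale, return_weights=True)
        grad = attention_backward(fx, w, out - y, scale)
        eps = 1e-6
        for i in range(5):
            for j in range(3):
                f1, f2 = fx.copy(), fx.copy()
                f1[i, j] += eps
                f2[i, j] -= eps
                l1 = 0.5 * np.sum((attention(f1, scale_dim=scale) - y) ** 2)
                l2 = 0.5 * np.sum((attention(f2, scale_dim=scale) - y) ** 2)
                assert abs(grad[i, j] - (l1 - l2) / (2 * eps)) < 1e-6


class TestDualLoss:
    def test_perfect_prediction_is_zero(self):
        y = np.ones((3, 2))
        rep = dual_loss(y, y.copy(), y.copy())
        assert rep.l_direct == rep.l_attended == rep.l_total == 0.0

    def test_one_by_one_arithmetic(self):
        rep = dual_loss(np.array([[1.0]]), np.array([[0.0]]), np.array([[3.0]]))
        assert rep.l_direct == 1.0
        assert rep.l_attended == 4.0
        assert rep.l_total == 5.0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(4)
        y, p, q = (rng.normal(size=(4, 3)) for _ in range(3))
        rep = dual_loss(y, p, q)
        acc_d = sum((y[i, j] - p[i, j]) ** 2 for i in range(4) for j in range(3))
        acc_a = sum((y[i, j] - q[i, j]) ** 2 for i in range(4) for j in range(3))
        assert abs(rep.l_direct - acc_d / 12) < 1e-9
        assert abs(rep.l_attended - acc_a / 12) < 1e-9
        assert rep.l_total == rep.l_direct + rep.l_attended

    def test_shape_mismatch_raises(self):
        with pytest.raises(DataError, match="shape"):
            dual_loss(np.ones((2, 2)), np.ones((2, 3)), np.ones((2, 2)))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_nonnegative_and_additive(self, seed):
        rng = np.random.default_rng(seed)
        y, p, q = (rng.normal(size=(3, 2)) for _ in range(3))
        rep = dual_loss(y, p, q)
        assert rep.l_direct >= 0 and rep.l_attended >= 0
        assert rep.l_total == rep.l_direct + rep.l_attended


def random_patches(n, size=16, seed=0):
    rng = np.random.default_rng(seed)
    return PatchSet(
        patches=rng.integers(0, 256, size=(n, 3, size, size), dtype=np.uint8),
        spot_ids=[f"s{i}" for i in range(n)],
    )


class TestForwardPasses:
    def test_empty_batch_gives_empty_matrix(self):
        model = SpotPredictor(gene_ids=["a", "b"], patch_size=16)
        ps = random_patches(0)
        out = forward_direct(model, ps)
        assert out.shape == (0, 2)

    def test_duplicated_patches_identical_rows(self):
        model = SpotPredictor(gene_ids=["a", "b", "c"], patch_size=16, seed=5)
        one = random_patches(1, seed=5)
        ps = PatchSet(patches=np.repeat(one.patches, 3, axis=0),
                      spot_ids=["s0", "s1", "s2"])
        out = forward_direct(model, ps)
        np.testing.assert_array_equal(out[0], out[1])
        np.testing.assert_array_equal(out[0], out[2])

    def test_full_forward_consistent_with_attention(self):
        model = SpotPredictor(gene_ids=list("abcd"), patch_size=16, seed=7)
        ps = random_patches(6, seed=7)
        direct, attended = forward_full(model, ps)
        np.testing.assert_allclose(
            attended, attention(direct, scale_dim=model.temperature_dim),
            atol=1e-6)

    def test_single_spot_attended_equals_direct(self):
        model = SpotPredictor(gene_ids=["a"], patch_size=16)
        ps = random_patches(1)
        direct, attended = forward_full(model, ps)
        np.testing.assert_allclose(attended, direct, atol=1e-7)

    def test_patch_size_mismatch_raises(self):
        model = SpotPredictor(gene_ids=["a"], patch_size=32)
        with pytest.raises(DataError, match="patch size"):
            forward_direct(model, random_patches(2, size=16))

    def test_residual_backbone_runs(self):
        model = SpotPredictor(gene_ids=["a", "b"], patch_size=16,
                              backbone_kind="residual_cnn")
        out = forward_direct(model, random_patches(3))
        assert out.shape == (3, 2)
        assert np.all(np.isfinite(out))


class TestEngineGradients:
    """Finite-difference checks of the conv/linear/pool backward passes."""

    def _check(self, layer, x_shape, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=x_shape)
        y = layer.forward(x)
        dout = rng.normal(size=y.shape)
        layer.zero_grad()
        dx = layer.backward(dout)
        eps = 1e-6
        flat = x.ravel()
        idx = rng.choice(flat.size, size=min(12, flat.size), replace=False)
        for i in idx:
            x1, x2 = x.copy().ravel(), x.copy().ravel()
            x1[i] += eps
            x2[i] -= eps
            l1 = np.sum(layer.forward(x1.reshape(x_shape)) * dout)
            l2 = np.sum(layer.forward(x2.reshape(x_shape)) * dout)
            assert abs(dx.ravel()[i] - (l1 - l2) / (2 * eps)) < 1e-5

    def test_conv_input_gradient(self):
        rng = np.random.default_rng(1)
        self._check(_nn.Conv2d(2, 3, k=3, stride=2, pad=1, rng=rng,
                               dtype=np.float64), (2, 2, 8, 8))

    def test_conv_against_scipy_correlate(self):
        from scipy.signal import correlate

        rng = np.random.default_rng(2)
        conv = _nn.Conv2d(1, 1, k=3, stride=1, pad=1, rng=rng, dtype=np.float64)
        x = rng.normal(size=(1, 1, 6, 6))
        got = conv.forward(x)[0, 0]
        kernel = conv.params["W"].reshape(3, 3)
        expected = correlate(np.pad(x[0, 0], 1), kernel, mode="valid")
        np.testing.assert_allclose(got, expected + conv.params["b"][0],
                                   atol=1e-10)

    def test_linear_and_residual_gradients(self):
        rng = np.random.default_rng(3)
        self._check(_nn.Linear(5, 4, rng=rng, dtype=np.float64), (3, 5))
        self._check(_nn.ResidualBlock(2, rng=rng, dtype=np.float64),
                    (1, 2, 6, 6), seed=4)

    def test_conv_weight_gradient(self):
        rng = np.random.default_rng(5)
        conv = _nn.Conv2d(1, 2, k=3, stride=1, pad=1, rng=rng, dtype=np.float64)
        x = rng.normal(size=(2, 1, 5, 5))
        y = conv.forward(x)
        dout = rng.normal(size=y.shape)
        conv.zero_grad()
        conv.backward(dout)
        eps = 1e-6
        W = conv.params["W"]
        for i in (0, 3, 8):
            orig = W[0, i]
            W[0, i] = orig + eps
            l1 = np.sum(conv.forward(x) * dout)
            W[0, i] = orig - eps
            l2 = np.sum(conv.forward(x) * dout)
            W[0, i] = orig
            assert abs(conv.grads["W"][0, i] - (l1 - l2) / (2 * eps)) < 1e-5


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = SpotPredictor(gene_ids=["a", "b"], patch_size=16, seed=3)
        ps = random_patches(4, seed=3)
        before = forward_direct(model, ps)
        save_checkpoint(model, tmp_path / "m.ckpt", extra_meta={"note": "x"})
        back, extra = load_checkpoint(tmp_path / "m.ckpt")
        assert extra == {"note": "x"}
        assert back.gene_ids == model.gene_ids
        np.testing.assert_array_equal(forward_direct(back, ps), before)
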