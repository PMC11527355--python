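"""Attribution methods against analytic, finite-difference, and hand oracles."""

import numpy as np
import pytest

from neurosal import nn
from neurosal.attribution import (
    AttributionOptions,
    compute_attribution,
    grad_saliency,
    gradient_shap,
    guided_backprop,
    guided_gradcam,
    input_x_gradient,
    integrated_gradients,
    masked_gradient,
)
from neurosal.bamodel import CNNConfig, build_model


def linear_model(weights):
    """f(x) = Σ w·x as a Sequential (flatten + dense, no nonlinearity)."""
    w = np.asarray(weights, dtype=float).ravel()
    dense = nn.Dense(w.size, 1, np.random.default_rng(0))
    dense.w[:, 0] = w
    dense.b[:] = 0.0
    return nn.Sequential([nn.Flatten(), dense])


@pytest.fixture(scope="module")
def small_cnn():
    cfg = CNNConfig(input_size=8, n_blocks=2, filters=(2, 3), conv_kernel=3,
                    dropout_rate=0.0, dropout_blocks=(), dense_sizes=(4,),
                    patience=1, seed=11)
    return build_model(cfg)


@pytest.fixture(scope="module")
def x8():
    return np.random.default_rng(21).random((8, 8, 8))


class TestGradSaliency:
    def test_linear_model_returns_weights(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(4, 4, 4))
        x = rng.random((4, 4, 4))
        att = grad_saliency(linear_model(w), x)
        assert np.allclose(att.data, w)

    def test_constant_model_zero_field(self):
        att = grad_saliency(linear_model(np.zeros((4, 4, 4))),
                            np.random.default_rng(1).random((4, 4, 4)))
        assert np.all(att.data == 0)

    def test_matches_finite_differences_on_cnn(self):
        cfg = CNNConfig(input_size=4, n_blocks=1, filters=(2,), conv_kernel=3,
                        dropout_rate=0.0, dropout_blocks=(), dense_sizes=(3,),
                        patience=1, seed=5)
        model = build_model(cfg)
        x = np.random.default_rng(2).random((4, 4, 4))
        att = grad_saliency(model, x).data
        eps = 1e-6
        rng = np.random.default_rng(3)
        for _ in range(10):
            idx = tuple(rng.integers(0, 4, 3))
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            fd = (model.forward(xp[None, None])[0, 0] -
                  model.forward(xm[None, None])[0, 0]) / (2 * eps)
            assert att[idx] == pytest.approx(fd, rel=1e-3, abs=1e-9)


class TestInputXGradient:
    def test_zero_input_zero_field(self, small_cnn):
        att = input_x_gradient(small_cnn, np.zeros((8, 8, 8)))
        assert np.all(att.data == 0)

    def test_linear_model_analytic(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(4, 4, 4))
        x = rng.random((4, 4, 4))
        att = input_x_gradient(linear_model(w), x)
        assert np.allclose(att.data, x * w)

    def test_definitional_identity(self, small_cnn, x8):
        ixg = input_x_gradient(small_cnn, x8).data
        g = grad_saliency(small_cnn, x8).data
        assert np.array_equal(ixg, x8 * g)


class TestMaskedGradient:
    def test_all_ones_mask_equals_gradient(self, small_cnn, x8):
        mg = masked_gradient(small_cnn, x8, np.ones((8, 8, 8)))
        assert np.array_equal(mg.data, grad_saliency(small_cnn, x8).data)

    def test_all_zero_mask_gives_zero_field(self, small_cnn, x8):
        mg = masked_gradient(small_cnn, x8, np.zeros((8, 8, 8)))
        assert np.all(mg.data == 0)

    def test_default_mask_is_nonzero_support(self, small_cnn):
        x = np.random.default_rng(6).random((8, 8, 8))
        x[:, :2] = 0.0      # "outside the brain"
        mg = masked_gradient(small_cnn, x)
        assert np.all(mg.data[:, :2] == 0)
        inside = grad_saliency(small_cnn, x).data[x != 0]
        assert np.array_equal(mg.data[x != 0], inside)

    def test_nonbinary_mask_rejected(self, small_cnn, x8):
        with pytest.raises(ValueError):
            masked_gradient(small_cnn, x8, np.full((8, 8, 8), 0.5))


class TestGuidedBackprop:
    def test_linear_model_equals_gradient(self):
        w = np.random.default_rng(7).normal(size=(4, 4, 4))
        x = np.random.default_rng(8).random((4, 4, 4))
        gb = guided_backprop(linear_model(w), x)
        assert np.allclose(gb.data, w)

    def test_hand_computed_relu_gating(self):
        """Two-input toy: f = v · relu(W x); gradient gates worked by hand.

        W = [[1, -1], [1, 1]], v = [1, -1], x = (2, 1):
        pre-activations (1, 3), both positive; upstream grads (1, -1).
        Plain gradient: W^T @ (1, -1) = (0, -2).
        Guided zeroes the negative upstream entry: W^T @ (1, 0) = (1, -1).
        """
        rng = np.random.default_rng(0)
        d1 = nn.Dense(2, 2, rng)
        d1.w[...] = np.array([[1.0, 1.0], [-1.0, 1.0]])  # (in, out) layout
        d1.b[:] = 0.0
        d2 = nn.Dense(2, 1, rng)
        d2.w[:, 0] = [1.0, -1.0]
        d2.b[:] = 0.0
        model = nn.Sequential([nn.Flatten(), d1, nn.ReLU(), d2])
        x = np.array([[2.0, 1.0]])

        out = model.forward(x)
        assert out[0, 0] == pytest.approx(-2.0)
        grad_plain = model.backward(np.ones_like(out))
        assert np.allclose(grad_plain.ravel(), [0.0, -2.0])
        model.forward(x)
        grad_guided = model.backward(np.ones((1, 1)), guided=True)
        assert np.allclose(grad_guided.ravel(), [1.0, -1.0])

    def test_model_state_unchanged(self, small_cnn, x8):
        before = {k: v.copy() for k, v in small_cnn.named_params().items()}
        guided_backprop(small_cnn, x8)
        after = small_cnn.named_params()
        assert all(np.array_equal(before[k], after[k]) for k in before)


class TestGuidedGradCAM:
    def test_output_shape_matches_input(self, small_cnn, x8):
        att = guided_gradcam(small_cnn, x8)
        assert att.data.shape == x8.shape

    def test_zero_where_gb_zero(self, small_cnn, x8):
        ggc = guided_gradcam(small_cnn, x8).data
        gb = guided_backprop(small_cnn, x8).data
        assert np.all(ggc[gb == 0] == 0)

    def test_hand_computable_single_channel_toy(self):
        """1-channel 1x1x1-kernel conv toy: CAM = relu(mean-grad · activation).

        f = Σ conv(x) with w=2, b=0 on a 2³ grid: activation A = 2x,
        d f/d A = 1 everywhere so α = 1, CAM = relu(A) = 2x (x > 0);
        GB field is 2 everywhere, so GGC = 4x.
        """
        rng = np.random.default_rng(0)
        conv = nn.Conv3d(1, 1, 1, rng)
        conv.w[...] = 2.0
        conv.b[:] = 0.0
        dense = nn.Dense(8, 1, rng)
        dense.w[:, 0] = 1.0
        dense.b[:] = 0.0
        model = nn.Sequential([conv, nn.Flatten(), dense])
        x = np.abs(np.random.default_rng(1).random((2, 2, 2))) + 0.1
        att = guided_gradcam(model, x, target_layer=0)
        assert np.allclose(att.data, 4.0 * x)

    def test_invalid_layer_rejected(self, small_cnn, x8):
        with pytest.raises(ValueError):
            guided_gradcam(small_cnn, x8, target_layer=len(small_cnn.layers) - 1)


class TestIntegratedGradients:
    def test_input_equals_baseline_zero_field(self, small_cnn, x8):
        att = integrated_gradients(small_cnn, x8, baseline=x8.copy(), n_points=8)
        assert np.allclose(att.data, 0.0)

    @pytest.mark.parametrize("n_points", [1, 5, 50])
    def test_linear_model_exact_for_any_node_count(self, n_points):
        rng = np.random.default_rng(9)
        w = rng.normal(size=(4, 4, 4))
        x = rng.random((4, 4, 4))
        b = rng.random((4, 4, 4))
        att = integrated_gradients(linear_model(w), x, baseline=b,
                                   n_points=n_points)
        assert np.allclose(att.data, (x - b) * w)

    def test_completeness_on_trained_cnn(self, trained_small_model):
        """IG attributions sum to f(x) − f(baseline) within 1% relative.

        The path integrand is only piecewise smooth (ReLU and max-pool
        switch points), so the node count is set where the quadrature has
        converged for this model scale, with an absolute floor for inputs
        whose output barely differs from the baseline's.
        """
        model, X, _ = trained_small_model
        for x in X[:3]:
            att = integrated_gradients(model, x, n_points=400)
            fx = model.forward(x[None, None])[0, 0]
            f0 = model.forward(np.zeros_like(x)[None, None])[0, 0]
            assert att.data.sum() == pytest.approx(fx - f0, rel=0.01, abs=5e-3)

    def test_shape_mismatch_rejected(self, small_cnn, x8):
        with pytest.raises(ValueError):
            integrated_gradients(small_cnn, x8, baseline=np.zeros((4, 4, 4)))


class TestGradientShap:
    def test_sigma_zero_self_baseline_zero_field(self, small_cnn, x8):
        att = gradient_shap(small_cnn, x8, [x8.copy()], n_samples=3, sigma=0.0,
                            rng=np.random.default_rng(0))
        assert np.allclose(att.data, 0.0)

    def test_linear_model_sigma_zero_analytic(self):
        rng = np.random.default_rng(10)
        w = rng.normal(size=(4, 4, 4))
        x = rng.random((4, 4, 4))
        b = rng.random((4, 4, 4))
        att = gradient_shap(linear_model(w), x, [b], n_samples=7, sigma=0.0,
                            rng=np.random.default_rng(1))
        assert np.allclose(att.data, (x - b) * w)

    def test_converges_to_ig_on_linear_model(self):
        """With noise, GSHAP approaches IG (same single baseline) in MC mean."""
        rng = np.random.default_rng(11)
        w = rng.normal(size=(4, 4, 4))
        x = rng.random((4, 4, 4))
        b = np.zeros((4, 4, 4))
        model = linear_model(w)
        ig = integrated_gradients(model, x, baseline=b, n_points=10).data
        gs = gradient_shap(model, x, [b], n_samples=400, sigma=0.02,
                           rng=np.random.default_rng(2)).data
        err = np.abs(gs - ig).mean() / np.abs(ig).mean()
        assert err < 0.05

    def test_empty_pool_rejected(self, small_cnn, x8):
        with pytest.raises(ValueError):
            gradient_shap(small_cnn, x8, [], n_samples=1, sigma=0.1)

    def test_seeded_determinism(self, small_cnn, x8):
        a = gradient_shap(small_cnn, x8, [np.zeros_like(x8)], n_samples=3,
                          sigma=0.1, rng=np.random.default_rng(5)).data
        b = gradient_shap(small_cnn, x8, [np.zeros_like(x8)], n_samples=3,
                          sigma=0.1, rng=np.random.default_rng(5)).data
        assert np.array_equal(a, b)


class TestDispatchAndInvariants:
    @pytest.mark.parametrize("method", ["G", "IXG", "MG", "GB", "GGC", "IG", "GSHAP"])
    def test_shape_and_finiteness(self, small_cnn, x8, method):
        att = compute_attribution(method, small_cnn, x8,
                                  AttributionOptions(ig_points=8, gshap_samples=2))
        assert att.data.shape == x8.shape
        assert np.all(np.isfinite(att.data))
        assert att.method == method

    def test_unknown_method_rejected(self, small_cnn, x8):
        with pytest.raises(ValueError, match="unknown"):
            compute_attribution("SmoothGrad", small_cnn, x8)

    def test_statelessness_repeat_calls_identical(self, small_cnn, x8):
        a = compute_attribution("IG", small_cnn, x8, AttributionOptions(ig_points=8))
        b = compute_attribution("IG", small_cnn, x8, AttributionOptions(ig_points=8))
        assert np.array_equal(a.data, b.data)

    def test_invalid_options_rejected(self):
        with pytest.raises(ValueError):
            AttributionOptions(ig_points=0)
        with pytest.raises(ValueError):
            AttributionOptions(gshap_samples=0)
        with pytest.raises(ValueError):
            AttributionOptions(gshap_sigma=-0.1)
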