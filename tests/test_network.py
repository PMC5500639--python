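"""Layer algebra, initialization, forward/backward and loss contracts.

The independent numeric oracle is a nested-loop implementation of the
convolution / pooling / matmul arithmetic, written here and nowhere else.
"""

import numpy as np
import pytest

from phenonet import ShapeError
from phenonet.nn import (
    ArchitectureSpec,
    Network,
    conv,
    count_parameters,
    cross_entropy,
    dropout,
    fully_connected,
    loss,
    mse,
    output,
    output_shape,
    pool,
    softmax,
    validate_spec,
    xavier_init,
)
from phenonet.nn.layers import Conv2D, Dense, MaxPool2D


def naive_forward_layers(layers, x):
    """Reference evaluation by direct summation; deliberately slow."""
    h = np.asarray(x, dtype=np.float64)
    for layer in layers:
        if isinstance(layer, Conv2D):
            n, H, W, C = h.shape
            kh, kw = layer.kh, layer.kw
            ph, pw = kh // 2, kw // 2
            hp = np.pad(h, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
            out = np.zeros((n, H, W, layer.filters))
            for b in range(n):
                for i in range(H):
                    for j in range(W):
                        for f in range(layer.filters):
                            acc = float(layer.b[f])
                            for u in range(kh):
                                for v in range(kw):
                                    for c in range(C):
                                        acc += hp[b, i + u, j + v, c] * layer.W[u, v, c, f]
                            out[b, i, j, f] = acc
            h = _naive_activate(out, layer.activation)
        elif isinstance(layer, MaxPool2D):
            n, H, W, C = h.shape
            k, s = layer.kh, layer.stride
            oh, pt, _ = layer._same_pad(H, k, s)
            ow, pl, _ = layer._same_pad(W, k, s)
            out = np.full((n, oh, ow, C), -np.inf)
            for b in range(n):
                for i in range(oh):
                    for j in range(ow):
                        for u in range(k):
                            for v in range(k):
                                r, c2 = i * s + u - pt, j * s + v - pl
                                if 0 <= r < H and 0 <= c2 < W:
                                    out[b, i, j] = np.maximum(out[b, i, j], h[b, r, c2])
            h = out
        elif isinstance(layer, Dense):
            n = h.shape[0]
            z = h.reshape(n, -1) @ layer.W.astype(np.float64) + layer.b
            h = _naive_activate(z, layer.activation)
    return h


def _naive_activate(z, kind):
    if kind == "tanh":
        return np.tanh(z)
    if kind == "relu":
        return np.maximum(z, 0.0)
    return z


class TestShapeAlgebra:
    def test_same_padded_conv_preserves_spatial_size(self):
        assert output_shape(conv(5, 32), (96, 96, 3)) == (96, 96, 32)

    def test_pool_stride_two_halves_with_ceiling(self):
        assert output_shape(pool(3, 2), (96, 96, 32)) == (48, 48, 32)
        assert output_shape(pool(3, 2), (3, 3, 8)) == (2, 2, 8)

    def test_dropout_preserves_shape(self):
        assert output_shape(dropout(0.5), (12, 12, 64)) == (12, 12, 64)
        assert output_shape(dropout(0.5), (4096,)) == (4096,)

    def test_conv_on_flat_vector_rejected(self):
        with pytest.raises(ShapeError):
            output_shape(conv(3, 8), (128,))

    def test_validation_catches_end_to_end_mismatch(self):
        with pytest.raises(Exception):
            ArchitectureSpec(
                name="bad", input_size=(32, 32),
                layers=(conv(3, 4), output(2)),
                task="regression", outputs=3,  # output units != outputs
            )


class TestParameterCount:
    def test_single_conv_closed_form(self):
        spec = ArchitectureSpec(
            name="c1", input_size=(32, 32),
            layers=(conv(5, 32), output(1)),
            task="regression", outputs=1, crop_fraction=0.0,
        )
        conv_params = 5 * 5 * 3 * 32 + 32
        assert conv_params == 2432
        out_params = 32 * 32 * 32 * 1 + 1
        assert count_parameters(spec) == conv_params + out_params

    def test_closed_form_matches_enumerated_arrays(self):
        spec = ArchitectureSpec(
            name="mix", input_size=(24, 24),
            layers=(conv(3, 6, "tanh"), pool(3, 2), fully_connected(10, "relu"),
                    dropout(0.4), output(2)),
            task="regression", outputs=2, crop_fraction=0.25,
        )
        net = Network(spec, np.random.default_rng(0))
        assert net.parameter_count == count_parameters(spec)

    def test_pool_and_dropout_contribute_nothing(self):
        spec = ArchitectureSpec(
            name="p", input_size=(32, 32),
            layers=(pool(3, 2), dropout(0.5), output(1)),
            task="regression", outputs=1, crop_fraction=0.0,
        )
        out_only = 16 * 16 * 3 * 1 + 1
        assert count_parameters(spec) == out_only


class TestXavierInit:
    def test_bound_is_one_at_fan_three_three(self, rng):
        w = xavier_init((1000,), 3, 3, rng)
        assert np.abs(w).max() <= 1.0  # sqrt(6/6) = 1 exactly

    def test_moments_of_uniform_law(self):
        rng = np.random.default_rng(8)
        fan_in, fan_out = 75, 32
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        w = xavier_init((100_000,), fan_in, fan_out, rng)
        assert np.abs(w).max() <= bound
        assert abs(w.var() - bound**2 / 3) < 0.1 * bound**2 / 3

    def test_same_seed_identical(self):
        a = xavier_init((50, 50), 50, 50, np.random.default_rng(3))
        b = xavier_init((50, 50), 50, 50, np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestForward:
    @pytest.fixture
    def toy_classifier(self):
        spec = ArchitectureSpec(
            name="toy", input_size=(16, 16),
            layers=(conv(3, 4, "relu"), pool(3, 2), dropout(0.5),
                    fully_connected(8, "relu"), output(3)),
            task="classification", outputs=3, crop_fraction=0.25,
        )
        return Network(spec, np.random.default_rng(1))

    def test_classifier_rows_sum_to_one(self, toy_classifier, rng):
        x = rng.standard_normal((5, 12, 12, 3)).astype(np.float32)
        probs = toy_classifier.forward(x)
        assert probs.shape == (5, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_ignores_dropout(self, toy_classifier, rng):
        x = rng.standard_normal((4, 12, 12, 3)).astype(np.float32)
        a = toy_classifier.forward(x, training=False)
        b = toy_classifier.forward(x, training=False)
        assert np.array_equal(a, b)

    def test_zero_input_zero_output_layer_gives_zero_prediction(self):
        spec = ArchitectureSpec(
            name="z", input_size=(8, 8), layers=(output(1),),
            task="regression", outputs=1, crop_fraction=0.0,
        )
        net = Network(spec, np.random.default_rng(0))
        net.layers[0].W[...] = 0.0
        pred = net.forward(np.zeros((2, 8, 8, 3), dtype=np.float32))
        assert np.array_equal(pred, np.zeros((2, 1)))

    def test_shape_mismatch_names_expected_and_got(self, toy_classifier, rng):
        x = rng.standard_normal((2, 16, 16, 3)).astype(np.float32)
        with pytest.raises(ShapeError, match=r"12, 12"):
            toy_classifier.forward(x)

    def test_forward_matches_naive_nested_loop_oracle(self):
        # hand-built two-layer net on a single-channel 8x8 input
        rng = np.random.default_rng(9)
        layers = [
            Conv2D((3, 3), 1, 2, "tanh", rng),
            MaxPool2D((3, 3), 2),
            Conv2D((3, 3), 2, 3, "relu", rng),
        ]
        layers[0].W[...] = rng.standard_normal(layers[0].W.shape).astype(np.float32) * 0.5
        layers[0].b[...] = [0.1, -0.2]
        layers[2].W[...] = rng.standard_normal(layers[2].W.shape).astype(np.float32) * 0.5
        x = rng.standard_normal((2, 8, 8, 1)).astype(np.float32)
        fast = x
        for layer in layers:
            fast = layer.forward(fast, training=False)
        slow = naive_forward_layers(layers, x)
        assert np.abs(fast - slow).max() < 1e-5


class TestLosses:
    def test_regression_zero_at_perfect_prediction(self):
        assert loss(np.array([1.0, 2.0]), np.array([1.0, 2.0]), "regression") == 0.0

    def test_mse_hand_case(self):
        assert mse(np.array([1.0, 3.0]), np.array([0.0, 0.0])) == 5.0

    def test_cross_entropy_fifty_fifty_is_ln_two(self):
        probs = np.array([[0.5, 0.5]])
        assert abs(cross_entropy(probs, np.array([0])) - np.log(2)) < 1e-9

    def test_interpolation_toward_labels_never_increases_mse(self, rng):
        preds = rng.standard_normal(50)
        labels = rng.standard_normal(50)
        values = [mse(preds + t * (labels - preds), labels) for t in np.linspace(0, 1, 11)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_softmax_is_shift_invariant(self, rng):
        z = rng.standard_normal((4, 6))
        assert np.allclose(softmax(z), softmax(z + 100.0), atol=1e-12)
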