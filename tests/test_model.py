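"""Architecture construction, forward math, and the exact complexity ledger."""

import math

import numpy as np
import pytest

from steatoscan.errors import ParameterError, ShapeError
from steatoscan.model import (
    ArchitectureSpec,
    BatchNormSpec,
    ConvSpec,
    FCSpec,
    FlattenSpec,
    PoolSpec,
    ReluSpec,
    build_network,
    count_flops,
    count_params,
    cross_entropy,
    experiment_spec,
    forward,
    load_model,
    propagate_shapes,
    relu,
    save_model,
    skip_add,
    softmax_head,
    spec_from_yaml,
    spec_to_yaml,
    reference_spec,
)


def tiny_spec(skip=True):
    return ArchitectureSpec(
        input_shape=(6, 6, 1),
        layers=(ConvSpec(3, 2, 1, 1), ReluSpec(), PoolSpec(2, 1),
                ConvSpec(3, 3, 1, 0), ReluSpec(), FlattenSpec(), FCSpec(5), FCSpec(4)),
        skip_enabled=skip,
    )


def random_small_spec(rng):
    """A random valid conv/pool/fc stack on a small input."""
    size = int(rng.integers(8, 15))
    layers = []
    cur = size
    n_conv = int(rng.integers(1, 3))
    for j in range(n_conv):
        k = int(rng.choice([1, 3, 5]))
        pad = k // 2 if rng.random() < 0.5 else 0
        if cur + 2 * pad - k + 1 < 2:
            continue
        layers.append(ConvSpec(k, int(rng.integers(1, 6)), 1, pad))
        cur = cur + 2 * pad - k + 1
        if rng.random() < 0.5:
            layers.append(BatchNormSpec())
        layers.append(ReluSpec())
    layers.append(FlattenSpec())
    for _ in range(int(rng.integers(1, 3))):
        layers.append(FCSpec(int(rng.integers(2, 10))))
    layers.append(FCSpec(4))
    return ArchitectureSpec(input_shape=(size, size, 1), layers=tuple(layers))


def naive_conv_multiply_count(in_h, in_w, in_c, kernel, filters, stride, padding):
    """Brute-force: count scalar multiplies of a triple-loop convolution."""
    count = 0
    h, w = in_h + 2 * padding, in_w + 2 * padding
    for f in range(filters):
        for r in range(0, h - kernel + 1, stride):
            for c in range(0, w - kernel + 1, stride):
                count += kernel * kernel * in_c
    return count


class TestShapePropagation:
    def test_default_flatten_is_123750(self):
        shapes = propagate_shapes(reference_spec())
        flat = [s for s in shapes if len(s) == 1][0]
        assert flat == (123750,)
        assert flat[0] == 25 * 25 * 198

    def test_pool_window_larger_than_input_rejected(self):
        spec = ArchitectureSpec(input_shape=(3, 3, 1),
                                layers=(PoolSpec(window=5, stride=1), FlattenSpec(), FCSpec(4)))
        with pytest.raises(ShapeError, match="pool"):
            propagate_shapes(spec)

    def test_conv_shrinking_to_nothing_rejected(self):
        spec = ArchitectureSpec(input_shape=(4, 4, 1),
                                layers=(ConvSpec(7, 2, 1, 0), FlattenSpec(), FCSpec(4)))
        with pytest.raises(ShapeError, match="conv"):
            propagate_shapes(spec)

    def test_skip_requires_matching_extents(self):
        # unpadded first conv shrinks the map, so the pooled input cannot align
        spec = ArchitectureSpec(
            input_shape=(8, 8, 1),
            layers=(ConvSpec(3, 2, 1, 0), ReluSpec(), PoolSpec(2, 1),
                    FlattenSpec(), FCSpec(4)),
            skip_enabled=True,
        )
        with pytest.raises(ShapeError, match="skip"):
            propagate_shapes(spec)

    def test_yaml_round_trip(self):
        spec = reference_spec()
        assert spec_from_yaml(spec_to_yaml(spec)) == spec

    def test_propagation_matches_live_forward_pass(self):
        """Symbolic shapes equal the activations of a real forward pass on a
        width-reduced network with the reference spatial geometry (28 -> 28
        -> 27 -> 25 with a 2x2/stride-1 pool and unpadded second conv)."""
        spec = ArchitectureSpec(
            input_shape=(28, 28, 1),
            layers=(ConvSpec(3, 2, 1, 1), ReluSpec(), PoolSpec(2, 1),
                    ConvSpec(3, 3, 1, 0), ReluSpec(), FlattenSpec(),
                    FCSpec(7), FCSpec(4)),
            skip_enabled=True,
        )
        shapes = propagate_shapes(spec)
        assert shapes[2][:2] == (27, 27)
        assert shapes[5] == (25 * 25 * 3,)

        m = build_network(spec, seed=0)
        x = np.random.default_rng(0).random((2, 28, 28, 1)).astype(np.float32)
        out = x
        for i, layer in enumerate(m.layers):
            out = layer.forward(out, False)
            assert out.shape[1:] == shapes[i], f"layer {i}"
            if m._skip_index is not None and i == m._skip_index:
                out = out + m._skip_pool.forward(x, train=False)
        assert out.shape == (2, 4)


class TestElementaryOps:
    def test_relu_sign_cases(self):
        np.testing.assert_array_equal(relu(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 2.0])

    def test_relu_saturation_and_idempotence(self):
        x = np.array([-5.0, -0.1, -100.0])
        assert np.all(relu(x) == 0)
        y = np.random.default_rng(0).normal(size=20)
        np.testing.assert_array_equal(relu(relu(y)), relu(y))

    def test_softmax_uniform(self):
        np.testing.assert_allclose(softmax_head(np.zeros(4)), 0.25)

    def test_softmax_closed_form(self):
        probs = softmax_head(np.array([0.0, 0.0, 0.0, math.log(3)]))
        np.testing.assert_allclose(probs, [1 / 6, 1 / 6, 1 / 6, 1 / 2], atol=1e-12)

    def test_softmax_shift_invariance_and_normalization(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=4)
        np.testing.assert_allclose(softmax_head(y), softmax_head(y + 137.0), atol=1e-12)
        assert softmax_head(y).sum() == pytest.approx(1.0, abs=1e-6)

    def test_softmax_rejects_nonfinite(self):
        with pytest.raises(ParameterError):
            softmax_head(np.array([0.0, np.nan, 0.0, 0.0]))

    def test_cross_entropy_perfect_prediction(self):
        assert cross_entropy([0, 1, 0, 0], [0, 1, 0, 0]) == 0.0

    def test_cross_entropy_ln2(self):
        L = cross_entropy([1, 0, 0, 0], [0.5, 0.2, 0.2, 0.1])
        assert L == pytest.approx(math.log(2), abs=1e-12)

    def test_cross_entropy_monotone_in_true_probability(self):
        losses = [cross_entropy([1, 0, 0, 0], [p, (1 - p) / 3, (1 - p) / 3, (1 - p) / 3])
                  for p in (0.2, 0.5, 0.9)]
        assert losses[0] > losses[1] > losses[2]

    def test_cross_entropy_zero_probability_clamped(self, caplog):
        with caplog.at_level("WARNING"):
            L = cross_entropy([1, 0, 0, 0], [0.0, 0.5, 0.5, 0.0])
        assert L == pytest.approx(-math.log(1e-12))
        assert "clamped" in caplog.text

    def test_skip_add_identity_and_broadcast(self):
        x = np.ones((2, 27, 27, 64))
        lam0 = np.zeros((2, 27, 27, 1))
        np.testing.assert_array_equal(skip_add(x, lam0), x)
        lam2 = np.full((2, 27, 27, 1), 2.0)
        assert np.all(skip_add(x, lam2) == 3.0)

    def test_skip_add_additivity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 5, 5, 3))
        l1 = rng.normal(size=(1, 5, 5, 1))
        l2 = rng.normal(size=(1, 5, 5, 1))
        np.testing.assert_allclose(skip_add(x, l1 + l2), skip_add(skip_add(x, l1), l2))

    def test_skip_add_shape_errors(self):
        x = np.ones((1, 5, 5, 3))
        with pytest.raises(ShapeError):
            skip_add(x, np.ones((1, 4, 4, 1)))
        with pytest.raises(ShapeError):
            skip_add(x, np.ones((1, 5, 5, 2)))


class TestBuildAndForward:
    def test_seeded_build_determinism(self):
        a = build_network(tiny_spec(), seed=5)
        b = build_network(tiny_spec(), seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_probabilities_sum_to_one(self):
        m = build_network(tiny_spec(), seed=0)
        x = np.random.default_rng(0).random((3, 6, 6, 1))
        probs = m.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_no_skip_model_matches_manual_lambda_removal(self):
        """Structure B's forward equals structure A's with the skip addend subtracted."""
        rng = np.random.default_rng(3)
        x = rng.random((2, 6, 6, 1)).astype(np.float32)
        m_skip = build_network(tiny_spec(skip=True), seed=7)
        m_plain = build_network(tiny_spec(skip=False), seed=7)
        assert m_plain._skip_index is None
        # identical weights, same seed: outputs differ only through the skip path
        for pa, pb in zip(m_skip.parameters(), m_plain.parameters()):
            np.testing.assert_array_equal(pa, pb)
        assert not np.allclose(m_skip.forward_logits(x), m_plain.forward_logits(x))

    def test_zero_weight_model_is_uniform(self):
        m = build_network(tiny_spec(skip=False), seed=0)
        for p in m.parameters():
            p[...] = 0.0
        probs = m.predict_proba(np.random.default_rng(1).random((2, 6, 6, 1)))
        np.testing.assert_allclose(probs, 0.25, atol=1e-7)

    def test_wrong_input_shape_rejected(self):
        m = build_network(tiny_spec(), seed=0)
        with pytest.raises(ShapeError):
            m.forward_logits(np.zeros((1, 5, 5, 1)))

    def test_forward_on_patch_object(self):
        from .conftest import constant_patch

        m = build_network(experiment_spec(window=28), seed=0)
        probs = forward(m, constant_patch(100, "C1", w=28))
        assert probs.shape == (4,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_gradients_match_numerical_differences(self):
        """Central-difference check of backprop through conv/pool/skip/fc."""
        m = build_network(tiny_spec(skip=True), seed=3)
        rng = np.random.default_rng(0)
        x = rng.random((4, 6, 6, 1)).astype(np.float32)
        y = np.array([0, 1, 2, 3])

        def loss():
            probs = softmax_head(m.forward_logits(x, train=True))
            return float(-np.log(probs[np.arange(4), y]).mean()), probs

        L, probs = loss()
        d = probs.copy()
        d[np.arange(4), y] -= 1
        m.backward((d / 4).astype(np.float32))
        grads = [g.copy() for g in m.gradients()]
        eps = 1e-3
        for par, g in zip(m.parameters(), grads):
            flat = par.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp, _ = loss()
                flat[i] = old - eps
                lm, _ = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert g.ravel()[i] == pytest.approx(num, abs=5e-3)

    def test_checkpoint_round_trip(self, tmp_path):
        m = build_network(tiny_spec(), seed=4)
        x = np.random.default_rng(0).random((2, 6, 6, 1))
        save_model(m, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        np.testing.assert_allclose(loaded.predict_proba(x), m.predict_proba(x))


class TestComplexity:
    def test_reference_parameter_count_exact(self):
        assert count_params(reference_spec()).total_params == 2_376_210_890
        assert count_params(reference_spec()).params_millions == 2376

    def test_reference_flop_count_exact(self):
        assert count_flops(reference_spec()).total_flops == 2_447_808_384
        assert count_flops(reference_spec()).flops_millions == 2448

    def test_empty_spec_is_zero(self):
        spec = ArchitectureSpec(input_shape=(8, 8, 1), layers=())
        assert count_params(spec).total_params == 0
        assert count_flops(spec).total_flops == 0

    def test_single_conv_hand_count(self):
        # 4x4x1 input, 3x3x2 conv, no pad: 2 filters x (9 weights) + 2 biases = 20
        spec = ArchitectureSpec(input_shape=(4, 4, 1), layers=(ConvSpec(3, 2, 1, 0),))
        assert count_params(spec).total_params == 20
        assert count_flops(spec).total_flops == 72  # 2x2 output x 2 filters x 9

    def test_totals_equal_per_layer_sums(self):
        c = count_params(reference_spec())
        assert c.total_params == sum(r["params"] for r in c.per_layer)
        assert c.total_flops == sum(r["macs"] for r in c.per_layer)

    def test_fc_layers_dominate_reference_totals(self):
        c = count_params(reference_spec())
        assert c.fc_share_params > 90.0
        assert c.fc_share_flops > 90.0

    def test_param_count_matches_instantiated_scalars(self):
        """Oracle equivalence on 50 random specs: symbolic count == live weights."""
        rng = np.random.default_rng(123)
        for _ in range(50):
            spec = random_small_spec(rng)
            expected = build_network(spec, seed=0).n_parameters
            assert count_params(spec).total_params == expected

    def test_conv_flops_match_naive_triple_loop(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            k = int(rng.choice([1, 3, 5]))
            size = int(rng.integers(k, 12))
            f = int(rng.integers(1, 5))
            c_in = int(rng.integers(1, 4))
            pad = int(rng.integers(0, 2))
            spec = ArchitectureSpec(input_shape=(size, size, c_in),
                                    layers=(ConvSpec(k, f, 1, pad),))
            assert count_flops(spec).total_flops == naive_conv_multiply_count(
                size, size, c_in, k, f, 1, pad
            )

    def test_kernel_size_monotonicity(self):
        counts = [
            count_params(experiment_spec(kernel=k)).total_params for k in (3, 5, 7)
        ]
        assert counts[0] < counts[1] < counts[2]
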