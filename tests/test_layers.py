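"""Quaternion layers against brute-force oracles.

The central check: the Hamilton convolution computed as a structured real
convolution must agree (a) with an explicit per-window loop summing
Hamilton products and (b) with finite-difference gradients.  The loop
oracle lives here and never touches the layer code paths.
"""

import numpy as np
import pytest

from qcsanet.autodiff import Tensor, bce_with_logits
from qcsanet.layers import (BatchNorm2d, InitSpec, QuaternionConv2d,
                            QuaternionDense, count_parameters, encode_image,
                            init_quaternion_weights, rotation_conv2d)
from qcsanet.quaternion import conjugate, hamilton_product


from tests_support import loop_hamilton_conv, loop_rotation_conv


class TestEncodeImage:
    def test_rgb_goes_to_imaginary_components(self, rng):
        img = rng.random((5, 6, 3))
        enc = encode_image(img, mode="rgb-imaginary")
        assert enc.shape == (1, 4, 5, 6)
        np.testing.assert_allclose(enc[0, 0], 0.0)
        np.testing.assert_allclose(enc[0, 1:], img.transpose(2, 0, 1), rtol=1e-6)

    def test_gray_replicates(self):
        enc = encode_image(np.full((3, 3), 0.5))
        np.testing.assert_allclose(enc[0, 0], 0.0)
        for k in (1, 2, 3):
            np.testing.assert_allclose(enc[0, k], 0.5)

    def test_zero_image_and_range_validation(self):
        assert encode_image(np.zeros((4, 4))).sum() == 0.0
        with pytest.raises(ValueError):
            encode_image(np.full((4, 4), 1.5))


class TestHamiltonConv:
    def test_degenerate_1x1_is_hamilton_product(self, rng):
        conv = QuaternionConv2d(1, 1, 1, padding="valid", bias=False)
        qin = rng.normal(size=4)
        x = qin.reshape(1, 4, 1, 1).astype(np.float32)
        got = conv(Tensor(x)).data.ravel()
        expected = hamilton_product(conv.weight.data[0, 0, 0, 0], qin)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_identity_kernel_passthrough(self, rng):
        conv = QuaternionConv2d(2, 2, 3, padding="same", bias=False)
        w = np.zeros_like(conv.weight.data)
        w[0, 0, 1, 1] = [1, 0, 0, 0]  # identity quaternion at the center
        w[1, 1, 1, 1] = [1, 0, 0, 0]
        conv.weight.data = w
        x = rng.random((2, 8, 5, 5)).astype(np.float32)
        np.testing.assert_allclose(conv(Tensor(x)).data, x, atol=1e-6)

    def test_matches_loop_oracle_random_case(self, rng):
        conv = QuaternionConv2d(2, 3, 3, padding="valid")
        conv.bias.data = rng.normal(size=conv.bias.shape).astype(np.float32)
        x = rng.random((2, 8, 4, 4)).astype(np.float32)
        got = conv(Tensor(x)).data
        oracle = loop_hamilton_conv(x, conv.weight.data, conv.bias.data)
        assert np.abs(got - oracle).max() < 1e-5

    @pytest.mark.parametrize("cin,cout,k,stride,pad,h,w", [
        (1, 1, 1, (1, 1), "valid", 3, 3),
        (1, 2, 3, (1, 1), "same", 5, 6),
        (2, 1, 3, (2, 2), "valid", 7, 7),
        (3, 2, 3, (1, 2), "same", 6, 5),
        (2, 2, 5, (2, 1), "same", 8, 9),
    ])
    def test_matches_loop_oracle_shapes(self, rng, cin, cout, k, stride, pad, h, w):
        conv = QuaternionConv2d(cin, cout, k, stride=stride, padding=pad)
        x = rng.normal(size=(2, 4 * cin, h, w)).astype(np.float32)
        got = conv(Tensor(x)).data
        p = ((k - 1) // 2,) * 2 if pad == "same" else (0, 0)
        oracle = loop_hamilton_conv(x, conv.weight.data, conv.bias.data,
                                    stride=stride, pad=p)
        assert got.shape == oracle.shape
        assert np.abs(got - oracle).max() < 1e-5

    def test_linearity(self, rng):
        conv = QuaternionConv2d(1, 2, 3, bias=False)
        x1 = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        x2 = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        lhs = conv(Tensor(2.0 * x1 + 3.0 * x2)).data
        rhs = 2.0 * conv(Tensor(x1)).data + 3.0 * conv(Tensor(x2)).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-4)

    def test_channel_mismatch_raises(self, rng):
        conv = QuaternionConv2d(2, 1, 3)
        with pytest.raises(ValueError):
            conv(Tensor(rng.random((1, 4, 5, 5))))

    def test_gradients_match_finite_differences(self, rng):
        conv = QuaternionConv2d(1, 2, 3, stride=(2, 2), padding="same")
        conv.weight.data = conv.weight.data.astype(np.float64)
        conv.bias.data = conv.bias.data.astype(np.float64)
        x = Tensor(rng.normal(size=(2, 4, 5, 5)), requires_grad=True)
        ((conv(x) ** 2.0).sum()).backward()
        for p in (conv.weight, conv.bias, x):
            num = _numeric_grad(lambda: float((conv(Tensor(x.data)) ** 2.0)
                                              .sum().data), p)
            rel = np.abs(num - p.grad).max() / (np.abs(num).max() + 1e-12)
            assert rel < 1e-4


def _numeric_grad(f, p, eps=1e-6):
    num = np.zeros_like(p.data)
    it = np.nditer(p.data, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = p.data[idx]
        p.data[idx] = orig + eps
        fp = f()
        p.data[idx] = orig - eps
        fm = f()
        p.data[idx] = orig
        num[idx] = (fp - fm) / (2 * eps)
    return num


class TestRotationConv:
    def test_identity_single_tap(self, rng):
        # theta = 0, s = 1: w = 1, sandwich is the identity
        w = np.zeros((1, 1, 1, 1, 4))
        w[..., 0] = 1.0
        s = np.ones((1, 1, 1, 1))
        x = rng.normal(size=(1, 4, 3, 3))
        np.testing.assert_allclose(rotation_conv2d(x, w, s), x, atol=1e-12)

    def test_unit_weight_preserves_norm_of_pure_input(self, rng):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        theta = rng.uniform(-np.pi, np.pi)
        w = np.concatenate([[np.cos(theta / 2)],
                            np.sin(theta / 2) * axis]).reshape(1, 1, 1, 1, 4)
        s = np.ones((1, 1, 1, 1))
        x = rng.normal(size=(1, 4, 4, 4))
        x[:, 0] = 0.0  # pure quaternion input
        out = rotation_conv2d(x, w, s)
        np.testing.assert_allclose(out[:, 0], 0.0, atol=1e-12)  # stays pure
        np.testing.assert_allclose(
            np.linalg.norm(out.reshape(1, 1, 4, 4, 4), axis=2),
            np.linalg.norm(x.reshape(1, 1, 4, 4, 4), axis=2), rtol=1e-9)

    @pytest.mark.parametrize("cin,cout,k,h,w", [
        (1, 2, 3, 5, 5), (2, 1, 3, 4, 6), (2, 2, 1, 3, 3)])
    def test_matches_sandwich_loop_oracle(self, rng, cin, cout, k, h, w):
        weight = rng.normal(size=(cout, cin, k, k, 4))
        scales = rng.uniform(0.5, 2.0, size=(cout, cin, k, k))
        x = rng.normal(size=(2, 4 * cin, h, w))
        got = rotation_conv2d(x, weight, scales)
        oracle = loop_rotation_conv(x, weight, scales)
        assert np.abs(got - oracle).max() < 1e-5

    def test_zero_scale_rejected(self, rng):
        with pytest.raises(ZeroDivisionError):
            rotation_conv2d(rng.normal(size=(1, 4, 3, 3)),
                            rng.normal(size=(1, 1, 1, 1, 4)),
                            np.zeros((1, 1, 1, 1)))


class TestQuaternionDense:
    def test_identity_weight_passthrough(self, rng):
        dense = QuaternionDense(1, 1, bias=False)
        dense.weight.data = np.array([[[1.0, 0, 0, 0]]], np.float32)
        x = rng.normal(size=(3, 4)).astype(np.float32)
        np.testing.assert_allclose(dense(Tensor(x)).data, x, atol=1e-7)

    def test_equals_conv_on_1x1_maps(self, rng):
        dense = QuaternionDense(2, 3)
        conv = QuaternionConv2d(2, 3, 1, padding="valid")
        conv.weight.data = dense.weight.data[..., None, None, :].copy()
        conv.bias.data = dense.bias.data.copy()
        x = rng.normal(size=(5, 8)).astype(np.float32)
        got_dense = dense(Tensor(x)).data
        got_conv = conv(Tensor(x.reshape(5, 8, 1, 1))).data.reshape(5, 12)
        np.testing.assert_allclose(got_dense, got_conv, atol=1e-5)

    def test_matches_loop_oracle(self, rng):
        dense = QuaternionDense(3, 2)
        x = rng.normal(size=(2, 12))
        out = np.zeros((2, 2, 4))
        xq = x.reshape(2, 3, 4)
        for b in range(2):
            for o in range(2):
                acc = dense.bias.data[o].astype(float).copy()
                for i in range(3):
                    acc += hamilton_product(dense.weight.data[o, i], xq[b, i])
                out[b, o] = acc
        np.testing.assert_allclose(dense(Tensor(x.astype(np.float32))).data,
                                   out.reshape(2, 8), atol=1e-5)


class TestInit:
    def test_seed_determinism(self):
        spec = InitSpec("quaternion-polar", seed=42)
        w1 = init_quaternion_weights((4, 3, 3, 3), spec)
        w2 = init_quaternion_weights((4, 3, 3, 3), spec)
        np.testing.assert_array_equal(w1, w2)

    @pytest.mark.parametrize("scheme", ["quaternion-polar", "component-glorot"])
    def test_component_variances_match_the_scheme_law(self, scheme):
        # 10^5 draws; closed-form component variances of each scheme
        shape = (500, 50)  # 25_000 quaternions = 10^5 real draws
        w = init_quaternion_weights(shape, InitSpec(scheme, seed=3))
        fan_in, fan_out = 4 * 50, 4 * 500
        if scheme == "quaternion-polar":
            s2 = 1.0 / (2 * fan_in)
            targets = [s2, s2 / 3, s2 / 3, s2 / 3]
        else:
            a2 = 6.0 / (fan_in + fan_out)
            targets = [a2 / 3] * 4
        for c, target in enumerate(targets):
            assert w[..., c].var() == pytest.approx(target, rel=0.10)

    def test_zero_fan_in_rejected(self):
        with pytest.raises(ValueError):
            init_quaternion_weights((1, 0, 3, 3), InitSpec())


class TestParameterCounting:
    def test_conv_count_formula(self):
        conv = QuaternionConv2d(2, 4, 3)
        total, trainable = count_parameters(conv)
        assert total == trainable == 4 * 2 * 4 * 9 + 4 * 4  # 304

    def test_quarter_of_real_conv(self):
        # same real shape 8 -> 16 channels, 3x3: real conv kernel has
        # 16*8*9 = 1152 weights; the quaternion layer shares 4x
        conv = QuaternionConv2d(2, 4, 3, bias=False)
        assert count_parameters(conv)[0] * 4 == 16 * 8 * 9

    def test_empty_model_counts_zero(self):
        from qcsanet.layers import Module

        class Empty(Module):
            pass

        assert count_parameters(Empty()) == (0, 0)

    def test_batchnorm_buffers_count_as_untrainable(self):
        bn = BatchNorm2d(8)
        total, trainable = count_parameters(bn)
        assert trainable == 16          # gamma + beta
        assert total - trainable == 16  # running mean + var
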