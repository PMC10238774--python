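"""Quaternion-valued neural layers.

A quaternion feature map is a real NCHW array whose channel axis is grouped
in quadruples: real channel ``4*c + k`` holds component ``k`` (order
r, x, y, z) of quaternion channel ``c``.  The Hamilton-product convolution
is computed as an ordinary real convolution whose kernel is built from the
quaternion weight components via the structured 4x4 block

    [[ r, -x, -y, -z],
     [ x,  r, -z,  y],
     [ y,  z,  r, -x],
     [ z, -y,  x,  r]]

so each quaternion weight (4 real parameters) stands in for the 16 free
entries of an unconstrained real block — the 4x parameter sharing that
motivates quaternion networks.

Layers use single precision; the algebra core and the test oracles stay in
double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, conv2d, structured_expand
from .quaternion import conjugate, hamilton_product

__all__ = [
    "HAMILTON_MIXING",
    "InitSpec",
    "Module",
    "Parameter",
    "QuaternionConv2d",
    "QuaternionDense",
    "BatchNorm2d",
    "Dense",
    "encode_image",
    "init_quaternion_weights",
    "count_parameters",
    "rotation_conv2d",
]

# HAMILTON_MIXING[a, b, c] is the coefficient of weight component c in row a
# (output component), column b (input component) of the block above.
HAMILTON_MIXING = np.zeros((4, 4, 4))
for _a, _row in enumerate([[(0, +1), (1, -1), (2, -1), (3, -1)],
                           [(1, +1), (0, +1), (3, -1), (2, +1)],
                           [(2, +1), (3, +1), (0, +1), (1, -1)],
                           [(3, +1), (2, -1), (1, +1), (0, +1)]]):
    for _b, (_c, _s) in enumerate(_row):
        HAMILTON_MIXING[_a, _b, _c] = _s


@dataclass(frozen=True)
class InitSpec:
    """Weight initialization: scheme name plus the seed that determines it."""

    scheme: str = "quaternion-polar"
    seed: int = 0


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class: parameter/buffer discovery and train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (running statistics, frozen kernels)."""
        out: list[np.ndarray] = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.buffers())
        out.extend(getattr(self, "_buffers", []))
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def state_arrays(self) -> list[np.ndarray]:
        """Snapshot of all parameters followed by all buffers."""
        return ([p.data.copy() for p in self.parameters()]
                + [b.copy() for b in self.buffers()])

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        buffers = self.buffers()
        if len(arrays) != len(params) + len(buffers):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays[:len(params)]):
            p.data = a.copy()
        for b, a in zip(buffers, arrays[len(params):]):
            b[...] = a  # in place: buffer arrays are shared by reference


def _fans(c_in_real: int, c_out_real: int, receptive: int) -> tuple[int, int]:
    return c_in_real * receptive, c_out_real * receptive


def init_quaternion_weights(shape: tuple[int, ...], spec: InitSpec) -> np.ndarray:
    """Draw quaternion weights of ``shape + (4,)``.

    ``shape`` is ``(out_q, in_q, kh, kw)`` for a convolution or
    ``(out_q, in_q)`` for a dense layer.

    quaternion-polar: magnitude ~ Rayleigh(sigma) with
    ``sigma^2 = 1/(2 * fan_in)`` (real fan-in), phase uniform in (-pi, pi],
    axis uniform on the unit sphere of pure quaternions.  Component
    variances follow in closed form: ``Var(r) = sigma^2``,
    ``Var(x) = Var(y) = Var(z) = sigma^2 / 3``.

    component-glorot: each of r, x, y, z independently
    ``U(-a, a)`` with ``a = sqrt(6 / (fan_in + fan_out))`` on real fans.
    """
    if len(shape) == 2:
        out_q, in_q = shape
        receptive = 1
    elif len(shape) == 4:
        out_q, in_q, kh, kw = shape
        receptive = kh * kw
    else:
        raise ValueError(f"unsupported weight shape {shape}")
    if in_q <= 0 or out_q <= 0:
        raise ValueError("fan-in and fan-out must be positive")
    fan_in, fan_out = _fans(4 * in_q, 4 * out_q, receptive)
    rng = np.random.default_rng(spec.seed)
    n = int(np.prod(shape))
    if spec.scheme == "quaternion-polar":
        sigma = np.sqrt(1.0 / (2.0 * fan_in))
        rho = rng.rayleigh(scale=sigma, size=n)
        theta = rng.uniform(-np.pi, np.pi, size=n)
        axis = rng.normal(size=(n, 3))
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        w = np.empty((n, 4))
        w[:, 0] = rho * np.cos(theta)
        w[:, 1:] = (rho * np.sin(theta))[:, None] * axis
    elif spec.scheme == "component-glorot":
        a = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-a, a, size=(n, 4))
    else:
        raise ValueError(f"unknown init scheme {spec.scheme!r}")
    return w.reshape(shape + (4,))


class QuaternionConv2d(Module):
    """Hamilton-product 2-D convolution over quaternion feature maps.

    ``in_channels``/``out_channels`` count quaternion channels; the real
    channel counts are four times larger.  Padding modes: ``"same"``
    (symmetric zero padding, odd kernels) or ``"valid"``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: tuple[int, int] | int = (1, 1), padding: str = "same",
                 bias: bool = True, init: InitSpec | None = None):
        super().__init__()
        if isinstance(stride, int):
            stride = (stride, stride)
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        if padding == "same" and kernel_size % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        init = init or InitSpec()
        self.weight = Parameter(init_quaternion_weights(
            (out_channels, in_channels, kernel_size, kernel_size), init
        ).astype(np.float32))
        self.bias = Parameter(np.zeros((out_channels, 4), np.float32)) if bias else None

    def _pad(self) -> tuple[int, int]:
        if self.padding == "same":
            p = (self.kernel_size - 1) // 2
            return (p, p)
        return (0, 0)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 4 * self.in_channels:
            raise ValueError(
                f"expected {4 * self.in_channels} real channels, got {x.shape[1]}")
        # weight layout (O, I, kh, kw, 4) -> structured real kernel (4O, 4I, kh, kw)
        rk = structured_expand(self.weight, HAMILTON_MIXING)
        b = self.bias.reshape(4 * self.out_channels) if self.bias is not None else None
        return conv2d(x, rk, b, stride=self.stride, padding=self._pad())


class QuaternionDense(Module):
    """Hamilton-product fully connected layer on flat quaternion vectors.

    Input ``(B, 4*in_features)`` with components grouped per quaternion;
    equivalent to :class:`QuaternionConv2d` with a 1x1 kernel on 1x1 maps.
    """

    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 init: InitSpec | None = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        init = init or InitSpec()
        self.weight = Parameter(init_quaternion_weights(
            (out_features, in_features), init).astype(np.float32))
        self.bias = Parameter(np.zeros((out_features, 4), np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != 4 * self.in_features:
            raise ValueError(
                f"expected {4 * self.in_features} real features, got {x.shape[-1]}")
        rk = structured_expand(self.weight, HAMILTON_MIXING)  # (4O, 4I)
        out = x @ rk.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias.reshape(4 * self.out_features)
        return out


class Dense(Module):
    """Plain real affine layer (classification head)."""

    def __init__(self, in_features: int, out_features: int, seed: int = 0,
                 zero_init: bool = False):
        super().__init__()
        rng = np.random.default_rng(seed)
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            a = np.sqrt(6.0 / (in_features + out_features))
            w = rng.uniform(-a, a, size=(in_features, out_features))
        self.weight = Parameter(w.astype(np.float32))
        self.bias = Parameter(np.zeros(out_features, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Component-wise (split) batch normalisation over the real channel axis.

    Each of the ``4*C_q`` real channels is normalised independently; the
    running mean/variance used at evaluation time are non-trainable buffers,
    counted in the total-but-not-trainable parameter tally.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1), np.float32))
        self.beta = Parameter(np.zeros((1, channels, 1, 1), np.float32))
        self.running_mean = np.zeros((1, channels, 1, 1), np.float32)
        self.running_var = np.ones((1, channels, 1, 1), np.float32)
        self._buffers = [self.running_mean, self.running_var]

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean *= (1 - m)
            self.running_mean += m * mu.data.astype(np.float32)
            self.running_var *= (1 - m)
            self.running_var += m * var.data.astype(np.float32)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * (
                (Tensor(self.running_var) + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


def encode_image(images: np.ndarray, mode: str = "gray-replicate") -> np.ndarray:
    """Project images in [0, 1] into the quaternion domain.

    ``gray-replicate``: pixel g -> (0, g, g, g); ``rgb-imaginary``: pixel
    (R, G, B) -> (0, R, G, B) — the three imaginary components carry the
    color planes, the real part is zero.  Accepts a single image (H, W) or
    (H, W, 3) or a batch with a leading axis; returns (B, 4, H, W).
    """
    images = np.asarray(images, dtype=np.float32)
    if images.min() < 0.0 or images.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    if mode == "gray-replicate":
        if images.ndim == 2:
            images = images[None]
        if images.ndim != 3:
            raise ValueError("gray-replicate expects (H, W) or (B, H, W)")
        b, h, w = images.shape
        out = np.zeros((b, 4, h, w), np.float32)
        for k in (1, 2, 3):
            out[:, k] = images
        return out
    if mode == "rgb-imaginary":
        if images.ndim == 3:
            images = images[None]
        if images.ndim != 4 or images.shape[-1] != 3:
            raise ValueError("rgb-imaginary expects (H, W, 3) or (B, H, W, 3)")
        b, h, w, _ = images.shape
        out = np.zeros((b, 4, h, w), np.float32)
        out[:, 1:] = images.transpose(0, 3, 1, 2)
        return out
    raise ValueError(f"unknown encoding mode {mode!r}")


def count_parameters(module: Module) -> tuple[int, int]:
    """(total, trainable) real-parameter counts.

    Trainable counts every element of every :class:`Parameter`; total adds
    non-trainable buffers (batch-norm running statistics, frozen attention
    kernels), mirroring the usual total/trainable split of model summaries.
    """
    trainable = sum(p.size for p in module.parameters())
    frozen = sum(b.size for b in module.buffers())
    return trainable + frozen, trainable


def rotation_conv2d(x: np.ndarray, weights: np.ndarray, scales: np.ndarray,
                    stride: tuple[int, int] = (1, 1)) -> np.ndarray:
    """Rotation/scaling quaternion convolution (valid padding, inference).

    Each kernel tap is a quaternion ``w = s (cos(theta/2) + mu sin(theta/2))``
    acting on the input quaternion ``q`` by the scaled sandwich product
    ``(1/s) w q w*``, summed over the window and input channels.  A pure
    input stays pure because the sandwich product preserves the real part
    (zero) and ``(1/s) * s^2 = s`` only rescales.

    ``x``: (B, 4*C_in, H, W) with quaternion-grouped channels;
    ``weights``: (C_out, C_in, kh, kw, 4); ``scales``: (C_out, C_in, kh, kw)
    — all non-zero.  Returns (B, 4*C_out, Ho, Wo).
    """
    from numpy.lib.stride_tricks import sliding_window_view

    if np.any(scales == 0):
        raise ZeroDivisionError("rotation-conv scale factors must be non-zero")
    if x.shape[1] % 4:
        raise ValueError("real channel count must be divisible by 4")
    x = x.reshape(x.shape[0], x.shape[1] // 4, 4, x.shape[2], x.shape[3])
    sh, sw = stride
    kh, kw = weights.shape[2], weights.shape[3]
    win = sliding_window_view(x, (kh, kw), axis=(3, 4))[:, :, :, ::sh, ::sw]
    # win: (B, Cin, 4, Ho, Wo, kh, kw) -> (B, Cin, Ho, Wo, kh, kw, 4)
    win = np.moveaxis(win, 2, -1)
    b_, cin, ho, wo = win.shape[:4]
    cout = weights.shape[0]
    w = weights[None, :, :, None, None]        # (1, Cout, Cin, 1, 1, kh, kw, 4)
    q = win[:, None]                            # (B, 1, Cin, Ho, Wo, kh, kw, 4)
    sandwich = hamilton_product(hamilton_product(w, q), conjugate(w))
    sandwich = sandwich / scales[None, :, :, None, None, :, :, None]
    out = sandwich.sum(axis=(2, 5, 6))          # (B, Cout, Ho, Wo, 4)
    out = np.moveaxis(out, -1, 2)               # (B, Cout, 4, Ho, Wo)
    return out.reshape(out.shape[0], 4 * cout, ho, wo)
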