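"""Channel and spatial attention gates for quaternion feature maps.

Channel attention squeezes the spatial extent of a feature map into two
per-channel descriptors (global average pool and global max pool), passes
both through a shared bottleneck MLP (or, in parameter-free mode, simply
standardises and sums them), and emits one sigmoid gate per attended
channel.  Spatial attention pools along the channel axis instead, stacks
the mean and max maps, and convolves them down to a single sigmoid gate
per pixel — "where to look" as opposed to channel attention's "what to
look at".

With the default per-quaternion-channel granularity all four components of
a quaternion channel share one gate, so gating never tears a quaternion
apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, conv2d
from .layers import Module, Parameter

__all__ = [
    "AttentionConfig",
    "ChannelAttention",
    "SpatialAttention",
    "AttentionBlock",
    "softmax_attention",
    "save_attention_maps",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Configuration of one channel+spatial attention block.

    reduction_ratio: bottleneck factor of the channel-attention MLP; must
        divide the attended channel count.
    spatial_kernel: odd size of the spatial-attention convolution.
    parameterized: if False, both gates are computed without any learnable
        parameters (standardised descriptors / fixed uniform kernel).
    granularity: 'per-quaternion-channel' shares one gate across the four
        components of each quaternion; 'per-real-channel' gates components
        independently.
    """

    reduction_ratio: int = 8
    spatial_kernel: int = 7
    parameterized: bool = True
    granularity: str = "per-quaternion-channel"

    def __post_init__(self) -> None:
        if self.spatial_kernel % 2 == 0 or self.spatial_kernel < 1:
            raise ValueError("spatial_kernel must be a positive odd integer")
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be a positive integer")
        if self.granularity not in ("per-quaternion-channel", "per-real-channel"):
            raise ValueError(f"unknown granularity {self.granularity!r}")


def _attended_channels(real_channels: int, cfg: AttentionConfig) -> int:
    if cfg.granularity == "per-quaternion-channel":
        if real_channels % 4:
            raise ValueError("real channel count must be divisible by 4")
        return real_channels // 4
    return real_channels


class ChannelAttention(Module):
    """Per-channel sigmoid gate from pooled spatial descriptors."""

    def __init__(self, real_channels: int, cfg: AttentionConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.real_channels = real_channels
        self.channels = _attended_channels(real_channels, cfg)
        if cfg.parameterized:
            if self.channels % cfg.reduction_ratio:
                raise ValueError(
                    f"reduction_ratio {cfg.reduction_ratio} does not divide "
                    f"the attended channel count {self.channels}")
            hidden = self.channels // cfg.reduction_ratio
            rng = np.random.default_rng(seed)
            a1 = np.sqrt(6.0 / (self.channels + hidden))
            a2 = np.sqrt(6.0 / (hidden + self.channels))
            self.w1 = Parameter(rng.uniform(-a1, a1,
                                            (self.channels, hidden)).astype(np.float32))
            self.w2 = Parameter(rng.uniform(-a2, a2,
                                            (hidden, self.channels)).astype(np.float32))

    def _descriptors(self, x: Tensor) -> tuple[Tensor, Tensor]:
        b, c, h, w = x.shape
        if self.cfg.granularity == "per-quaternion-channel":
            xq = x.reshape(b, c // 4, 4, h, w)
            avg = xq.mean(axis=(2, 3, 4))
            mx = xq.max(axis=4).max(axis=3).max(axis=2)
        else:
            avg = x.mean(axis=(2, 3))
            mx = x.max(axis=3).max(axis=2)
        return avg, mx

    def _squeeze(self, d: Tensor) -> Tensor:
        return (d @ self.w1).relu() @ self.w2

    def forward(self, x: Tensor) -> Tensor:
        """Return the channel gate, shape (B, attended_channels), in (0,1)."""
        avg, mx = self._descriptors(x)
        if self.cfg.parameterized:
            score = self._squeeze(avg) + self._squeeze(mx)
        else:
            score = _standardize(avg) + _standardize(mx)
        return score.sigmoid()

    def apply(self, x: Tensor, gate: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if self.cfg.granularity == "per-quaternion-channel":
            xq = x.reshape(b, c // 4, 4, h, w)
            out = xq * gate.reshape(b, c // 4, 1, 1, 1)
            return out.reshape(b, c, h, w)
        return x * gate.reshape(b, c, 1, 1)


def _standardize(d: Tensor, eps: float = 1e-5) -> Tensor:
    """Zero-mean, unit-variance across the channel axis (parameter-free)."""
    mu = d.mean(axis=1, keepdims=True)
    var = ((d - mu) ** 2.0).mean(axis=1, keepdims=True)
    return (d - mu) * ((var + eps) ** -0.5)


class SpatialAttention(Module):
    """Per-pixel sigmoid gate from channel-pooled mean/max maps.

    Parameterized mode learns one ``k x k`` convolution (2 -> 1 channels,
    with bias); parameter-free mode uses a fixed uniform positive kernel
    built on the fly, so the block owns no state at all.
    """

    def __init__(self, cfg: AttentionConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        k = cfg.spatial_kernel
        if cfg.parameterized:
            rng = np.random.default_rng(seed)
            a = np.sqrt(6.0 / (2 * k * k + 1))
            self.kernel = Parameter(rng.uniform(-a, a, (1, 2, k, k)).astype(np.float32))
            self.bias = Parameter(np.zeros(1, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        """Return the spatial gate, shape (B, 1, H, W), in (0,1)."""
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        stacked = concat([avg, mx], axis=1)
        k = self.cfg.spatial_kernel
        if self.cfg.parameterized:
            kernel, bias = self.kernel, self.bias
        else:
            kernel = Tensor(np.full((1, 2, k, k), 1.0 / (2 * k * k), np.float32))
            bias = None
        p = (k - 1) // 2
        return conv2d(stacked, kernel, bias, padding=(p, p)).sigmoid()

    @staticmethod
    def apply(x: Tensor, gate: Tensor) -> Tensor:
        return x * gate


class AttentionBlock(Module):
    """Channel-then-spatial gating; preserves tensor shape.

    ``bypass=True`` forces both gates to one (the ablation hook); the most
    recent gates are kept as NumPy arrays for inspection/export.
    """

    def __init__(self, real_channels: int, cfg: AttentionConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.channel = ChannelAttention(real_channels, cfg, seed=seed)
        self.spatial = SpatialAttention(cfg, seed=seed + 1)
        self.bypass = False
        self.last_channel_gate: np.ndarray | None = None
        self.last_spatial_gate: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        if self.bypass:
            return x
        cg = self.channel(x)
        x = self.channel.apply(x, cg)
        sg = self.spatial(x)
        x = SpatialAttention.apply(x, sg)
        self.last_channel_gate = cg.data.copy()
        self.last_spatial_gate = sg.data[:, 0].copy()
        return x


def softmax_attention(h: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Soft attention over encoded vectors.

    ``alpha_i = exp(h_i . v) / sum_j exp(h_j . v)`` (computed with
    max-subtraction for stability) and the context ``O = sum_i alpha_i h_i``.

    h: (n, d) sequence of encoded vectors; v: (d,) query.
    Returns (alpha of shape (n,), context of shape (d,)).
    """
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    if h.ndim != 2 or h.shape[0] == 0:
        raise ValueError("h must be a nonempty (n, d) array")
    if v.shape != (h.shape[1],):
        raise ValueError("query dimension must match the encoded vectors")
    scores = h @ v
    scores = scores - scores.max()
    e = np.exp(scores)
    alpha = e / e.sum()
    return alpha, alpha @ h


def save_attention_maps(block: AttentionBlock, out_prefix: str) -> list[str]:
    """Write the block's most recent spatial gates as grayscale PNGs.

    One file per image in the batch, named ``<prefix>_<index>.png``;
    returns the written paths.  Gates are in (0,1) and map directly to
    8-bit intensity.
    """
    from PIL import Image

    if block.last_spatial_gate is None:
        raise RuntimeError("run a forward pass before exporting attention maps")
    paths = []
    for i, gate in enumerate(block.last_spatial_gate):
        img = Image.fromarray((np.clip(gate, 0, 1) * 255).astype(np.uint8), mode="L")
        path = f"{out_prefix}_{i}.png"
        img.save(path)
        paths.append(path)
    return paths
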