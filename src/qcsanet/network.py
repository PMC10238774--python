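"""The QCSA classifier network: quaternion residual blocks with attention.

The architecture is a compact residual stack in the quaternion domain: a
stem quaternion convolution, four residual blocks (each two Hamilton
convolutions with split batch-norm/ReLU, an attention block before the
skip-add, and 2x spatial downsampling from the second block on), global
average pooling, and a real sigmoid head for the binary decision.

Block widths are configurable; the printed layout of the original
architecture is under-determined, so the default widths are a desk-scale
stand-in and a ``miniature`` preset exists for CPU-bound experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .attention import AttentionBlock, AttentionConfig
from .autodiff import Tensor
from .layers import (BatchNorm2d, Dense, InitSpec, Module, QuaternionConv2d,
                     count_parameters, encode_image)

__all__ = ["ModelConfig", "ResidualBlock", "QcsaNetwork",
           "build_residual_block", "build_qcsa_network", "predict"]


class ConfigError(ValueError):
    """Raised when a model configuration field is invalid."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture configuration.

    input_size: (H, W) of the preprocessed image, default 50x50.
    block_widths: quaternion-channel count of the four residual blocks.
    conv_variant: 'hamilton' (trainable default); the rotation variant is
        available as a standalone op, not as a trainable block.
    attention: gate configuration; ``use_attention=False`` builds the plain
        quaternion residual twin for ablation.
    head: 'flatten' turns the pooled quaternion features into real features
        component-wise; 'quaternion-norm' reduces each quaternion to its
        magnitude first.
    """

    input_size: tuple[int, int] = (50, 50)
    block_widths: tuple[int, ...] = (8, 16, 32, 64)
    conv_variant: str = "hamilton"
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    use_attention: bool = True
    num_classes: int = 2
    head: str = "flatten"
    init_scheme: str = "quaternion-polar"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_widths) != 4:
            raise ConfigError("block_widths: exactly four residual blocks are used")
        if any(w < 1 for w in self.block_widths):
            raise ConfigError("block_widths: widths must be positive")
        h, w = self.input_size
        if h < 8 or w < 8:
            raise ConfigError("input_size: height and width must be >= 8")
        if self.num_classes != 2:
            raise ConfigError("num_classes: only binary classification is supported")
        if self.conv_variant not in ("hamilton",):
            raise ConfigError("conv_variant: only 'hamilton' builds a trainable model")
        if self.head not in ("flatten", "quaternion-norm"):
            raise ConfigError("head: must be 'flatten' or 'quaternion-norm'")

    @staticmethod
    def miniature(**overrides) -> "ModelConfig":
        """Small CPU-friendly preset used by the synthetic-data experiments."""
        cfg = ModelConfig(block_widths=(2, 4, 4, 8),
                          attention=AttentionConfig(reduction_ratio=2))
        return replace(cfg, **overrides) if overrides else cfg


class ResidualBlock(Module):
    """conv-BN-ReLU-conv-BN -> attention -> skip-add -> ReLU."""

    def __init__(self, width_in: int, width_out: int, cfg: ModelConfig,
                 stride: int = 1, seed: int = 0):
        super().__init__()
        init1 = InitSpec(cfg.init_scheme, seed)
        init2 = InitSpec(cfg.init_scheme, seed + 1)
        # bias-free convs: batch-norm's mean subtraction would cancel any
        # bias exactly, leaving dead parameters
        self.conv1 = QuaternionConv2d(width_in, width_out, 3, stride=stride,
                                      padding="same", bias=False, init=init1)
        self.bn1 = BatchNorm2d(4 * width_out)
        self.conv2 = QuaternionConv2d(width_out, width_out, 3, stride=1,
                                      padding="same", bias=False, init=init2)
        self.bn2 = BatchNorm2d(4 * width_out)
        self.attention: AttentionBlock | None = None
        if cfg.use_attention:
            self.attention = AttentionBlock(4 * width_out, cfg.attention,
                                            seed=seed + 2)
        self.project: QuaternionConv2d | None = None
        if width_in != width_out or stride != 1:
            self.project = QuaternionConv2d(
                width_in, width_out, 1, stride=stride, padding="valid",
                bias=False, init=InitSpec(cfg.init_scheme, seed + 3))

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        if self.attention is not None:
            out = self.attention(out)
        skip = self.project(x) if self.project is not None else x
        return (out + skip).relu()


class QcsaNetwork(Module):
    """Full quaternion channel-spatial attention classifier."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        w0 = cfg.block_widths[0]
        self.stem = QuaternionConv2d(1, w0, 3, padding="same",
                                     init=InitSpec(cfg.init_scheme, cfg.seed))
        widths = [w0, *cfg.block_widths]
        strides = [1, 2, 2, 2]  # blocks 2-4 halve the spatial extent
        self.blocks = [
            ResidualBlock(widths[i], widths[i + 1], cfg, stride=strides[i],
                          seed=cfg.seed + 10 * (i + 1))
            for i in range(4)
        ]
        w_last = cfg.block_widths[-1]
        head_in = 4 * w_last if cfg.head == "flatten" else w_last
        self.head = Dense(head_in, 1, seed=cfg.seed + 99)

    def forward(self, x: Tensor) -> Tensor:
        """Quaternion feature map (B, 4, H, W) -> logits (B,)."""
        out = self.stem(x)
        for block in self.blocks:
            out = block(out)
        pooled = out.mean(axis=(2, 3))  # (B, 4*w_last)
        if self.cfg.head == "quaternion-norm":
            b, c = pooled.shape
            q = pooled.reshape(b, c // 4, 4)
            pooled = ((q ** 2.0).sum(axis=2) + 1e-12) ** 0.5
        logits = self.head(pooled)
        return logits.reshape(logits.shape[0])

    def set_attention_bypass(self, bypass: bool) -> None:
        """Force all attention gates to one (ablation hook)."""
        for block in self.blocks:
            if block.attention is not None:
                block.attention.bypass = bypass

    def attention_blocks(self) -> list[AttentionBlock]:
        return [b.attention for b in self.blocks if b.attention is not None]

    def layer_table(self) -> list[tuple[str, int, int]]:
        """(name, total, trainable) per top-level layer, for inspection."""
        rows = [("stem", *count_parameters(self.stem))]
        for i, block in enumerate(self.blocks, start=1):
            rows.append((f"block{i}", *count_parameters(block)))
        rows.append(("head", *count_parameters(self.head)))
        return rows


def build_residual_block(width_in: int, width_out: int, cfg: ModelConfig,
                         stride: int = 1, seed: int = 0) -> ResidualBlock:
    return ResidualBlock(width_in, width_out, cfg, stride=stride, seed=seed)


def build_qcsa_network(cfg: ModelConfig) -> QcsaNetwork:
    return QcsaNetwork(cfg)


def predict(model: QcsaNetwork, images: np.ndarray, batch_size: int = 64,
            encode_mode: str = "gray-replicate") -> np.ndarray:
    """Class-1 probabilities for a batch of images in [0, 1].

    ``images`` may already be encoded (B, 4, H, W) or raw (B, H, W) /
    (B, H, W, 3); order-preserving; evaluation mode (running BN statistics).
    """
    images = np.asarray(images)
    if images.ndim != 4 or images.shape[1] != 4:
        images = encode_image(images, mode=encode_mode)
    h, w = model.cfg.input_size
    if images.shape[2:] != (h, w):
        raise ValueError(f"expected {h}x{w} input, got {images.shape[2:]}")
    was_training = model.training
    model.eval()
    probs = []
    for lo in range(0, images.shape[0], batch_size):
        logits = model(Tensor(images[lo:lo + batch_size]))
        probs.append(1.0 / (1.0 + np.exp(-logits.data)))
    model.train(was_training)
    return np.concatenate(probs) if probs else np.empty(0)
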