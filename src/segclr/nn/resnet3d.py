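"""3D ResNet-18 trunk and the contrastive encoder built on it.

The encoder follows the ResNet-18 layout with all convolutions extended to
three dimensions: a 7x7x7 stride-2 stem, 3x3x3 max pooling, four stages of
two basic blocks each, and global average pooling. Three fully connected
bottleneck layers map the pooled features to the 64-dimensional embedding;
during contrastive training three further projection layers map the
embedding to a 16-dimensional output on which the contrastive loss acts.

The default ("full-size") widths — bottleneck 512, 512, 64 and
projection 144, 64, 16 — give a training-time network of exactly
33,737,824 trainable parameters for a single-channel input.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .layers import (BasicBlock3d, Conv3d, BatchNorm3d, Dense, GlobalAvgPool3d,
                     Layer, MaxPool3d, ReLU, Sequential, parameter_count)


@dataclass(frozen=True)
class EncoderConfig:
    view_size: int = 129
    in_channels: int = 1
    base_channels: int = 64
    block_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    bottleneck_widths: tuple[int, int, int] = (512, 512, 64)
    projection_widths: tuple[int, int, int] = (144, 64, 16)
    stem_kernel: int = 7

    @property
    def embedding_dim(self) -> int:
        return self.bottleneck_widths[-1]

    @property
    def projection_dim(self) -> int:
        return self.projection_widths[-1]

    def __post_init__(self):
        if any(w <= 0 for w in (self.view_size, self.base_channels,
                                *self.block_widths, *self.bottleneck_widths,
                                *self.projection_widths)):
            raise ValueError("all widths must be positive")

    @classmethod
    def full_size(cls) -> "EncoderConfig":
        """Full-size configuration: 129-voxel views, 64-d embedding, 16-d
        projection, 33,737,824 trainable parameters."""
        return cls()

    @classmethod
    def toy(cls, view_size: int = 33, base_channels: int = 8) -> "EncoderConfig":
        w = base_channels
        return cls(view_size=view_size, base_channels=w,
                   block_widths=(w, 2 * w, 4 * w, 8 * w),
                   bottleneck_widths=(8 * w, 8 * w, 64),
                   projection_widths=(64, 64, 16), stem_kernel=3)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        d = dict(d)
        for key in ("block_widths", "bottleneck_widths", "projection_widths"):
            d[key] = tuple(d[key])
        return cls(**d)


def build_trunk(config: EncoderConfig, *, rng: np.random.Generator) -> Sequential:
    """Convolutional trunk: stem + 4 residual stages + global pooling."""
    w = config.block_widths
    k = config.stem_kernel
    layers: list[Layer] = [
        Conv3d(config.in_channels, config.base_channels, k, stride=2, pad=k // 2, rng=rng),
        BatchNorm3d(config.base_channels),
        ReLU(),
        MaxPool3d(3, 2, 1),
    ]
    in_ch = config.base_channels
    for stage, width in enumerate(w):
        for block in range(2):
            stride = 2 if (stage > 0 and block == 0) else 1
            layers.append(BasicBlock3d(in_ch, width, stride, rng=rng))
            in_ch = width
    layers.append(GlobalAvgPool3d())
    return Sequential(*layers)


def _mlp(in_dim: int, widths: tuple[int, ...], *, rng: np.random.Generator) -> Sequential:
    layers: list[Layer] = []
    for i, width in enumerate(widths):
        layers.append(Dense(in_dim, width, rng=rng))
        if i < len(widths) - 1:
            layers.append(ReLU())
        in_dim = width
    return Sequential(*layers)


class Encoder:
    """Trunk + bottleneck (embedding) + projection head (training only)."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.trunk = build_trunk(config, rng=rng)
        self.bottleneck = _mlp(config.block_widths[-1], config.bottleneck_widths, rng=rng)
        self.projection = _mlp(config.embedding_dim, config.projection_widths, rng=rng)
        self._all = Sequential(self.trunk, self.bottleneck, self.projection)

    # -- forward / backward ------------------------------------------------
    def forward(self, views: np.ndarray, with_projection: bool = True):
        """Returns (embeddings, projections) for (N, 1, V, V, V) input."""
        feats = self.trunk.forward(views)
        emb = self.bottleneck.forward(feats)
        proj = self.projection.forward(emb) if with_projection else None
        return emb, proj

    def backward(self, d_emb: np.ndarray | None, d_proj: np.ndarray | None):
        grad = np.zeros_like(d_emb) if d_emb is None else d_emb.copy()
        if d_proj is not None:
            grad += self.projection.backward(d_proj)
        return self.trunk.backward(self.bottleneck.backward(grad))

    def embed(self, views: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """64-d embeddings in eval mode; the projection head is dropped."""
        self.set_training(False)
        out = []
        for i in range(0, len(views), batch_size):
            emb, _ = self.forward(views[i:i + batch_size], with_projection=False)
            out.append(emb)
        return np.concatenate(out, axis=0) if out else np.zeros((0, self.config.embedding_dim), np.float32)

    # -- bookkeeping -------------------------------------------------------
    def parameters(self):
        return self._all.parameters()

    def parameter_count(self) -> int:
        return parameter_count(self._all)

    def set_training(self, flag: bool):
        self._all.set_training(flag)

    @property
    def state_container(self) -> Sequential:
        return self._all


def build_encoder(config: EncoderConfig, seed: int = 0) -> tuple[Encoder, int]:
    """Instantiate the encoder; returns (model, trainable parameter count)."""
    enc = Encoder(config, seed=seed)
    return enc, enc.parameter_count()
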