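"""Construction of the single-fidelity segmentation networks.

Thin configuration layer over the architecture classes in
:mod:`strain2infarct.nn`: a :class:`NetworkConfig` fixes the family
(UNet, attention UNet, dense UNet, residual attention UNet), the input
size and the channel schedule (base 16 doubling per level to 256 at
depth 5), and :func:`build_network` instantiates a seeded model.  The
base UNet with the default schedule has exactly 1,941,105 trainable
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (AttentionUNet, DenseUNet, ResidualAttentionUNet, Tensor,
                 UNet, UNetBase)

ARCHITECTURES = {
    "unet": UNet,
    "attention_unet": AttentionUNet,
    "dense_unet": DenseUNet,
    "residual_attention_unet": ResidualAttentionUNet,
}

VALID_INPUT_SIZES = (128, 256, 512)


@dataclass(frozen=True)
class NetworkConfig:
    architecture: str = "unet"
    input_size: int = 128
    in_channels: int = 3
    base_channels: int = 16
    depth: int = 5
    seed: int | None = None

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        div = 2 ** (self.depth - 1)
        if self.input_size % div:
            raise ValueError(
                f"input size {self.input_size} must be divisible by {div}")

    @property
    def channel_widths(self) -> tuple:
        return tuple(self.base_channels * 2 ** i for i in range(self.depth))


def build_network(config: NetworkConfig) -> UNetBase:
    cls = ARCHITECTURES[config.architecture]
    return cls(in_channels=config.in_channels,
               base_channels=config.base_channels,
               depth=config.depth, seed=config.seed)


def build_unet(config: NetworkConfig) -> UNet:
    if config.architecture != "unet":
        config = NetworkConfig(**{**config.__dict__, "architecture": "unet"})
    return build_network(config)


def build_attention_unet(config: NetworkConfig) -> AttentionUNet:
    config = NetworkConfig(**{**config.__dict__, "architecture": "attention_unet"})
    return build_network(config)


def build_dense_unet(config: NetworkConfig) -> DenseUNet:
    config = NetworkConfig(**{**config.__dict__, "architecture": "dense_unet"})
    return build_network(config)


def build_residual_attention_unet(config: NetworkConfig) -> ResidualAttentionUNet:
    config = NetworkConfig(
        **{**config.__dict__, "architecture": "residual_attention_unet"})
    return build_network(config)


def forward_proba(model: UNetBase, images: np.ndarray,
                  batch_size: int = 8) -> np.ndarray:
    """Per-pixel probabilities for (n, H, W, 3) images -> (n, H, W)."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    model.set_training(False)
    out = []
    for i in range(0, images.shape[0], batch_size):
        x = Tensor(images[i:i + batch_size].transpose(0, 3, 1, 2))
        out.append(model(x).data[:, 0])
    model.set_training(True)
    return np.concatenate(out, axis=0)


def predict_mask(model: UNetBase, image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Binarize per-pixel probabilities at the sigmoid threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    proba = forward_proba(model, image)
    mask = (proba >= threshold).astype(np.uint8)
    return mask[0] if np.asarray(image).ndim == 3 else mask
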