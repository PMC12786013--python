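"""Modality-specific encoders mapping images to a shared latent space.

Three encoders with modality-appropriate pooling semantics:

* endoscopy — CNN backbone over RGB frames;
* CT — CNN backbone applied per slice, slice embeddings aggregated by
  global average pooling into one case-level vector;
* histology — backbone applied per patch, patch embeddings aggregated by
  learned attention pooling (multiple-instance style).

All encoders project into the same ``d_latent`` width so the fusion stage
can treat them as exchangeable tokens.  Backbones are configurable: compact
CNN / patch-transformer backbones are the default and train in minutes on a
CPU; large pretrained architectures are declared in the config enum for
interface compatibility but require externally supplied weights and are not
bundled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Parameter, Tensor
from .layers import (
    Conv2d,
    Dropout,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    global_average_pool,
)

TINY_BACKBONES = ("tiny_cnn", "tiny_vit")
PAPER_BACKBONES = ("resnet50", "efficientnet_b3", "vit_base")


@dataclass
class EncoderConfig:
    modality: str  # 'E', 'C' or 'H'
    backbone: str = "tiny_cnn"
    d_latent: int = 32
    pooling: str = "none"  # none | global_average | attention
    width: int = 8  # base channel width of the tiny CNN
    patch_size: int = 8  # token size for the tiny transformer

    def __post_init__(self):
        if self.modality not in ("E", "C", "H"):
            raise ValueError(f"modality must be one of E/C/H, got {self.modality!r}")
        if self.d_latent <= 0:
            raise ValueError("d_latent must be positive")
        if self.backbone not in TINY_BACKBONES + PAPER_BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.pooling == "attention" and self.modality != "H":
            raise ValueError("attention pooling is reserved for the histology modality")
        if self.pooling == "global_average" and self.modality != "C":
            raise ValueError("global-average slice pooling is reserved for the CT modality")


class TinyCNN(Module):
    """Three conv blocks (stride 2) + global average pool + linear projection."""

    def __init__(self, c_in: int, d_latent: int, rng: np.random.Generator, width: int = 8):
        super().__init__()
        self.conv1 = Conv2d(c_in, width, 3, rng, stride=2, pad=1)
        self.conv2 = Conv2d(width, 2 * width, 3, rng, stride=2, pad=1)
        self.conv3 = Conv2d(2 * width, 2 * width, 3, rng, stride=2, pad=1)
        self.proj = Linear(2 * width, d_latent, rng)
        # saliency target layers, retained per forward pass
        self.feature_maps: dict[str, Tensor] = {}

    @property
    def last_feature_map(self) -> Tensor | None:
        return self.feature_maps.get("conv3")

    def __call__(self, x: Tensor) -> Tensor:
        h1 = self.conv1(x).relu()
        h2 = self.conv2(h1).relu()
        h3 = self.conv3(h2).relu()
        self.feature_maps = {"conv1": h1, "conv2": h2, "conv3": h3}
        return self.proj(global_average_pool(h3))


class _TransformerBlock(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, 2 * dim, rng)
        self.fc2 = Linear(2 * dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).relu())


class TinyViT(Module):
    """Two-layer patch transformer: linear patch embedding over a square
    token grid, transformer blocks, mean token pooling, linear projection."""

    def __init__(
        self,
        c_in: int,
        d_latent: int,
        rng: np.random.Generator,
        image_size: int = 64,
        patch_size: int = 8,
        dim: int = 32,
        n_heads: int = 4,
    ):
        super().__init__()
        if image_size % patch_size:
            raise ValueError("patch size must divide image size")
        self.patch_size = patch_size
        self.grid = image_size // patch_size
        self.embed = Linear(c_in * patch_size * patch_size, dim, rng)
        self.pos = Parameter(0.02 * rng.standard_normal((1, self.grid ** 2, dim)))
        self.block1 = _TransformerBlock(dim, n_heads, rng)
        self.block2 = _TransformerBlock(dim, n_heads, rng)
        self.proj = Linear(dim, d_latent, rng)
        self.last_token_grid: Tensor | None = None

    def __call__(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        p, g = self.patch_size, self.grid
        tokens = (
            x.reshape(N, C, g, p, g, p)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(N, g * g, C * p * p)
        )
        h = self.embed(tokens) + self.pos
        h = self.block2(self.block1(h))
        # token grid reshaped to (N, D, g, g): saliency target for transformers
        self.last_token_grid = h.transpose(0, 2, 1).reshape(N, h.shape[-1], g, g)
        return self.proj(h.mean(axis=1))


def build_backbone(config: EncoderConfig, c_in: int, rng: np.random.Generator, image_size: int):
    if config.backbone == "tiny_cnn":
        return TinyCNN(c_in, config.d_latent, rng, width=config.width)
    if config.backbone == "tiny_vit":
        return TinyViT(
            c_in, config.d_latent, rng, image_size=image_size, patch_size=config.patch_size
        )
    raise NotImplementedError(
        f"backbone {config.backbone!r} requires externally supplied pretrained weights; "
        "load them through a checkpoint or use a tiny backbone"
    )


class AttentionPool(Module):
    """Learned softmax pooling over a bag of embeddings (N, p, D) -> (N, D)."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.score = Linear(dim, 1, rng)
        self.last_weights: np.ndarray | None = None

    def __call__(self, bag: Tensor) -> Tensor:
        if bag.ndim != 3 or bag.shape[1] == 0:
            raise ValueError("attention pooling needs a non-empty (N, p, D) bag")
        scores = self.score(bag).reshape(bag.shape[0], bag.shape[1])  # (N, p)
        w = scores.softmax(axis=-1)
        self.last_weights = w.data.copy()
        return (w.reshape(w.shape[0], w.shape[1], 1) * bag).sum(axis=1)


def attention_pool(patch_embeddings: np.ndarray, score_vector: np.ndarray, bias: float = 0.0):
    """Functional attention pooling on a single bag (p, D) with a given
    scoring vector; returns (pooled vector, softmax weights)."""
    bag = np.asarray(patch_embeddings, dtype=float)
    if bag.ndim != 2 or bag.shape[0] == 0:
        raise ValueError("patch_embeddings must be a non-empty (p, D) array")
    scores = bag @ np.asarray(score_vector, dtype=float) + bias
    scores = scores - scores.max()
    w = np.exp(scores)
    w /= w.sum()
    return w @ bag, w


class EndoscopyEncoder(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator, image_size: int):
        super().__init__()
        self.config = config
        self.backbone = build_backbone(config, 3, rng, image_size)

    def __call__(self, images: Tensor) -> Tensor:
        if images.ndim != 4 or images.shape[1] != 3:
            raise ValueError(f"endoscopy input must be (N, 3, H, W), got {images.shape}")
        return self.backbone(images)


class CTEncoder(Module):
    """Per-slice backbone; global average pooling over the slice axis."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator, image_size: int):
        super().__init__()
        self.config = config
        self.backbone = build_backbone(config, 1, rng, image_size)

    def __call__(self, slices: Tensor) -> Tensor:
        if slices.ndim != 4:
            raise ValueError(f"CT input must be (N, k, H, W) slice stacks, got {slices.shape}")
        N, k, H, W = slices.shape
        if k == 0:
            raise ValueError("CT slice stack is empty")
        flat = slices.reshape(N * k, 1, H, W)
        emb = self.backbone(flat)  # (N*k, d)
        return emb.reshape(N, k, emb.shape[-1]).mean(axis=1)


class HistologyEncoder(Module):
    """Per-patch backbone; attention pooling over the patch axis."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator, image_size: int):
        super().__init__()
        self.config = config
        self.backbone = build_backbone(config, 3, rng, image_size)
        self.pool = AttentionPool(config.d_latent, rng)

    def __call__(self, patches: Tensor) -> Tensor:
        if patches.ndim != 5 or patches.shape[2] != 3:
            raise ValueError(
                f"histology input must be (N, p, 3, H, W) patch stacks, got {patches.shape}"
            )
        N, p, C, H, W = patches.shape
        if p == 0:
            raise ValueError("histology patch stack is empty")
        flat = patches.reshape(N * p, C, H, W)
        emb = self.backbone(flat)
        return self.pool(emb.reshape(N, p, emb.shape[-1]))
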