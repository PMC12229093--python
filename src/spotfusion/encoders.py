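"""Image and gene-expression encoders producing shared 512-d embeddings.

The image side is a vision transformer over non-overlapping pixel patches
(ViT-B/32-shaped by default, fully configurable down to a tiny CPU size).
The gene side tokenizes each panel gene as a learned identity embedding plus
a binned-value embedding, runs a transformer backbone over the gene tokens,
then a 2-D convolution over the token × embedding map, global average
pooling over the token axis, and a three-layer fully connected head with
ReLU and dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Conv2d,
    Dropout,
    LayerNorm,
    Linear,
    Module,
    ModuleList,
    Tensor,
    TransformerBlock,
)

__all__ = [
    "ImageEncoderConfig",
    "GeneEncoderConfig",
    "ViTImageEncoder",
    "GeneEncoder",
    "EmbeddingBatch",
    "encode_image",
    "encode_expression",
    "l2_normalize",
]


@dataclass
class ImageEncoderConfig:
    input_resolution: int = 224
    vit_patch_size: int = 32
    depth: int = 12
    heads: int = 12
    width: int = 768
    embed_dim: int = 512
    dtype: object = np.float32

    def __post_init__(self):
        if self.input_resolution % self.vit_patch_size:
            raise ValueError(
                f"input_resolution {self.input_resolution} not divisible by "
                f"vit_patch_size {self.vit_patch_size}"
            )
        if self.embed_dim <= 0:
            raise ValueError("embed_dim must be positive")

    @classmethod
    def tiny(cls, **overrides) -> "ImageEncoderConfig":
        """Small CPU configuration used by tests and the desk-scale pipeline."""
        base = dict(input_resolution=32, vit_patch_size=16, depth=2, heads=4, width=64)
        base.update(overrides)
        return cls(**base)


@dataclass
class GeneEncoderConfig:
    n_genes: int = 2000
    backbone_layers: int = 12
    backbone_heads: int = 8
    backbone_width: int = 200
    conv_kernel: tuple = (7, 5)
    conv_padding: tuple = (0, 2)
    conv_channels: int = 1
    n_bins: int = 16
    max_value: float = 14.0   # bin range upper bound; ~ln(1 + 1e6)
    fc_layers: int = 3
    dropout: float = 0.5
    embed_dim: int = 512
    dtype: object = np.float32

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.conv_kernel[0] <= 0 or self.conv_kernel[1] <= 0:
            raise ValueError(f"conv kernel must be positive, got {self.conv_kernel}")
        if self.n_genes < self.conv_kernel[0]:
            raise ValueError("n_genes must be at least the token-axis kernel size")

    @classmethod
    def tiny(cls, n_genes: int = 128, **overrides) -> "GeneEncoderConfig":
        base = dict(n_genes=n_genes, backbone_layers=2, backbone_heads=4,
                    backbone_width=64, dropout=0.1)
        base.update(overrides)
        return cls(**base)


@dataclass
class EmbeddingBatch:
    """Matched image/gene embeddings for a batch of spots (and momentum copies)."""

    V: np.ndarray
    E: np.ndarray
    V_m: np.ndarray | None = None
    E_m: np.ndarray | None = None


def l2_normalize(x, axis: int = -1, eps: float = 1e-12):
    if isinstance(x, Tensor):
        norm = (x * x).sum(axis=axis, keepdims=True).sqrt() + eps
        return x / norm
    x = np.asarray(x, dtype=float)
    return x / (np.linalg.norm(x, axis=axis, keepdims=True) + eps)


class ViTImageEncoder(Module):
    """Patch-token vision transformer with a class token and linear head."""

    def __init__(self, config: ImageEncoderConfig, rng=None):
        from .nn.layers import get_rng

        rng = rng or get_rng()
        c = self.config = config
        n_patches = (c.input_resolution // c.vit_patch_size) ** 2
        patch_dim = 3 * c.vit_patch_size ** 2
        self.patch_embed = Linear(patch_dim, c.width, rng, dtype=c.dtype)
        self.cls_token = Tensor(
            (rng.standard_normal((1, 1, c.width)) * 0.02).astype(c.dtype), requires_grad=True
        )
        self.pos_embed = Tensor(
            (rng.standard_normal((1, n_patches + 1, c.width)) * 0.02).astype(c.dtype),
            requires_grad=True,
        )
        self.blocks = ModuleList(
            TransformerBlock(c.width, c.heads, rng=rng, dtype=c.dtype) for _ in range(c.depth)
        )
        self.norm = LayerNorm(c.width, dtype=c.dtype)
        self.head = Linear(c.width, c.embed_dim, rng, dtype=c.dtype)

    def _patchify(self, patches: np.ndarray) -> np.ndarray:
        c = self.config
        B, H, W, _ = patches.shape
        P = c.vit_patch_size
        x = patches.reshape(B, H // P, P, W // P, P, 3)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(B, (H // P) * (W // P), P * P * 3)
        return x

    def __call__(self, patches: np.ndarray, return_tokens: bool = False):
        c = self.config
        patches = np.asarray(patches)
        if patches.ndim != 4 or patches.shape[1] != c.input_resolution or patches.shape[2] != c.input_resolution:
            raise ValueError(
                f"expected (batch, {c.input_resolution}, {c.input_resolution}, 3) patches, "
                f"got {patches.shape}"
            )
        x = patches.astype(c.dtype) / 255.0 - 0.5
        tokens = self.patch_embed(Tensor(self._patchify(x)))
        B = patches.shape[0]
        cls_rep = Tensor(np.ones((B, 1, 1), dtype=c.dtype)) * self.cls_token
        from .nn import concatenate

        seq = concatenate([cls_rep, tokens], axis=1) + self.pos_embed
        for block in self.blocks:
            seq = block(seq)
        seq = self.norm(seq)
        emb = self.head(seq[:, 0, :])
        if return_tokens:
            return emb, seq[:, 1:, :]
        return emb


class GeneEncoder(Module):
    """scBERT-style gene-token transformer + convolution + GAP + FC head."""

    def __init__(self, config: GeneEncoderConfig, rng=None):
        from .nn.layers import get_rng

        rng = rng or get_rng()
        c = self.config = config
        self.gene_embed = Tensor(
            (rng.standard_normal((c.n_genes, c.backbone_width)) * 0.02).astype(c.dtype),
            requires_grad=True,
        )
        self.value_embed = Tensor(
            (rng.standard_normal((c.n_bins, c.backbone_width)) * 0.02).astype(c.dtype),
            requires_grad=True,
        )
        self.blocks = ModuleList(
            TransformerBlock(c.backbone_width, c.backbone_heads, rng=rng, dtype=c.dtype)
            for _ in range(c.backbone_layers)
        )
        self.conv = Conv2d(1, c.conv_channels, c.conv_kernel, c.conv_padding, rng, dtype=c.dtype)
        width_out = c.backbone_width + 2 * c.conv_padding[1] - c.conv_kernel[1] + 1
        fc_in = c.conv_channels * width_out
        dims = [fc_in] + [c.embed_dim] * c.fc_layers
        self.fc = ModuleList(
            Linear(dims[i], dims[i + 1], rng, dtype=c.dtype) for i in range(c.fc_layers)
        )
        self.drop = Dropout(c.dropout)

    def _bin(self, x: np.ndarray) -> np.ndarray:
        c = self.config
        idx = np.floor(np.asarray(x, dtype=float) / c.max_value * c.n_bins).astype(int)
        return np.clip(idx, 0, c.n_bins - 1)

    def __call__(self, x: np.ndarray, return_tokens: bool = False):
        c = self.config
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != c.n_genes:
            raise ValueError(f"expected (batch, {c.n_genes}) expression, got {x.shape}")
        bins = self._bin(x)
        tokens = self.value_embed[bins] + self.gene_embed
        for block in self.blocks:
            tokens = block(tokens)
        # token x embedding map as a 1-channel image
        B, T, D = tokens.shape
        fmap = self.conv(tokens.reshape(B, 1, T, D))           # (B, C, L, D')
        pooled = fmap.mean(axis=2)                             # GAP over the token axis
        h = pooled.reshape(B, -1)
        for i, fc in enumerate(self.fc):
            h = fc(h)
            if i < len(self.fc) - 1:
                h = h.relu()
        e = self.drop(h.relu())
        if return_tokens:
            return e, tokens
        return e


def encode_image(patches, encoder: ViTImageEncoder, mode: str = "eval") -> np.ndarray:
    """Run the image encoder; returns a (batch, embed_dim) array."""
    from .nn.tensor import no_grad

    encoder.train(mode == "train")
    if mode == "train":
        out = encoder(patches)
    else:
        with no_grad():
            out = encoder(patches)
    encoder.eval()
    return out.data


def encode_expression(x, encoder: GeneEncoder, mode: str = "eval") -> np.ndarray:
    """Run the gene encoder; returns a (batch, embed_dim) array."""
    from .nn.tensor import no_grad

    encoder.train(mode == "train")
    if mode == "train":
        out = encoder(x)
    else:
        with no_grad():
            out = encoder(x)
    encoder.eval()
    return out.data
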