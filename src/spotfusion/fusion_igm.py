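"""Cross-modal fusion and the binary image–gene matching (IGM) head.

Gene token features are refined by self-attention, fused with image patch
features by cross-attention (gene side as query, image side as key/value),
and passed through a residual feed-forward block; a small MLP on the pooled
fused representation scores whether an image and an expression profile
belong to the same spot.  Negatives are mined as the hardest (most similar)
non-matching partner under the momentum embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    FeedForward,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    Tensor,
    concatenate,
)

__all__ = [
    "FusionConfig",
    "MatchBatch",
    "FusionIGM",
    "mine_hard_negatives",
    "igm_loss",
    "igm_loss_tensor",
]


@dataclass
class FusionConfig:
    dim: int = 64
    heads: int = 4
    ffn_hidden: int = 256
    n_blocks: int = 1
    symmetric_negatives: bool = True
    dtype: object = np.float32

    def __post_init__(self):
        if self.dim % self.heads:
            raise ValueError(f"dim {self.dim} not divisible by heads {self.heads}")


@dataclass
class MatchBatch:
    pair_features: np.ndarray  # (n_pairs, dim) pooled fused representations
    labels: np.ndarray         # (n_pairs,) binary
    logits: np.ndarray         # (n_pairs,)


class _FusionBlock(Module):
    """Post-norm block: self-attention, cross-attention, residual FFN."""

    def __init__(self, c: FusionConfig, rng=None):
        self.self_attn = MultiHeadAttention(c.dim, c.heads, rng, dtype=c.dtype)
        self.norm_self = LayerNorm(c.dim, dtype=c.dtype)
        self.cross_attn = MultiHeadAttention(c.dim, c.heads, rng, dtype=c.dtype)
        self.norm_cross = LayerNorm(c.dim, dtype=c.dtype)
        self.ffn = FeedForward(c.dim, c.ffn_hidden, rng, dtype=c.dtype)
        self.norm_out = LayerNorm(c.dim, dtype=c.dtype)

    def self_attend(self, gene_tokens: Tensor) -> Tensor:
        return self.norm_self(gene_tokens + self.self_attn(gene_tokens))

    def cross_fuse(self, z_self: Tensor, image_tokens: Tensor) -> Tensor:
        z_cross = self.norm_cross(z_self + self.cross_attn(z_self, image_tokens))
        return self.norm_out(z_cross + self.ffn(z_cross))

    def __call__(self, gene_tokens: Tensor, image_tokens: Tensor) -> Tensor:
        return self.cross_fuse(self.self_attend(gene_tokens), image_tokens)


class FusionIGM(Module):
    def __init__(self, config: FusionConfig, rng=None):
        from .nn.layers import get_rng

        rng = rng or get_rng()
        c = self.config = config
        from .nn import ModuleList

        self.blocks = ModuleList(_FusionBlock(c, rng) for _ in range(c.n_blocks))
        self.head1 = Linear(c.dim, c.dim, rng, dtype=c.dtype)
        self.head2 = Linear(c.dim, 1, rng, dtype=c.dtype)

    def self_attend(self, gene_tokens) -> Tensor:
        """Residual + layer-normalized self-attention over gene tokens."""
        return self.blocks[0].self_attend(Tensor._wrap(gene_tokens))

    def cross_fuse(self, z_self, image_tokens) -> Tensor:
        """Cross-attention fusion (gene query, image key/value) + residual FFN."""
        z_self = Tensor._wrap(z_self)
        image_tokens = Tensor._wrap(image_tokens)
        if z_self.shape[-1] != image_tokens.shape[-1]:
            raise ValueError(
                f"feature dim mismatch: gene {z_self.shape[-1]} vs image {image_tokens.shape[-1]}"
            )
        return self.blocks[0].cross_fuse(z_self, image_tokens)

    def fuse(self, gene_tokens, image_tokens) -> Tensor:
        z = Tensor._wrap(gene_tokens)
        image_tokens = Tensor._wrap(image_tokens)
        if z.shape[-1] != image_tokens.shape[-1]:
            raise ValueError(
                f"feature dim mismatch: gene {z.shape[-1]} vs image {image_tokens.shape[-1]}"
            )
        for block in self.blocks:
            z = block(z, image_tokens)
        return z

    def match_logits(self, gene_tokens, image_tokens) -> Tensor:
        """Fuse and score; pooled (first-token) representation -> 1 logit."""
        z = self.fuse(gene_tokens, image_tokens)
        pooled = z[:, 0, :]
        return self.head2(self.head1(pooled).relu()).reshape(-1)


def mine_hard_negatives(sim: np.ndarray, rng_seed: int | None = None) -> np.ndarray:
    """Per row i, index of the most similar non-matching column (argmax over
    j != i); ties broken by smallest index.  Deterministic; ``rng_seed`` is
    accepted for interface symmetry with stochastic miners."""
    sim = np.asarray(sim, dtype=float)
    S = sim.shape[0]
    if S < 2:
        raise ValueError("need at least 2 items to mine negatives")
    masked = sim.copy()
    np.fill_diagonal(masked, -np.inf)
    return masked.argmax(axis=1)


def igm_loss(logits: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy of sigmoid(logits) against 0/1 labels."""
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if logits.shape != labels.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs labels {labels.shape}")
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise ValueError("labels must be binary (0/1)")
    p = np.clip(1.0 / (1.0 + np.exp(-logits)), eps, 1.0 - eps)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def igm_loss_tensor(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable, numerically stable BCE-with-logits (mean reduction)."""
    labels = np.asarray(labels, dtype=logits.data.dtype)
    if logits.shape != labels.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs labels {labels.shape}")
    # max(l, 0) - l*y + log(1 + exp(-|l|))
    abs_l = logits.relu() + (-logits).relu()
    loss = logits.relu() - logits * Tensor(labels) + (1.0 + (-abs_l).exp()).log()
    return loss.mean()
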