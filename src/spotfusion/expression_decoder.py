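"""Stage 2: frozen image encoder -> projection -> transformer decoder ->
multi-gene expression prediction trained with mean squared error.

The frozen stage-1 image embedding is mapped by two linear layers to a
high-dimensional feature, reshaped into a short token sequence so
self-attention is non-degenerate, refined by post-norm transformer blocks
(multi-head attention, add & norm, feed-forward, add & norm), pooled, and
linearly mapped to the target gene panel (300 genes by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import (
    AdamW,
    FeedForward,
    LayerNorm,
    Linear,
    Module,
    ModuleList,
    MultiHeadAttention,
    Tensor,
    set_rng,
)
from .spatial_dataset import GenePanel

__all__ = [
    "DecoderConfig",
    "PredictionBatch",
    "ExpressionDecoder",
    "mse_loss",
    "decoder_training_step",
    "train_decoder",
]


@dataclass
class DecoderConfig:
    in_dim: int = 512
    hidden_dim: int = 512
    n_layers: int = 4
    heads: int = 8
    tokens: int = 8
    n_genes_out: int = 300
    dtype: object = np.float32

    def __post_init__(self):
        if self.hidden_dim % self.heads:
            raise ValueError(f"hidden_dim {self.hidden_dim} not divisible by heads {self.heads}")

    @classmethod
    def tiny(cls, n_genes_out: int = 50, **overrides) -> "DecoderConfig":
        base = dict(hidden_dim=64, n_layers=2, heads=2, tokens=4, n_genes_out=n_genes_out)
        base.update(overrides)
        return cls(**base)


@dataclass
class PredictionBatch:
    X_p: np.ndarray                 # (spots, n_genes_out) predicted log expression
    X: np.ndarray | None = None     # matching ground truth, if available
    panel: GenePanel | None = None


class _DecoderBlock(Module):
    """Post-norm: attention -> add & norm -> FFN -> add & norm."""

    def __init__(self, dim: int, heads: int, rng=None, dtype=np.float32):
        self.attn = MultiHeadAttention(dim, heads, rng, dtype=dtype)
        self.norm1 = LayerNorm(dim, dtype=dtype)
        self.ffn = FeedForward(dim, 4 * dim, rng, dtype=dtype)
        self.norm2 = LayerNorm(dim, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        return self.norm2(x + self.ffn(x))


class ExpressionDecoder(Module):
    def __init__(self, config: DecoderConfig, rng=None):
        from .nn.layers import get_rng

        rng = rng or get_rng()
        c = self.config = config
        self.proj1 = Linear(c.in_dim, c.hidden_dim // 2, rng, dtype=c.dtype)
        self.proj2 = Linear(c.hidden_dim // 2, c.hidden_dim, rng, dtype=c.dtype)
        self.tokenize = Linear(c.hidden_dim, c.tokens * c.hidden_dim, rng, dtype=c.dtype)
        self.pos_embed = Tensor(
            (rng.standard_normal((1, c.tokens, c.hidden_dim)) * 0.02).astype(c.dtype),
            requires_grad=True,
        )
        self.blocks = ModuleList(
            _DecoderBlock(c.hidden_dim, c.heads, rng, c.dtype) for _ in range(c.n_layers)
        )
        self.out_head = Linear(c.hidden_dim, c.n_genes_out, rng, dtype=c.dtype)

    def project_features(self, V, nonlinear: bool = True) -> Tensor:
        """Two linear layers (ReLU between) lifting 512-d embeddings to
        hidden_dim."""
        V = Tensor._wrap(V)
        h = self.proj1(V)
        if nonlinear:
            h = h.relu()
        return self.proj2(h)

    def decode_expression(self, E_prime) -> Tensor:
        """Transformer blocks over the tokenized projection; mean-pooled
        output mapped linearly to the target panel."""
        E_prime = Tensor._wrap(E_prime)
        B = E_prime.shape[0]
        c = self.config
        seq = self.tokenize(E_prime).reshape(B, c.tokens, c.hidden_dim) + self.pos_embed
        for block in self.blocks:
            seq = block(seq)
        return self.out_head(seq.mean(axis=1))

    def __call__(self, V) -> Tensor:
        return self.decode_expression(self.project_features(V))

    def predict(self, V: np.ndarray) -> np.ndarray:
        from .nn.tensor import no_grad

        self.eval()
        with no_grad():
            return self(np.asarray(V)).data

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cfg = {k: v for k, v in vars(self.config).items() if k != "dtype"}
        np.savez_compressed(
            path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            **self.state_dict())

    @classmethod
    def load(cls, path) -> "ExpressionDecoder":
        with np.load(path) as archive:
            cfg = json.loads(bytes(archive["__config__"].tobytes()).decode())
            state = {k: archive[k] for k in archive.files if k != "__config__"}
        model = cls(DecoderConfig(**cfg))
        model.load_state_dict(state)
        return model


def mse_loss(X, X_p, variant: str = "mean"):
    """Mean squared error between truth and prediction.

    ``variant="mean"`` is the mean over all entries of the squared
    difference; ``variant="l2"`` returns the raw Frobenius norm instead.
    """
    X = X.data if isinstance(X, Tensor) else np.asarray(X, dtype=float)
    Xp_is_tensor = isinstance(X_p, Tensor)
    Xp = X_p.data if Xp_is_tensor else np.asarray(X_p, dtype=float)
    if X.shape != Xp.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xp.shape}")
    if Xp_is_tensor:
        diff = X_p - Tensor(X.astype(X_p.data.dtype))
        if variant == "l2":
            return (diff * diff).sum().sqrt()
        return (diff * diff).mean()
    if variant == "l2":
        return float(np.linalg.norm(X - Xp))
    return float(np.mean((X - Xp) ** 2))


@dataclass
class DecodeTrainConfig:
    lr: float = 1e-4
    weight_decay: float = 0.02
    batch_size: int = 32
    steps: int = 200
    seed: int = 0


def _encoder_fingerprint(encoder) -> bytes:
    import hashlib

    h = hashlib.sha256()
    for name, p in sorted(encoder.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.digest()


def decoder_training_step(images: np.ndarray, targets: np.ndarray,
                          decoder: ExpressionDecoder, frozen_encoder,
                          optimizer: AdamW) -> dict:
    """One MSE step on the decoder; the image encoder stays frozen."""
    if getattr(frozen_encoder, "_frozen", False) is not True:
        raise ValueError("image encoder must be frozen (call freeze_encoder) before decoder training")
    frozen_encoder.eval()
    from .nn.tensor import no_grad

    with no_grad():
        V = frozen_encoder(images).data  # numpy: no gradient reaches the encoder
    decoder.train(True)
    pred = decoder(V)
    loss = mse_loss(targets, pred)
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    decoder.eval()
    return {"loss": float(loss.data)}


def freeze_encoder(encoder):
    encoder._frozen = True
    return encoder


def train_decoder(images: np.ndarray, targets: np.ndarray,
                  decoder: ExpressionDecoder, frozen_encoder,
                  config: DecodeTrainConfig, log_path=None) -> list:
    """Stage-2 loop; verifies after the fact that the encoder is bitwise
    untouched."""
    before = _encoder_fingerprint(frozen_encoder)
    n = images.shape[0]
    rng = np.random.default_rng(config.seed)
    set_rng(np.random.default_rng(config.seed + 1))
    optimizer = AdamW(decoder.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    history = []
    log_file = open(log_path, "w") if log_path else None
    try:
        for step in range(config.steps):
            idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
            record = decoder_training_step(images[idx], targets[idx], decoder,
                                           frozen_encoder, optimizer)
            record["step"] = step
            history.append(record)
            if log_file:
                log_file.write(json.dumps(record) + "\n")
    finally:
        if log_file:
            log_file.close()
    if _encoder_fingerprint(frozen_encoder) != before:
        raise RuntimeError("frozen encoder parameters changed during decoder training")
    return history
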