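"""Stage 1: momentum-distilled contrastive alignment of image and gene
embeddings, with the image–gene matching (IGM) auxiliary objective.

A momentum copy of both encoders is maintained by an exponential moving
average of the primary parameters (coefficient beta).  Its softmax
similarity distributions are mixed with the one-hot pairing matrix
(weight alpha) to form the pseudo-targets of a bidirectional
cross-entropy contrastive loss at temperature tau; a binary classifier on
fused representations separates true pairs from mined hardest negatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoders import (
    GeneEncoder,
    GeneEncoderConfig,
    ImageEncoderConfig,
    ViTImageEncoder,
    l2_normalize,
)
from .fusion_igm import FusionConfig, FusionIGM, igm_loss_tensor, mine_hard_negatives
from .nn import AdamW, Tensor, concatenate, log_softmax, set_rng
from .nn.tensor import no_grad

__all__ = [
    "MomentumState",
    "AlignConfig",
    "AlignmentModel",
    "ema_update",
    "similarity_softmax",
    "build_pseudo_targets",
    "contrastive_loss",
    "alignment_training_step",
    "train_alignment",
]


# ---------------------------------------------------------------------------
# the contrastive/momentum primitives
# ---------------------------------------------------------------------------

def ema_update(state: "MomentumState") -> "MomentumState":
    """theta_m <- beta * theta_m + (1 - beta) * theta, parameter by parameter."""
    theta, theta_m = state.theta, state.theta_m
    if set(theta) != set(theta_m):
        offending = sorted(set(theta) ^ set(theta_m))
        raise ValueError(f"momentum state structural mismatch at: {offending[:5]}")
    b = state.beta
    for name, p in theta.items():
        m = theta_m[name]
        if m.data.shape != p.data.shape:
            raise ValueError(f"momentum shape mismatch at {name}: {m.data.shape} vs {p.data.shape}")
        m.data = (b * m.data + (1.0 - b) * p.data).astype(m.data.dtype)
    return state


def similarity_softmax(Q: np.ndarray, K: np.ndarray, tau: float) -> np.ndarray:
    """Row-stochastic softmax over cosine similarities at temperature tau."""
    if tau <= 0:
        raise ValueError(f"temperature must be positive, got {tau}")
    sims = l2_normalize(np.asarray(Q, dtype=float)) @ l2_normalize(np.asarray(K, dtype=float)).T
    z = sims / tau
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_pseudo_targets(p_m: np.ndarray, alpha: float) -> np.ndarray:
    """alpha * p_m + (1 - alpha) * I — momentum distribution mixed with the
    one-hot pairing matrix."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    p_m = np.asarray(p_m, dtype=float)
    return alpha * p_m + (1.0 - alpha) * np.eye(p_m.shape[0])


def contrastive_loss(p_h2g, p_g2h, y_h2g, y_g2h, eps: float = 1e-12) -> float:
    """Half the mean of both directions' cross-entropies CE(y, p)."""
    losses = []
    for p, y in ((p_h2g, y_h2g), (p_g2h, y_g2h)):
        p = np.asarray(p, dtype=float)
        y = np.asarray(y, dtype=float)
        ce = -(y * np.log(np.maximum(p, eps))).sum(axis=1)
        losses.append(ce.mean())
    return float(0.5 * (losses[0] + losses[1]))


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class MomentumState:
    theta: dict      # name -> Tensor (primary parameters)
    theta_m: dict    # name -> Tensor (momentum copy)
    beta: float = 0.995


@dataclass
class AlignConfig:
    beta: float = 0.995
    alpha: float = 0.4
    tau: float = 0.07
    batch_size: int = 32
    lr: float = 1e-4
    weight_decay: float = 0.02
    steps: int = 300
    lambda_igm: float = 1.0
    seed: int = 0
    symmetric_negatives: bool = True
    igm_into_encoders: bool = True


class AlignmentModel:
    """Primary encoders + fusion/IGM head + momentum encoder copies."""

    def __init__(self, image_config: ImageEncoderConfig, gene_config: GeneEncoderConfig,
                 fusion_config: FusionConfig | None = None, beta: float = 0.995, seed: int = 0):
        if fusion_config is None:
            if image_config.width != gene_config.backbone_width:
                raise ValueError("encoder widths must match for fusion")
            fusion_config = FusionConfig(dim=image_config.width)
        rng = np.random.default_rng(seed)
        set_rng(rng)
        self.image_config, self.gene_config, self.fusion_config = (
            image_config, gene_config, fusion_config)
        self.image_encoder = ViTImageEncoder(image_config, rng)
        self.gene_encoder = GeneEncoder(gene_config, rng)
        self.fusion = FusionIGM(fusion_config, rng)
        self.image_encoder_m = ViTImageEncoder(image_config, rng)
        self.gene_encoder_m = GeneEncoder(gene_config, rng)
        self.image_encoder_m.load_state_dict(self.image_encoder.state_dict())
        self.gene_encoder_m.load_state_dict(self.gene_encoder.state_dict())
        self.beta = beta

    # ----- momentum plumbing ---------------------------------------------
    def momentum_state(self) -> MomentumState:
        theta = {f"img.{k}": v for k, v in self.image_encoder.named_parameters()}
        theta.update({f"gene.{k}": v for k, v in self.gene_encoder.named_parameters()})
        theta_m = {f"img.{k}": v for k, v in self.image_encoder_m.named_parameters()}
        theta_m.update({f"gene.{k}": v for k, v in self.gene_encoder_m.named_parameters()})
        return MomentumState(theta, theta_m, self.beta)

    def parameters(self):
        return (self.image_encoder.parameters() + self.gene_encoder.parameters()
                + self.fusion.parameters())

    def train(self, mode: bool = True):
        self.image_encoder.train(mode)
        self.gene_encoder.train(mode)
        self.fusion.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # ----- inference ------------------------------------------------------
    def embed(self, patches: np.ndarray, expression: np.ndarray):
        """Eval-mode embeddings for matched patches/expression (numpy)."""
        self.eval()
        with no_grad():
            V = self.image_encoder(patches).data
            E = self.gene_encoder(expression).data
        return V, E

    # ----- checkpointing --------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        state = {}
        for prefix, mod in (("img", self.image_encoder), ("gene", self.gene_encoder),
                            ("fusion", self.fusion), ("img_m", self.image_encoder_m),
                            ("gene_m", self.gene_encoder_m)):
            for k, v in mod.state_dict().items():
                state[f"{prefix}.{k}"] = v
        config = {
            "image": _config_dict(self.image_config),
            "gene": _config_dict(self.gene_config),
            "fusion": _config_dict(self.fusion_config),
            "beta": self.beta,
        }
        np.savez_compressed(path, __config__=np.frombuffer(
            json.dumps(config).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "AlignmentModel":
        with np.load(path) as archive:
            config = json.loads(bytes(archive["__config__"].tobytes()).decode())
            state = {k: archive[k] for k in archive.files if k != "__config__"}
        model = cls(
            ImageEncoderConfig(**config["image"]),
            GeneEncoderConfig(**config["gene"]),
            FusionConfig(**config["fusion"]),
            beta=config["beta"],
        )
        for prefix, mod in (("img", model.image_encoder), ("gene", model.gene_encoder),
                            ("fusion", model.fusion), ("img_m", model.image_encoder_m),
                            ("gene_m", model.gene_encoder_m)):
            mod.load_state_dict({k[len(prefix) + 1:]: v for k, v in state.items()
                                 if k.startswith(prefix + ".")})
        return model


def _config_dict(cfg) -> dict:
    out = {}
    for k, v in vars(cfg).items():
        if k == "dtype":
            continue
        out[k] = list(v) if isinstance(v, tuple) else v
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _contrastive_term(v: Tensor, e: Tensor, vm: np.ndarray, em: np.ndarray,
                      alpha: float, tau: float) -> Tensor:
    S = v.shape[0]
    v_n, e_n = l2_normalize(v), l2_normalize(e)
    logits_h2g = (v_n @ e_n.transpose(1, 0)) / tau
    logits_g2h = (e_n @ v_n.transpose(1, 0)) / tau
    y_h2g = build_pseudo_targets(similarity_softmax(vm, em, tau), alpha)
    y_g2h = build_pseudo_targets(similarity_softmax(em, vm, tau), alpha)
    ce_h2g = -(Tensor(y_h2g.astype(v.data.dtype)) * log_softmax(logits_h2g)).sum(axis=1)
    ce_g2h = -(Tensor(y_g2h.astype(v.data.dtype)) * log_softmax(logits_g2h)).sum(axis=1)
    return 0.5 * (ce_h2g.mean() + ce_g2h.mean())


def _igm_term(model: AlignmentModel, v_tok: Tensor, e_tok: Tensor,
              vm: np.ndarray, em: np.ndarray, config: AlignConfig) -> Tensor:
    S = v_tok.shape[0]
    if not config.igm_into_encoders:
        v_tok, e_tok = v_tok.detach(), e_tok.detach()
    vm_n, em_n = l2_normalize(vm), l2_normalize(em)
    neg_img = mine_hard_negatives(em_n @ vm_n.T)   # hardest image per gene profile
    gene_in = [e_tok, e_tok]
    img_in = [v_tok, v_tok[neg_img]]
    labels = [np.ones(S), np.zeros(S)]
    if config.symmetric_negatives:
        neg_gene = mine_hard_negatives(vm_n @ em_n.T)  # hardest gene profile per image
        gene_in.append(e_tok[neg_gene])
        img_in.append(v_tok)
        labels.append(np.zeros(S))
    genes = concatenate(gene_in, axis=0)
    imgs = concatenate(img_in, axis=0)
    logits = model.fusion.match_logits(genes, imgs)
    return igm_loss_tensor(logits, np.concatenate(labels))


def alignment_training_step(images: np.ndarray, expression: np.ndarray,
                            model: AlignmentModel, optimizer: AdamW,
                            config: AlignConfig) -> dict:
    """One optimizer step on L_con + lambda * L_IGM, then the EMA update."""
    S = images.shape[0]
    if S < 2:
        raise ValueError("alignment needs a batch of at least 2 spots (no negatives otherwise)")
    model.train(True)
    v, v_tok = model.image_encoder(images, return_tokens=True)
    e, e_tok = model.gene_encoder(expression, return_tokens=True)
    model.image_encoder_m.eval()
    model.gene_encoder_m.eval()
    with no_grad():
        vm = model.image_encoder_m(images).data
        em = model.gene_encoder_m(expression).data

    l_con = _contrastive_term(v, e, vm, em, config.alpha, config.tau)
    l_igm = _igm_term(model, v_tok, e_tok, vm, em, config)
    loss = l_con + config.lambda_igm * l_igm

    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    ema_update(model.momentum_state())
    model.eval()
    return {"loss": float(loss.data), "l_con": float(l_con.data), "l_igm": float(l_igm.data)}


def train_alignment(images: np.ndarray, expression: np.ndarray,
                    model: AlignmentModel, config: AlignConfig,
                    log_path=None) -> list:
    """Minibatch training loop over matched (patches, expression) arrays.

    Batches are sampled uniformly with a generator derived from
    ``config.seed``; the same seed also drives dropout, making two runs with
    identical inputs bitwise-identical.
    """
    n = images.shape[0]
    rng = np.random.default_rng(config.seed)
    set_rng(np.random.default_rng(config.seed + 1))
    optimizer = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    history = []
    log_file = open(log_path, "w") if log_path else None
    try:
        for step in range(config.steps):
            idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
            record = alignment_training_step(images[idx], expression[idx], model,
                                             optimizer, config)
            record["step"] = step
            history.append(record)
            if log_file:
                log_file.write(json.dumps(record) + "\n")
    finally:
        if log_file:
            log_file.close()
    return history
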