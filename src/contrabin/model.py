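"""Contrastive multi-view representation learning for contigs.

Two feed-forward encoders are trained jointly:

* the **Coverage network** ``f_cov`` — three affine layers mapping the
  2M-dimensional normalized coverage vector to a fixed-dimensional
  embedding, so downstream layers are insulated from the number of
  sequencing samples;
* the **Combine network** ``f_combine`` — three affine layers applied to
  the concatenation of the L2-normalized coverage embedding and the
  136-dimensional composition vector, producing the latent embedding z.

Training minimizes the multi-view NT-Xent (normalized temperature-scaled
cross-entropy) loss: within a mini-batch of N_bs contigs carrying V views
each, all view pairs of one contig are positives and every view of every
other contig is a negative. Cosine similarity is scaled by a temperature
tau, set by assembly contiguity: tau = 0.07 when the assembly N50 exceeds
10,000 bp, else 0.15.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autograd import Adam, Tensor

logger = logging.getLogger(__name__)

TAU_HIGH_N50 = 0.07
TAU_LOW_N50 = 0.15
N50_TAU_THRESHOLD = 10000


def tau_from_n50(n50: int) -> float:
    """Temperature rule: 0.07 for contiguous assemblies (N50 > 10,000 bp),
    0.15 otherwise."""
    return TAU_HIGH_N50 if n50 > N50_TAU_THRESHOLD else TAU_LOW_N50


@dataclass
class EncoderConfig:
    """Architecture of the two encoders. Widths are deliberately
    config-exposed; the library defaults below are the documented package
    defaults, not values with any external provenance."""

    cov_hidden: tuple = (2048, 2048)
    cov_out_dim: int = 2048
    combine_hidden: tuple = (2048, 2048)
    latent_dim: int = 128
    activation: str = "leaky_relu"
    leaky_alpha: float = 0.01
    dropout: float = 0.2

    def __post_init__(self):
        if len(self.cov_hidden) != 2 or len(self.combine_hidden) != 2:
            raise ValueError("each network has exactly 3 affine layers (2 hidden widths)")

    @classmethod
    def small(cls) -> "EncoderConfig":
        """Reduced-width configuration for communities of ~10^3 contigs.

        Narrow layers plus stronger dropout (0.5): on small communities the
        instance-discrimination objective can otherwise memorize individual
        contigs, which erodes the genome-level structure the clustering
        needs."""
        return cls(cov_hidden=(128, 128), cov_out_dim=64,
                   combine_hidden=(128, 128), latent_dim=32, dropout=0.5)


@dataclass
class TrainConfig:
    tau: float | None = None  # None -> resolve by the N50 rule
    epochs: int = 200
    batch_size: int = 1024
    lr: float = 1e-3
    optimizer: str = "adam"
    early_stop_patience: int = 10
    early_stop_min_delta: float = 1e-4
    seed: int = 0


# ---------------------------------------------------------------------------
# similarity and losses (numpy reference API)
# ---------------------------------------------------------------------------

def cosine(a, b) -> float:
    """cos(a, b) = a.b / (|a||b|); errors on zero vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for zero vectors")
    return float(a @ b / (na * nb))


def _cos_matrix(Z: np.ndarray) -> np.ndarray:
    Zn = Z / np.linalg.norm(Z, axis=-1, keepdims=True)
    return Zn @ Zn.reshape(-1, Z.shape[-1]).T if Z.ndim == 2 else Zn


def ntxent_pair(Z: np.ndarray, i: int, k: int, kp: int, tau: float) -> float:
    """Two-view NT-Xent term l(z_{i,k}, z_{i,k'}) for a batch Z of shape
    (N_bs, V, d). The denominator runs over all contigs s: the same-view
    term exp(cos(z_{i,k}, z_{s,k})/tau) is excluded for s = i, while the
    other-view term (which includes the positive at s = i) is kept."""
    Z = np.asarray(Z, dtype=np.float64)
    n_bs = Z.shape[0]
    anchor = Z[i, k]
    num = np.exp(cosine(anchor, Z[i, kp]) / tau)
    den = 0.0
    for s in range(n_bs):
        if s != i:
            den += np.exp(cosine(anchor, Z[s, k]) / tau)
        den += np.exp(cosine(anchor, Z[s, kp]) / tau)
    return float(-np.log(num / den))


def loss_2view(Z: np.ndarray, tau: float) -> float:
    """Symmetric two-view NT-Xent batch loss,
    (1/2N_bs) sum_i [l(z_i1, z_i2) + l(z_i2, z_i1)]."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 3 or Z.shape[1] != 2:
        raise ValueError("loss_2view requires Z of shape (N_bs, 2, d)")
    n_bs = Z.shape[0]
    total = sum(ntxent_pair(Z, i, 0, 1, tau) + ntxent_pair(Z, i, 1, 0, tau)
                for i in range(n_bs))
    return total / (2 * n_bs)


def _pair_masks(n_bs: int, V: int):
    cidx = np.repeat(np.arange(n_bs), V)
    same = cidx[:, None] == cidx[None, :]
    pos = same & ~np.eye(n_bs * V, dtype=bool)
    neg = ~same
    return pos, neg


def loss_multiview(Z: np.ndarray, tau: float) -> float:
    """Multi-view NT-Xent batch loss for Z of shape (N_bs, V, d).

    For each anchor view v of contig i and each other view v1 of the same
    contig, the denominator is the positive term plus every view of every
    *other* contig in the batch; the remaining views of contig i itself are
    not negatives. Averaged over the N_bs * V * (V-1) ordered positive
    pairs."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 3:
        raise ValueError("loss_multiview requires Z of shape (N_bs, V, d)")
    n_bs, V, d = Z.shape
    if V < 2:
        raise ValueError("need at least two views")
    if n_bs == 1:
        return 0.0
    flat = Z.reshape(n_bs * V, d)
    flat = flat / np.linalg.norm(flat, axis=1, keepdims=True)
    S = (flat @ flat.T) / tau
    E = np.exp(S)
    pos, neg = _pair_masks(n_bs, V)
    neg_sum = (E * neg).sum(axis=1, keepdims=True)
    terms = (S - np.log(E + neg_sum)) * pos
    return float(-terms.sum() / (n_bs * V * (V - 1)))


def _loss_multiview_tensor(Z: Tensor, n_bs: int, V: int, tau: float) -> Tensor:
    """Autograd twin of :func:`loss_multiview` on a flat (N_bs*V, d) Tensor."""
    Zn = Z.l2_normalize_rows()
    S = Zn.matmul(Zn.T) * (1.0 / tau)
    E = S.exp()
    pos, neg = _pair_masks(n_bs, V)
    neg_sum = (E * Tensor(neg.astype(np.float64))).sum(axis=1, keepdims=True)
    terms = (S - (E + neg_sum).log()) * Tensor(pos.astype(np.float64))
    return -terms.sum() * (1.0 / (n_bs * V * (V - 1)))


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Trained weights plus the configs and feature dims they assume."""

    weights: dict              # name -> Tensor
    encoder_cfg: EncoderConfig
    cov_dim: int               # 2M
    com_dim: int               # T (136)
    tau: float | None = None
    fitted: bool = False
    loss_history: list = field(default_factory=list)

    def parameters(self):
        return list(self.weights.values())


def _init_layer(rng, fan_in, fan_out, name, weights):
    w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
    weights[name + ".W"] = Tensor(w, requires_grad=True)
    weights[name + ".b"] = Tensor(np.zeros(fan_out), requires_grad=True)


def init_params(cov_dim: int, com_dim: int, cfg: EncoderConfig,
                seed: int = 0) -> ModelParams:
    rng = np.random.default_rng(seed)
    weights = {}
    dims = [cov_dim, *cfg.cov_hidden, cfg.cov_out_dim]
    for i in range(3):
        _init_layer(rng, dims[i], dims[i + 1], f"cov.{i}", weights)
    dims = [cfg.cov_out_dim + com_dim, *cfg.combine_hidden, cfg.latent_dim]
    for i in range(3):
        _init_layer(rng, dims[i], dims[i + 1], f"combine.{i}", weights)
    return ModelParams(weights=weights, encoder_cfg=cfg,
                       cov_dim=cov_dim, com_dim=com_dim)


def _mlp(x: Tensor, weights, prefix, cfg: EncoderConfig, train: bool, rng) -> Tensor:
    for i in range(3):
        x = x.matmul(weights[f"{prefix}.{i}.W"]) + weights[f"{prefix}.{i}.b"]
        if i < 2:  # activation + dropout on hidden layers only
            x = x.leaky_relu(cfg.leaky_alpha)
            if train and cfg.dropout > 0:
                mask = (rng.random(x.shape) >= cfg.dropout) / (1 - cfg.dropout)
                x = x * Tensor(mask)
    return x


def forward(params: ModelParams, x_cov, x_com, train: bool = False,
            rng=None) -> Tensor:
    """z = f_combine(concat(l2norm(f_cov(x_cov)), x_com)).

    Deterministic in eval mode (``train=False``); dropout needs ``rng``."""
    x_cov = np.atleast_2d(np.asarray(x_cov, dtype=np.float64))
    x_com = np.atleast_2d(np.asarray(x_com, dtype=np.float64))
    if x_cov.shape[1] != params.cov_dim or x_com.shape[1] != params.com_dim:
        raise ValueError(
            f"feature dims ({x_cov.shape[1]}, {x_com.shape[1]}) do not match "
            f"model ({params.cov_dim}, {params.com_dim})")
    if train and rng is None:
        raise ValueError("training-mode forward requires an rng for dropout")
    cfg = params.encoder_cfg
    cov_emb = _mlp(Tensor(x_cov), params.weights, "cov", cfg, train, rng)
    cov_emb = cov_emb.l2_normalize_rows()
    combined = Tensor.concat([cov_emb, Tensor(x_com)], axis=1)
    return _mlp(combined, params.weights, "combine", cfg, train, rng)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def train(feature_block, view_set, train_cfg: TrainConfig,
          encoder_cfg: EncoderConfig, n50: int | None = None) -> ModelParams:
    """Fit the encoders by minimizing the multi-view NT-Xent loss.

    Mini-batches sample ``batch_size`` contigs and gather all their V views;
    the last incomplete batch is dropped (the loss needs a fixed negative
    structure), except that a batch size larger than the number of contigs
    is clamped to it. Early stopping watches the epoch-mean training loss.
    Returns fitted ModelParams carrying the per-epoch loss history.
    """
    tau = train_cfg.tau
    if tau is None:
        if n50 is None:
            raise ValueError("tau unset and no N50 given to resolve it")
        tau = tau_from_n50(n50)
    n_contigs, V = view_set.n_contigs, view_set.V
    params = init_params(feature_block.x_cov.shape[1], feature_block.x_com.shape[1],
                         encoder_cfg, seed=train_cfg.seed)
    params.tau = tau
    opt = Adam(params.parameters(), lr=train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed + 1)
    batch_size = train_cfg.batch_size
    if batch_size > n_contigs:
        logger.info("batch_size %d > %d contigs; clamping", batch_size, n_contigs)
        batch_size = n_contigs
    best = np.inf
    stall = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n_contigs)
        losses = []
        for b0 in range(0, n_contigs - batch_size + 1, batch_size):
            batch = order[b0:b0 + batch_size]
            rows = (batch[:, None] * V + np.arange(V)[None, :]).ravel()
            z = forward(params, feature_block.x_cov[rows], feature_block.x_com[rows],
                        train=True, rng=rng)
            loss = _loss_multiview_tensor(z, len(batch), V, tau)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        mean_loss = float(np.mean(losses))
        params.loss_history.append(mean_loss)
        if best - mean_loss > train_cfg.early_stop_min_delta:
            best = mean_loss
            stall = 0
        else:
            stall += 1
            if stall >= train_cfg.early_stop_patience:
                logger.info("early stop at epoch %d (loss %.5f)", epoch, mean_loss)
                break
    params.fitted = True
    return params


def embed(feature_block, params: ModelParams) -> np.ndarray:
    """Latent embeddings of the original contigs (view 0 only), eval mode."""
    if not params.fitted:
        raise ValueError("model has not been trained")
    rows = feature_block.original_rows()
    return forward(params, feature_block.x_cov[rows],
                   feature_block.x_com[rows], train=False).data


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_SCHEMA = 1


def save_checkpoint(params: ModelParams, path) -> None:
    path = os.fspath(path)
    arrays = {name: t.data for name, t in params.weights.items()}
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "encoder_cfg": asdict(params.encoder_cfg),
        "cov_dim": params.cov_dim,
        "com_dim": params.com_dim,
        "tau": params.tau,
        "fitted": params.fitted,
        "loss_history": params.loss_history,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> ModelParams:
    with np.load(os.fspath(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        cfg_d = meta["encoder_cfg"]
        cfg_d["cov_hidden"] = tuple(cfg_d["cov_hidden"])
        cfg_d["combine_hidden"] = tuple(cfg_d["combine_hidden"])
        cfg = EncoderConfig(**cfg_d)
        weights = {k: Tensor(data[k], requires_grad=True)
                   for k in data.files if k != "__meta__"}
    return ModelParams(weights=weights, encoder_cfg=cfg, cov_dim=meta["cov_dim"],
                       com_dim=meta["com_dim"], tau=meta["tau"],
                       fitted=meta["fitted"], loss_history=meta["loss_history"])
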