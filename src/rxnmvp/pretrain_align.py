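"""Stage-I self-supervised pre-training: distribution alignment + contrastive learning.

Both encoder outputs pass through one shared projection head g into the
alignment space. There, each embedding is turned into a distribution over its
d features with a softmax, and two objectives act per batch of N reactions:

* alignment: the Jeffreys divergence (symmetrized KL) between the two views'
  distributions of the same reaction, averaged as (1/2N) sum_i [KL(P_i||Q_i)
  + KL(Q_i||P_i)];
* contrast: symmetric InfoNCE over raw dot-product similarities at
  temperature tau, with in-batch negatives.

The combined loss is L_I = L_KL + lambda * L_InfoNCE. With lambda = 0 the
alignment term alone admits the degenerate solution where every embedding
maps to the same distribution; the contrastive term is what prevents it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .chem_data import ReactionDataset
from .nn import Adam, Dropout, Linear, Module, Tensor, log_softmax
from .sequence_encoder import SequenceEncoder
from .conformer_encoder import ConformerEncoder
from .tokenizer import EncodedReaction, Vocabulary, encode_reaction

__all__ = [
    "Stage1Config", "ProjectionHead", "Stage1LossReport",
    "jeffreys_alignment_loss", "infonce_loss", "stage1_loss",
    "train_stage1", "Stage1Model",
]


@dataclass(frozen=True)
class Stage1Config:
    lambda_weight: float = 1.0
    temperature: float = 0.1
    projector_hidden: int = 256
    projector_out: int = 128
    batch_size: int = 32
    epochs: int = 30
    learning_rate: float = 1e-3
    seed: int = 0
    max_len: int = 128
    normalize_embeddings: bool = False   # L2-normalize before similarities (off: raw dot)
    valid_fraction: float = 0.1

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.lambda_weight < 0:
            raise ValueError(f"lambda must be nonnegative, got {self.lambda_weight}")
        if self.batch_size < 2:
            raise ValueError("contrastive training needs batch_size >= 2")


@dataclass
class Stage1LossReport:
    l_kl: float
    l_infonce: float
    l_total: float

    @classmethod
    def from_components(cls, l_kl: float, l_infonce: float, lam: float) -> "Stage1LossReport":
        return cls(l_kl, l_infonce, l_kl + lam * l_infonce)


class ProjectionHead(Module):
    """Two-layer perceptron with one nonlinearity; shared across both views."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, out_dim, rng)

    def __call__(self, h: Tensor) -> Tensor:
        if h.shape[-1] != self.fc1.weight.shape[0]:
            raise ValueError(
                f"projector expects input dim {self.fc1.weight.shape[0]}, got {h.shape[-1]}"
            )
        return self.fc2(self.fc1(h).relu())


def _ensure_tensor(x) -> Tensor:
    # float64 inputs keep full precision (diagnostics/verification); model
    # activations arrive as float32 tensors and stay float32
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def jeffreys_alignment_loss(x_s, x_c) -> Tensor:
    """(1/2N) sum_i [KL(P_i||Q_i) + KL(Q_i||P_i)] with P = softmax(x_s_i),
    Q = softmax(x_c_i) over the d features; computed in log-space."""
    x_s, x_c = _ensure_tensor(x_s), _ensure_tensor(x_c)
    if x_s.shape != x_c.shape:
        raise ValueError(f"shape mismatch: {x_s.shape} vs {x_c.shape}")
    if not (np.all(np.isfinite(x_s.data)) and np.all(np.isfinite(x_c.data))):
        raise ValueError("non-finite alignment inputs")
    n = x_s.shape[0]
    log_p = log_softmax(x_s, axis=1)
    log_q = log_softmax(x_c, axis=1)
    p = log_p.exp()
    q = log_q.exp()
    kl_pq = (p * (log_p - log_q)).sum()
    kl_qp = (q * (log_q - log_p)).sum()
    return (kl_pq + kl_qp) * (1.0 / (2.0 * n))


def infonce_loss(x_s, x_c, temperature: float = 0.1) -> Tensor:
    """Symmetric InfoNCE with raw dot-product similarities and in-batch
    negatives: -(1/2N) sum_i [log softmax_k(s_ik)|_i + log softmax_k(s_ki)|_i]."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    x_s, x_c = _ensure_tensor(x_s), _ensure_tensor(x_c)
    if x_s.shape != x_c.shape:
        raise ValueError(f"shape mismatch: {x_s.shape} vs {x_c.shape}")
    n = x_s.shape[0]
    sim = (x_s @ x_c.transpose()) * (1.0 / temperature)   # (N, N), s_ik
    diag = np.arange(n)
    log_rows = log_softmax(sim, axis=1)[diag, diag]       # seq -> conf direction
    log_cols = log_softmax(sim.transpose(), axis=1)[diag, diag]
    return -(log_rows.sum() + log_cols.sum()) * (1.0 / (2.0 * n))


def stage1_loss(x_s, x_c, cfg: Stage1Config) -> tuple[Tensor, Stage1LossReport]:
    l_kl = jeffreys_alignment_loss(x_s, x_c)
    l_nce = infonce_loss(x_s, x_c, cfg.temperature)
    total = l_kl + cfg.lambda_weight * l_nce
    report = Stage1LossReport(float(l_kl.data), float(l_nce.data), float(total.data))
    return total, report


def jeffreys_divergence_rows(x_s: np.ndarray, x_c: np.ndarray) -> np.ndarray:
    """Plain-NumPy per-row Jeffreys divergence between softmax distributions
    (diagnostics; no gradients)."""
    def logsm(x):
        x = x - x.max(axis=1, keepdims=True)
        return x - np.log(np.exp(x).sum(axis=1, keepdims=True))

    lp, lq = logsm(np.asarray(x_s, float)), logsm(np.asarray(x_c, float))
    p, q = np.exp(lp), np.exp(lq)
    return ((p - q) * (lp - lq)).sum(axis=1)


class Stage1Model(Module):
    """Both encoders plus the shared projection head."""

    def __init__(self, seq_encoder: SequenceEncoder, conf_encoder: ConformerEncoder,
                 cfg: Stage1Config):
        super().__init__()
        self.seq_encoder = seq_encoder
        self.conf_encoder = conf_encoder
        self.cfg = cfg
        in_dim = seq_encoder.cfg.output_dim
        if in_dim != conf_encoder.output_dim:
            raise ValueError("view dimensions must match for a shared projector")
        self.projector = ProjectionHead(in_dim, cfg.projector_hidden, cfg.projector_out,
                                        seed=cfg.seed + 17)

    def project_views(self, records, encoded: list[EncodedReaction]) -> tuple[Tensor, Tensor]:
        h_s = self.seq_encoder(encoded)
        h_c = self.conf_encoder(records)
        x_s = self.projector(h_s)
        x_c = self.projector(h_c)
        if self.cfg.normalize_embeddings:
            x_s = x_s * ((x_s * x_s).sum(axis=1, keepdims=True) + 1e-12) ** -0.5
            x_c = x_c * ((x_c * x_c).sum(axis=1, keepdims=True) + 1e-12) ** -0.5
        return x_s, x_c


def train_stage1(
    dataset: ReactionDataset,
    vocab: Vocabulary,
    cfg: Stage1Config,
    seq_encoder: Optional[SequenceEncoder] = None,
    conf_encoder: Optional[ConformerEncoder] = None,
    log_path: Optional[str | Path] = None,
) -> tuple[Stage1Model, list[dict]]:
    """Jointly optimize both encoders and the projector with Adam.

    Returns the best-validation model (weights restored) and the per-epoch
    history of training/validation losses.
    """
    from .sequence_encoder import SeqEncoderConfig
    from .conformer_encoder import SchNetConfig

    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if seq_encoder is None:
        seq_encoder = SequenceEncoder(SeqEncoderConfig(vocab_size=len(vocab)), seed=cfg.seed)
    if conf_encoder is None:
        conf_encoder = ConformerEncoder(SchNetConfig(), seed=cfg.seed + 1)
    model = Stage1Model(seq_encoder, conf_encoder, cfg)

    records = list(dataset.records)
    encoded = [encode_reaction(r, vocab, cfg.max_len) for r in records]
    rng = np.random.default_rng(cfg.seed)
    n = len(records)
    order = rng.permutation(n)
    n_valid = max(cfg.batch_size, int(round(cfg.valid_fraction * n))) if n >= 2 * cfg.batch_size else 0
    valid_idx, train_idx = order[:n_valid], order[n_valid:]

    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[dict] = []
    best_state, best_val = None, np.inf

    def run_batches(idx: np.ndarray, train: bool) -> Stage1LossReport:
        totals = np.zeros(3)
        count = 0
        for start in range(0, len(idx) - 1, cfg.batch_size):
            chunk = idx[start : start + cfg.batch_size]
            if len(chunk) < 2:
                continue
            recs = [records[i] for i in chunk]
            encs = [encoded[i] for i in chunk]
            x_s, x_c = model.project_views(recs, encs)
            loss, rep = stage1_loss(x_s, x_c, cfg)
            if train:
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
            totals += (rep.l_kl, rep.l_infonce, rep.l_total)
            count += 1
        if count == 0:
            raise ValueError("not enough records for a single batch")
        return Stage1LossReport(*(totals / count))

    log_file = open(log_path, "w") if log_path else None
    try:
        for epoch in range(cfg.epochs):
            model.train()
            epoch_order = train_idx[rng.permutation(len(train_idx))]
            train_rep = run_batches(epoch_order, train=True)
            entry = {"epoch": epoch, "train_l_kl": train_rep.l_kl,
                     "train_l_infonce": train_rep.l_infonce, "train_l_total": train_rep.l_total}
            model.eval()
            if n_valid:
                val_rep = run_batches(valid_idx, train=False)
                entry.update(valid_l_kl=val_rep.l_kl, valid_l_infonce=val_rep.l_infonce,
                             valid_l_total=val_rep.l_total)
                score = val_rep.l_total
            else:
                score = train_rep.l_total
            if score < best_val:
                best_val = score
                best_state = model.state_dict()
            history.append(entry)
            if log_file:
                log_file.write(json.dumps(entry) + "\n")
    finally:
        if log_file:
            log_file.close()
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history
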