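"""Sequence-view encoder: token embedding + multi-layer bidirectional GRU.

An encoded reaction ([CLS] mol1 [SEP] mol2 [SEP] ..., padded) is embedded
token-wise and run through a bidirectional GRU; the reaction representation
h_s is the concatenation of the final hidden states of the two directions of
the last layer (forward first), giving a 2 * hidden_dim vector. Padding
positions are masked out of the recurrence, so extra [PAD] tokens never
change h_s.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn import BiGRU, Dropout, Embedding, Module, Tensor
from .tokenizer import EncodedReaction

__all__ = ["SeqEncoderConfig", "SequenceEncoder", "batch_encoded", "pool_bigru_states"]


def pool_bigru_states(forward_final, backward_final):
    """Read the reaction representation off a bidirectional GRU: the
    concatenation [forward_final ; backward_final], forward first.

    Accepts (B, H) tensors or arrays; linear in both arguments.
    """
    from .nn import concat as _concat

    f = forward_final if isinstance(forward_final, Tensor) else Tensor(forward_final)
    b = backward_final if isinstance(backward_final, Tensor) else Tensor(backward_final)
    if f.shape != b.shape:
        raise ValueError(f"direction shape mismatch: {f.shape} vs {b.shape}")
    return _concat([f, b], axis=f.ndim - 1)


@dataclass(frozen=True)
class SeqEncoderConfig:
    vocab_size: int
    embedding_dim: int = 256
    hidden_dim: int = 128          # per direction
    num_layers: int = 2
    dropout: float = 0.3

    def __post_init__(self):
        if min(self.vocab_size, self.embedding_dim, self.hidden_dim, self.num_layers) < 1:
            raise ValueError("all sequence-encoder dimensions must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")

    @property
    def output_dim(self) -> int:
        return 2 * self.hidden_dim


def batch_encoded(batch: list[EncodedReaction]) -> tuple[np.ndarray, np.ndarray]:
    """Stack encoded reactions into (T, B) index and (B,) length arrays,
    trimming shared padding to the batch maximum length."""
    if not batch:
        raise ValueError("empty batch")
    lengths = np.array([e.length for e in batch], dtype=np.int64)
    T = int(lengths.max())
    idx = np.zeros((T, len(batch)), dtype=np.int64)
    for b, e in enumerate(batch):
        idx[:, b] = e.indices[:T]
    return idx, lengths


class SequenceEncoder(Module):
    def __init__(self, cfg: SeqEncoderConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.embedding = Embedding(cfg.vocab_size, cfg.embedding_dim, rng)
        self.emb_drop = Dropout(cfg.dropout, np.random.default_rng(rng.integers(2**31)))
        self.gru = BiGRU(cfg.embedding_dim, cfg.hidden_dim, cfg.num_layers, rng,
                         dropout=cfg.dropout)

    def __call__(self, batch: list[EncodedReaction]) -> Tensor:
        """Encode a batch; returns (B, 2*hidden_dim) representations h_s."""
        idx, lengths = batch_encoded(batch)
        if idx.max() >= self.cfg.vocab_size:
            raise ValueError(
                f"token index {idx.max()} out of range for vocab size {self.cfg.vocab_size}"
            )
        x = self.embedding(idx)          # (T, B, E)
        x = self.emb_drop(x)
        return self.gru(x, lengths)

    def config_dict(self) -> dict:
        return asdict(self.cfg)
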