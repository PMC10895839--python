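"""Stage-II supervised pre-training and fine-tuning for yield regression.

The predictor is a two-layer perceptron on the concatenated view
representations h_s ⊕ h_c (sequence first, 512 -> 256 -> 1 by default). The
training objective is the sum of squared (or absolute, for fine-tuning)
errors on yields normalized to [0, 1]; all reported metrics are on the 0-100
percentage scale. Training is end to end (encoders + predictor) unless the
encoders are frozen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

import numpy as np

from .chem_data import Reaction, ReactionDataset
from .nn import Adam, Dropout, Linear, Module, Tensor, concat
from .sequence_encoder import SequenceEncoder, SeqEncoderConfig
from .conformer_encoder import ConformerEncoder, SchNetConfig
from .tokenizer import Vocabulary, encode_reaction

__all__ = [
    "PredictorConfig", "TrainConfig", "FineTuneGrid", "YieldPrediction",
    "YieldModel", "stage2_loss", "train_yield_model", "predict_yield",
    "grid_search_finetune",
]


@dataclass(frozen=True)
class PredictorConfig:
    input_dim: int = 512           # dim(h_s) + dim(h_c)
    hidden_dim: int = 256
    dropout: float = 0.1

    def __post_init__(self):
        if self.input_dim < 1 or self.hidden_dim < 1:
            raise ValueError("predictor dimensions must be positive")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    loss: str = "mse"              # "mse" (squared) or "mae" (absolute)
    seed: int = 0
    max_len: int = 128
    freeze_encoders: bool = False
    sequence_only: bool = False    # fall back to h_s when conformers are absent

    def __post_init__(self):
        if self.loss not in ("mse", "mae"):
            raise ValueError(f"loss must be 'mse' or 'mae', got {self.loss!r}")


@dataclass(frozen=True)
class FineTuneGrid:
    learning_rates: tuple[float, ...] = (3e-4, 1e-3, 3e-3)
    dropouts: tuple[float, ...] = (0.1, 0.3)
    weight_decays: tuple[float, ...] = (0.0, 1e-4, 1e-5)
    losses: tuple[str, ...] = ("mse", "mae")

    def cells(self) -> list[dict]:
        if not all((self.learning_rates, self.dropouts, self.weight_decays, self.losses)):
            raise ValueError("every grid axis must be nonempty")
        return [
            {"learning_rate": lr, "dropout": dr, "weight_decay": wd, "loss": loss}
            for lr, dr, wd, loss in itertools.product(
                self.learning_rates, self.dropouts, self.weight_decays, self.losses
            )
        ]


@dataclass(frozen=True)
class YieldPrediction:
    record_id: str
    yield_pct: float               # clipped to [0, 100] on report


class Predictor(Module):
    def __init__(self, cfg: PredictorConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.fc1 = Linear(cfg.input_dim, cfg.hidden_dim, rng)
        self.drop = Dropout(cfg.dropout, np.random.default_rng(rng.integers(2**31)))
        self.fc2 = Linear(cfg.hidden_dim, 1, rng)

    def __call__(self, h: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(h).relu()))


class YieldModel(Module):
    """Encoders + predictor; predicts normalized yield in [0, 1]."""

    def __init__(self, seq_encoder: SequenceEncoder, conf_encoder: ConformerEncoder,
                 predictor_cfg: Optional[PredictorConfig] = None, seed: int = 0,
                 sequence_only: bool = False):
        super().__init__()
        self.seq_encoder = seq_encoder
        self.conf_encoder = conf_encoder
        self.sequence_only = sequence_only
        in_dim = seq_encoder.cfg.output_dim + (0 if sequence_only else conf_encoder.output_dim)
        cfg = predictor_cfg or PredictorConfig(input_dim=in_dim)
        if cfg.input_dim != in_dim:
            raise ValueError(f"predictor input dim {cfg.input_dim} != encoder output {in_dim}")
        self.predictor_cfg = cfg
        self.predictor = Predictor(cfg, seed=seed + 23)

    def forward_batch(self, records: list[Reaction], encoded) -> Tensor:
        h_s = self.seq_encoder(encoded)
        if self.sequence_only:
            h = h_s
        else:
            h_c = self.conf_encoder(records)
            h = concat([h_s, h_c], axis=1)   # sequence view first
        return self.predictor(h)[:, 0]


def stage2_loss(y: np.ndarray, y_hat: Tensor | np.ndarray, kind: str = "mse") -> Tensor:
    """Sum of squared (or absolute) errors on the normalized [0, 1] scale."""
    y = np.asarray(y, dtype=np.float32)
    y_hat = y_hat if isinstance(y_hat, Tensor) else Tensor(np.asarray(y_hat, dtype=np.float32))
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    diff = y_hat - Tensor(y)
    if kind == "mse":
        return (diff * diff).sum()
    if kind == "mae":
        # |x| = x * sign(x); sign is constant wrt the graph
        return (diff * Tensor(np.sign(diff.data))).sum()
    raise ValueError(f"unknown loss kind {kind!r}")


def predict_yield(
    model: YieldModel, records: list[Reaction], vocab: Vocabulary, max_len: int = 128
) -> list[YieldPrediction]:
    """Deterministic (eval-mode) yield predictions on the percentage scale."""
    model.eval()
    encoded = [encode_reaction(r, vocab, max_len) for r in records]
    y_hat = model.forward_batch(records, encoded).data * 100.0
    return [
        YieldPrediction(r.record_id, float(np.clip(y, 0.0, 100.0)))
        for r, y in zip(records, y_hat)
    ]


def _predictions_raw(model: YieldModel, records, vocab, max_len, batch_size=256) -> np.ndarray:
    model.eval()
    out = []
    for start in range(0, len(records), batch_size):
        chunk = records[start : start + batch_size]
        encoded = [encode_reaction(r, vocab, max_len) for r in chunk]
        out.append(model.forward_batch(chunk, encoded).data)
    return np.concatenate(out) * 100.0


def train_yield_model(
    dataset: ReactionDataset,
    vocab: Vocabulary,
    cfg: TrainConfig,
    seq_encoder: Optional[SequenceEncoder] = None,
    conf_encoder: Optional[ConformerEncoder] = None,
    init_model: Optional[YieldModel] = None,
) -> tuple[YieldModel, list[dict]]:
    """Supervised training with best-validation checkpointing.

    `dataset` must carry split labels; records in the "train" split are
    optimized and "valid" drives model selection. Encoders may come from a
    stage-I model (`seq_encoder`/`conf_encoder`) for pre-trained
    initialization, or a full `init_model` may be resumed.
    """
    if dataset.split_labels is None:
        raise ValueError("train_yield_model requires split labels")
    train_recs = [r for r in dataset.records if dataset.split_labels[r.record_id] == "train"]
    valid_recs = [r for r in dataset.records if dataset.split_labels[r.record_id] == "valid"]
    if not valid_recs:
        raise ValueError("no validation split present")
    for rec in train_recs + valid_recs:
        if not rec.has_valid_yield():
            raise ValueError(f"record {rec.record_id!r} lacks a valid yield")

    if init_model is not None:
        model = init_model
    else:
        if seq_encoder is None:
            seq_encoder = SequenceEncoder(SeqEncoderConfig(vocab_size=len(vocab)), seed=cfg.seed)
        if conf_encoder is None:
            conf_encoder = ConformerEncoder(SchNetConfig(), seed=cfg.seed + 1)
        model = YieldModel(seq_encoder, conf_encoder, seed=cfg.seed,
                           sequence_only=cfg.sequence_only)

    params = (
        model.predictor.parameters() if cfg.freeze_encoders else model.parameters()
    )
    optimizer = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    encoded_train = [encode_reaction(r, vocab, cfg.max_len) for r in train_recs]
    y_train = np.array([r.yield_pct for r in train_recs], dtype=np.float32) / 100.0
    y_valid = np.array([r.yield_pct for r in valid_recs], dtype=np.float32)

    history: list[dict] = []
    best_state, best_val = None, np.inf
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_recs))
        train_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            chunk = order[start : start + cfg.batch_size]
            recs = [train_recs[i] for i in chunk]
            encs = [encoded_train[i] for i in chunk]
            y_hat = model.forward_batch(recs, encs)
            loss = stage2_loss(y_train[chunk], y_hat, cfg.loss)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            train_loss += float(loss.data)
        pred_valid = _predictions_raw(model, valid_recs, vocab, cfg.max_len)
        val_rmse = float(np.sqrt(np.mean((pred_valid - y_valid) ** 2)))
        history.append({"epoch": epoch, "train_loss": train_loss / max(len(train_recs), 1),
                        "valid_rmse": val_rmse})
        if val_rmse < best_val:
            best_val = val_rmse
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def grid_search_finetune(
    train: ReactionDataset,
    vocab: Vocabulary,
    grid: FineTuneGrid,
    base_cfg: TrainConfig,
    eval_fraction: float = 0.1,
    seed: int = 0,
    stage1_states: Optional[dict] = None,
) -> tuple[dict, YieldModel, list[dict]]:
    """Grid search over learning rate, dropout, weight decay, and loss.

    Each cell trains on (1 - eval_fraction) of the training records and is
    scored by held-out RMSE; ties resolve to the first cell in deterministic
    grid order. The winning configuration is retrained on all records (with
    an internal validation split for checkpoint selection).
    """
    if not 0.0 < eval_fraction < 1.0:
        raise ValueError(f"eval_fraction must be in (0, 1), got {eval_fraction}")
    records = list(train.records)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_eval = max(1, int(round(eval_fraction * len(records))))
    if n_eval >= len(records) - 1:
        raise ValueError("degenerate split: too few records for grid search")
    eval_ids = {records[i].record_id for i in order[:n_eval]}

    def labelled(valid_ids: set[str]) -> ReactionDataset:
        labels = {
            r.record_id: "valid" if r.record_id in valid_ids else "train" for r in records
        }
        return ReactionDataset(records, labels, train.provenance)

    inner = labelled(eval_ids)
    report: list[dict] = []
    best_cell, best_rmse = None, np.inf
    for cell in grid.cells():
        cfg = dc_replace(base_cfg, learning_rate=cell["learning_rate"],
                         weight_decay=cell["weight_decay"], loss=cell["loss"], seed=seed)
        seq = SequenceEncoder(SeqEncoderConfig(vocab_size=len(vocab)), seed=seed)
        conf = ConformerEncoder(SchNetConfig(), seed=seed + 1)
        model = YieldModel(seq, conf, PredictorConfig(
            input_dim=seq.cfg.output_dim + conf.output_dim, dropout=cell["dropout"]),
            seed=seed)
        if stage1_states is not None:
            model.seq_encoder.load_state_dict(stage1_states["seq_encoder"])
            model.conf_encoder.load_state_dict(stage1_states["conf_encoder"])
        model, _ = train_yield_model(inner, vocab, cfg, init_model=model)
        eval_recs = [r for r in records if r.record_id in eval_ids]
        preds = _predictions_raw(model, eval_recs, vocab, cfg.max_len)
        truth = np.array([r.yield_pct for r in eval_recs])
        rmse = float(np.sqrt(np.mean((preds - truth) ** 2)))
        report.append({**cell, "heldout_rmse": rmse})
        if rmse < best_rmse:
            best_rmse, best_cell = rmse, cell

    # retrain the winner on the full training set
    cfg = dc_replace(base_cfg, learning_rate=best_cell["learning_rate"],
                     weight_decay=best_cell["weight_decay"], loss=best_cell["loss"], seed=seed)
    seq = SequenceEncoder(SeqEncoderConfig(vocab_size=len(vocab)), seed=seed)
    conf = ConformerEncoder(SchNetConfig(), seed=seed + 1)
    model = YieldModel(seq, conf, PredictorConfig(
        input_dim=seq.cfg.output_dim + conf.output_dim, dropout=best_cell["dropout"]),
        seed=seed)
    if stage1_states is not None:
        model.seq_encoder.load_state_dict(stage1_states["seq_encoder"])
        model.conf_encoder.load_state_dict(stage1_states["conf_encoder"])
    final, _ = train_yield_model(labelled(eval_ids), vocab, cfg, init_model=model)
    return best_cell, final, report
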