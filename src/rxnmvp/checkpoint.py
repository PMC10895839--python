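"""Model checkpointing: weights + configuration + vocabulary hash in one .npz.

Loading refuses to proceed against a vocabulary whose content hash differs
from the one recorded at save time, which catches silently mismatched
token-index maps before they corrupt results.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .conformer_encoder import ConformerEncoder, SchNetConfig
from .pretrain_align import Stage1Config, Stage1Model
from .sequence_encoder import SeqEncoderConfig, SequenceEncoder
from .tokenizer import Vocabulary
from .yield_model import PredictorConfig, YieldModel

__all__ = ["save_stage1", "load_stage1", "save_yield_model", "load_yield_model",
           "checkpoint_hash"]


def _pack(model, meta: dict, path: str | Path) -> None:
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _unpack(path: str | Path) -> tuple[dict, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    return meta, state


def checkpoint_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def save_stage1(model: Stage1Model, vocab: Vocabulary, path: str | Path) -> None:
    meta = {
        "kind": "stage1",
        "stage1": model.cfg.__dict__,
        "seq": model.seq_encoder.cfg.__dict__,
        "schnet": model.conf_encoder.cfg.__dict__,
        "gru_hidden": model.conf_encoder.gru_hidden,
        "vocab_hash": vocab.content_hash(),
    }
    _pack(model, meta, path)


def load_stage1(path: str | Path, vocab: Vocabulary) -> Stage1Model:
    meta, state = _unpack(path)
    if meta.get("kind") != "stage1":
        raise ValueError(f"{path} is not a stage-1 checkpoint")
    if meta["vocab_hash"] != vocab.content_hash():
        raise ValueError(f"{path}: checkpoint was saved with a different vocabulary")
    seq = SequenceEncoder(SeqEncoderConfig(**meta["seq"]))
    conf = ConformerEncoder(SchNetConfig(**meta["schnet"]), gru_hidden=meta["gru_hidden"])
    model = Stage1Model(seq, conf, Stage1Config(**meta["stage1"]))
    model.load_state_dict(state)
    model.eval()
    return model


def save_yield_model(model: YieldModel, vocab: Vocabulary, path: str | Path) -> None:
    meta = {
        "kind": "yield",
        "seq": model.seq_encoder.cfg.__dict__,
        "schnet": model.conf_encoder.cfg.__dict__,
        "gru_hidden": model.conf_encoder.gru_hidden,
        "predictor": model.predictor_cfg.__dict__,
        "sequence_only": model.sequence_only,
        "vocab_hash": vocab.content_hash(),
    }
    _pack(model, meta, path)


def load_yield_model(path: str | Path, vocab: Vocabulary) -> YieldModel:
    meta, state = _unpack(path)
    if meta.get("kind") != "yield":
        raise ValueError(f"{path} is not a yield-model checkpoint")
    if meta["vocab_hash"] != vocab.content_hash():
        raise ValueError(f"{path}: checkpoint was saved with a different vocabulary")
    seq = SequenceEncoder(SeqEncoderConfig(**meta["seq"]))
    conf = ConformerEncoder(SchNetConfig(**meta["schnet"]), gru_hidden=meta["gru_hidden"])
    model = YieldModel(seq, conf, PredictorConfig(**meta["predictor"]),
                       sequence_only=meta["sequence_only"])
    model.load_state_dict(state)
    model.eval()
    return model
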