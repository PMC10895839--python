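"""Yield predictor: loss, prediction contracts, freezing, checkpoints, grid search."""

import numpy as np
import pytest

from rxnmvp.chem_data import ReactionDataset, stratified_split
from rxnmvp.checkpoint import load_yield_model, save_yield_model
from rxnmvp.conformer_encoder import ConformerEncoder, SchNetConfig
from rxnmvp.sequence_encoder import SeqEncoderConfig, SequenceEncoder
from rxnmvp.synthetic_data import SyntheticSpec, make_synthetic_dataset
from rxnmvp.yield_model import (
    FineTuneGrid, PredictorConfig, TrainConfig, YieldModel, grid_search_finetune,
    predict_yield, stage2_loss, train_yield_model,
)


@pytest.fixture(scope="module")
def tiny_split(small_dataset, small_vocab):
    d = stratified_split(small_dataset, (16, 2, 2), n_bins=5, seed=0)
    return d, small_vocab


def small_model(vocab, seed=0, **kw):
    seq = SequenceEncoder(SeqEncoderConfig(vocab_size=len(vocab)), seed=seed)
    conf = ConformerEncoder(SchNetConfig(), seed=seed + 1)
    return YieldModel(seq, conf, seed=seed, **kw)


def test_stage2_loss_examples():
    assert float(stage2_loss([0.5, 0.2], [0.5, 0.2]).data) == pytest.approx(0.0)
    assert float(stage2_loss([1.0, 0.0], [0.0, 0.0]).data) == pytest.approx(1.0)
    assert float(stage2_loss([0.5], [0.1]).data) == pytest.approx(0.16, abs=1e-6)
    assert float(stage2_loss([0.5], [0.1], kind="mae").data) == pytest.approx(0.4, abs=1e-6)
    with pytest.raises(ValueError):
        stage2_loss([1.0], [1.0, 2.0])


def test_predict_yield_scalar_deterministic_and_clipped(tiny_split):
    d, vocab = tiny_split
    model = small_model(vocab)
    preds1 = predict_yield(model, d.records[:4], vocab)
    preds2 = predict_yield(model, d.records[:4], vocab)
    assert len(preds1) == 4
    assert all(0.0 <= p.yield_pct <= 100.0 for p in preds1)
    assert [p.yield_pct for p in preds1] == [p.yield_pct for p in preds2]


def test_sequence_only_fallback_ignores_missing_conformers(small_vocab):
    from rxnmvp.chem_data import parse_reaction_smiles

    model = small_model(small_vocab, sequence_only=True)
    bare = [parse_reaction_smiles("CCO>>CC=O", record_id="x")]  # no coords at all
    preds = predict_yield(model, bare, small_vocab)
    assert len(preds) == 1 and np.isfinite(preds[0].yield_pct)


def test_freeze_keeps_encoder_weights_bit_identical(tiny_split):
    d, vocab = tiny_split
    model = small_model(vocab, seed=3)
    before_seq = {k: v.copy() for k, v in model.seq_encoder.state_dict().items()}
    before_conf = {k: v.copy() for k, v in model.conf_encoder.state_dict().items()}
    before_pred = {k: v.copy() for k, v in model.predictor.state_dict().items()}
    cfg = TrainConfig(epochs=1, batch_size=16, freeze_encoders=True, seed=3)
    model, _ = train_yield_model(d, vocab, cfg, init_model=model)
    for k, v in model.seq_encoder.state_dict().items():
        assert np.array_equal(v, before_seq[k])
    for k, v in model.conf_encoder.state_dict().items():
        assert np.array_equal(v, before_conf[k])
    assert any(
        not np.array_equal(v, before_pred[k]) for k, v in model.predictor.state_dict().items()
    )


def test_checkpoint_round_trip_preserves_predictions(tiny_split, tmp_path):
    d, vocab = tiny_split
    cfg = TrainConfig(epochs=1, batch_size=16, seed=1)
    model, _ = train_yield_model(d, vocab, cfg)
    path = tmp_path / "model.npz"
    save_yield_model(model, vocab, path)
    loaded = load_yield_model(path, vocab)
    p1 = [p.yield_pct for p in predict_yield(model, d.records[:6], vocab)]
    p2 = [p.yield_pct for p in predict_yield(loaded, d.records[:6], vocab)]
    assert p1 == p2


def test_checkpoint_rejects_mismatched_vocabulary(tiny_split, tmp_path):
    from rxnmvp.tokenizer import build_vocabulary

    d, vocab = tiny_split
    model = small_model(vocab)
    path = tmp_path / "model.npz"
    save_yield_model(model, vocab, path)
    other = build_vocabulary([["C"], ["O"]], min_frequency=1)
    with pytest.raises(ValueError, match="vocabulary"):
        load_yield_model(path, other)


def test_training_requires_valid_yields_and_splits(small_vocab, small_dataset):
    with pytest.raises(ValueError, match="split"):
        train_yield_model(small_dataset, small_vocab, TrainConfig(epochs=1))


def test_grid_search_prefers_working_learning_rate(tiny_split):
    d, vocab = tiny_split
    grid = FineTuneGrid(learning_rates=(1e-3, 300.0), dropouts=(0.1,),
                        weight_decays=(0.0,), losses=("mse",))
    base = TrainConfig(epochs=2, batch_size=16)
    best, model, report = grid_search_finetune(
        ReactionDataset(list(d.records)), vocab, grid, base, eval_fraction=0.2, seed=0
    )
    assert len(report) == 2
    assert best["learning_rate"] == 1e-3
    # the report carries one row per cell with its held-out score
    assert all("heldout_rmse" in row for row in report)


def test_default_grid_has_36_cells():
    assert len(FineTuneGrid().cells()) == 36


def test_predictor_dim_validation(small_vocab):
    seq = SequenceEncoder(SeqEncoderConfig(vocab_size=len(small_vocab)), seed=0)
    conf = ConformerEncoder(SchNetConfig(), seed=1)
    with pytest.raises(ValueError):
        YieldModel(seq, conf, PredictorConfig(input_dim=100))
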