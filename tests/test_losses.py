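"""Stage-I losses: worked values, double-loop oracles, and invariants."""

import numpy as np
import pytest

from rxnmvp.nn import Linear, Tensor
from rxnmvp.pretrain_align import (
    ProjectionHead, Stage1Config, infonce_loss, jeffreys_alignment_loss,
    jeffreys_divergence_rows, stage1_loss,
)


def softmax_np(x):
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def jeffreys_reference(x_s, x_c):
    """Naive double-loop Jeffreys alignment loss."""
    n, d = x_s.shape
    total = 0.0
    for i in range(n):
        p, q = softmax_np(x_s[i]), softmax_np(x_c[i])
        for j in range(d):
            total += p[j] * np.log(p[j] / q[j]) + q[j] * np.log(q[j] / p[j])
    return total / (2 * n)


def infonce_reference(x_s, x_c, tau):
    """Naive double-loop symmetric InfoNCE."""
    n = x_s.shape[0]
    sim = np.array([[x_s[i] @ x_c[k] / tau for k in range(n)] for i in range(n)])
    shift = sim.max()   # overflow guard; cancels in the softmax ratio
    total = 0.0
    for i in range(n):
        total -= np.log(np.exp(sim[i, i] - shift) / np.exp(sim[i] - shift).sum())
        total -= np.log(np.exp(sim[i, i] - shift) / np.exp(sim[:, i] - shift).sum())
    return total / (2 * n)


def test_jeffreys_worked_value():
    # P = (1/2, 1/2), Q = (2/3, 1/3): (KL(P||Q) + KL(Q||P)) / 2 = 0.057762...
    x_s = np.array([[0.0, 0.0]])
    x_c = np.array([[np.log(2.0), 0.0]])
    value = float(jeffreys_alignment_loss(x_s, x_c).data)
    assert value == pytest.approx(0.0577624, abs=1e-6)


def test_jeffreys_zero_and_symmetry():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(4, 8))
    assert float(jeffreys_alignment_loss(x, x).data) == pytest.approx(0.0, abs=1e-7)
    y = rng.normal(size=(4, 8))
    assert float(jeffreys_alignment_loss(x, y).data) == pytest.approx(
        float(jeffreys_alignment_loss(y, x).data), abs=1e-6
    )


def test_infonce_worked_values():
    # N=1: numerator equals denominator
    x = np.array([[1.0, 2.0]])
    assert float(infonce_loss(x, x, 1.0).data) == pytest.approx(0.0, abs=1e-6)
    # uniform similarities at N=2 -> ln 2
    zeros = np.zeros((2, 3))
    assert float(infonce_loss(zeros, zeros, 1.0).data) == pytest.approx(np.log(2), abs=1e-6)
    # identity similarity matrix at tau=1 -> log(1 + e^-1)
    x_s = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert float(infonce_loss(x_s, x_s, 1.0).data) == pytest.approx(0.313262, abs=1e-6)


def test_loss_oracle_equivalence_random_batches():
    rng = np.random.default_rng(1)
    for _ in range(100):
        n = int(rng.integers(1, 9))
        d = int(rng.integers(2, 17))
        x_s = rng.normal(size=(n, d))
        x_c = rng.normal(size=(n, d))
        tau = float(rng.uniform(0.05, 2.0))
        assert float(jeffreys_alignment_loss(x_s, x_c).data) == pytest.approx(
            jeffreys_reference(x_s, x_c), abs=1e-6, rel=1e-5
        )
        assert float(infonce_loss(x_s, x_c, tau).data) == pytest.approx(
            infonce_reference(x_s, x_c, tau), abs=1e-6, rel=1e-5
        )


def test_infonce_expected_value_at_random_embeddings():
    """For i.i.d. embeddings the loss concentrates near ln N."""
    rng = np.random.default_rng(2)
    n, d = 128, 128
    losses = []
    for _ in range(3):
        x_s = rng.normal(size=(n, d)) / np.sqrt(d)
        x_c = rng.normal(size=(n, d)) / np.sqrt(d)
        losses.append(float(infonce_loss(x_s, x_c, 1.0).data))
    assert np.mean(losses) == pytest.approx(np.log(n), rel=0.15)


def test_infonce_invalid_temperature():
    x = np.zeros((2, 2))
    with pytest.raises(ValueError):
        infonce_loss(x, x, 0.0)


def test_stage1_loss_combination_linearity():
    rng = np.random.default_rng(3)
    x_s, x_c = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
    _, rep1 = stage1_loss(x_s, x_c, Stage1Config(lambda_weight=1.0))
    _, rep0 = stage1_loss(x_s, x_c, Stage1Config(lambda_weight=0.0))
    _, rep_half = stage1_loss(x_s, x_c, Stage1Config(lambda_weight=0.5))
    assert rep0.l_total == pytest.approx(rep0.l_kl, abs=1e-7)
    assert rep1.l_total - rep1.l_kl == pytest.approx(
        2 * (rep_half.l_total - rep_half.l_kl), rel=1e-5
    )


def test_jeffreys_rejects_nonfinite():
    x = np.zeros((2, 2))
    bad = x.copy()
    bad[0, 0] = np.inf
    with pytest.raises(ValueError):
        jeffreys_alignment_loss(bad, x)


def test_diagnostic_rows_match_loss():
    rng = np.random.default_rng(4)
    x_s, x_c = rng.normal(size=(5, 7)), rng.normal(size=(5, 7))
    rows = jeffreys_divergence_rows(x_s, x_c)
    assert rows.shape == (5,)
    assert rows.mean() / 2.0 == pytest.approx(
        float(jeffreys_alignment_loss(x_s, x_c).data), rel=1e-5
    )


def test_projection_head_shared_across_views():
    head = ProjectionHead(8, 16, 4, seed=0)
    rng = np.random.default_rng(5)
    h = rng.normal(size=(3, 8)).astype(np.float32)
    x1 = head(Tensor(h)).data
    x2 = head(Tensor(h)).data
    assert x1.shape == (3, 4)
    assert np.array_equal(x1, x2)       # same g for both views: h_s = h_c => x_s = x_c
    with pytest.raises(ValueError):
        head(Tensor(np.zeros((2, 5), dtype=np.float32)))
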