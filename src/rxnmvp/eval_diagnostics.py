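"""Regression metrics, pair-divergence CDF diagnostics, and histogram shift.

* Regression: MAE, RMSE (both in yield points) and R².
* Pair divergence: on held-out data, per-batch Jeffreys divergences between
  the two views' alignment-space distributions, separately for positive pairs
  (the same reaction's two views) and in-batch negative pairs. After stage-I
  training with the contrastive term active the negative-pair distribution
  should sit well to the right of the positive-pair distribution.
* Histogram shift: normalized intersection, (symmetric) chi-squared distance,
  and Jeffreys divergence between two yield samples binned on [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .chem_data import ReactionDataset
from .pretrain_align import Stage1Model, jeffreys_divergence_rows
from .tokenizer import Vocabulary, encode_reaction

__all__ = [
    "RegressionMetrics", "DivergenceCDF", "HistogramShift",
    "regression_metrics", "pair_divergence_distribution",
    "cross_view_retrieval_top1", "histogram_shift_metrics",
]


@dataclass(frozen=True)
class RegressionMetrics:
    mae: float
    rmse: float
    r2: float

    def as_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2}


def regression_metrics(y, y_hat) -> RegressionMetrics:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError(f"need equal nonzero-length inputs, got {y.shape} and {y_hat.shape}")
    if np.allclose(y, y[0]):
        raise ValueError("R^2 is undefined for constant truths")
    return RegressionMetrics(
        mae=float(mean_absolute_error(y, y_hat)),
        rmse=float(np.sqrt(mean_squared_error(y, y_hat))),
        r2=float(r2_score(y, y_hat)),
    )


@dataclass(frozen=True)
class DivergenceCDF:
    """Empirical CDFs of pair divergences for positive and negative pairs."""

    positive: np.ndarray        # sorted divergence values
    negative: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "positive", np.sort(np.asarray(self.positive, float)))
        object.__setattr__(self, "negative", np.sort(np.asarray(self.negative, float)))

    def cdf(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        values = getattr(self, which)
        fracs = np.arange(1, len(values) + 1) / len(values)
        return values, fracs

    @property
    def positive_median(self) -> float:
        return float(np.median(self.positive))

    @property
    def negative_median(self) -> float:
        return float(np.median(self.negative))


def _batched_projections(model: Stage1Model, dataset: ReactionDataset, vocab: Vocabulary,
                         batch_size: int, seed: int, max_len: int = 128):
    model.eval()
    records = list(dataset.records)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    for start in range(0, len(records) - 1, batch_size):
        chunk = [records[i] for i in order[start : start + batch_size]]
        if len(chunk) < 2:
            continue
        encoded = [encode_reaction(r, vocab, max_len) for r in chunk]
        x_s, x_c = model.project_views(chunk, encoded)
        yield x_s.data, x_c.data


def pair_divergence_distribution(
    dataset: ReactionDataset,
    model: Stage1Model,
    vocab: Vocabulary,
    batch_size: int = 32,
    seed: int = 0,
) -> DivergenceCDF:
    """Per-batch Jeffreys divergences for positive and all negative pairs."""
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2 to form negative pairs")
    pos, neg = [], []
    for x_s, x_c in _batched_projections(model, dataset, vocab, batch_size, seed):
        n = x_s.shape[0]
        pos.append(jeffreys_divergence_rows(x_s, x_c))
        for shift in range(1, n):
            neg.append(jeffreys_divergence_rows(x_s, np.roll(x_c, shift, axis=0)))
    if not pos:
        raise ValueError("dataset too small for a single batch")
    return DivergenceCDF(np.concatenate(pos), np.concatenate(neg))


def cross_view_retrieval_top1(
    dataset: ReactionDataset,
    model: Stage1Model,
    vocab: Vocabulary,
    batch_size: int = 32,
    seed: int = 0,
) -> float:
    """Fraction of reactions whose conformer view is the nearest (dot-product)
    alignment-space neighbor of their sequence view within a batch."""
    hits, total = 0, 0
    for x_s, x_c in _batched_projections(model, dataset, vocab, batch_size, seed):
        sim = x_s @ x_c.T
        hits += int((sim.argmax(axis=1) == np.arange(sim.shape[0])).sum())
        total += sim.shape[0]
    if total == 0:
        raise ValueError("dataset too small for a single batch")
    return hits / total


@dataclass(frozen=True)
class HistogramShift:
    intersection: float         # in [0, 1]; 1 for identical histograms
    chi_squared: float          # >= 0
    jeffreys: float             # >= 0
    bins: int


def histogram_shift_metrics(a, b, bins: int = 20, eps: float = 1e-10) -> HistogramShift:
    """Distribution-shift metrics between two yield samples on shared
    equal-width bins over [0, 100]."""
    if bins < 2:
        raise ValueError(f"need at least 2 bins, got {bins}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    edges = np.linspace(0.0, 100.0, bins + 1)
    p = np.histogram(a, bins=edges)[0].astype(float)
    q = np.histogram(b, bins=edges)[0].astype(float)
    p /= p.sum()
    q /= q.sum()
    intersection = float(np.minimum(p, q).sum())
    denom = p + q
    with np.errstate(invalid="ignore"):
        chi_terms = np.where(denom > 0, (p - q) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    chi_squared = float(chi_terms.sum())
    ps, qs = p + eps, q + eps
    jeffreys = float(((ps - qs) * (np.log(ps) - np.log(qs))).sum())
    return HistogramShift(intersection, chi_squared, jeffreys, bins)
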