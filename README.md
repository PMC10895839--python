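# rxnmvp

Multi-view representation learning for chemical reaction yield prediction.

Predicting the yield of an organic reaction — the percentage of theoretical
product actually obtained — is a regression problem over sets of molecules:
reactants, catalysts/solvents/additives (agents), and products. `rxnmvp`
models each reaction through two complementary views and learns to fuse
them:

* **sequence view** `h_s = Bi-GRU({h_t1, ..., h_tn})`: the reaction SMILES,
  tokenized at the character level (with ring-label, Cl/Br, and bracket-atom
  exceptions), embedded (256-d) and encoded by a two-layer bidirectional GRU
  (128-d per direction);
* **conformer view** `h_c = Bi-GRU({SchNet(C_1), ..., SchNet(C_n)})`: one 3D
  conformer per molecule, embedded by a SchNet network (4 continuous-filter
  convolution blocks, 64 Gaussian radial basis functions on [0, 10] Å,
  128-d features, mean atom readout) and aggregated across the reaction's
  molecules by a second bidirectional GRU. Only interatomic distances enter
  the computation, so `h_c` is invariant to rigid motions and atom order.

Training proceeds in two pre-training stages followed by fine-tuning:

1. **Stage I (self-supervised).** A shared projection head `g` maps both
   views into an alignment space, `x_s = g(h_s)`, `x_c = g(h_c)`. Each batch
   of N reactions is optimized with
   `L_I = L_KL + λ · L_InfoNCE`, where `L_KL` is the Jeffreys divergence
   (symmetrized KL) between softmax distributions of the two views of the
   same reaction, and `L_InfoNCE` is the symmetric InfoNCE contrastive loss
   over dot-product similarities at temperature τ with in-batch negatives.
   The alignment term pulls positive pairs together; the contrastive term is
   what prevents the degenerate solution where every reaction maps to the
   same distribution (observable here by setting λ = 0).
2. **Stage II (supervised).** A predictor `p` on the concatenation
   `h_s ⊕ h_c` is trained with squared error on yields normalized to [0, 1]:
   `L_II = Σ_i (y_i − p(h_s_i ⊕ h_c_i))²`.
3. **Fine-tuning.** End-to-end training on a downstream set, with a grid
   search over learning rate {3e-4, 1e-3, 3e-3}, dropout {0.1, 0.3}, weight
   decay {0, 1e-4, 1e-5}, and loss {squared, absolute error}.

The package also ships the full data-curation pipeline (reaction-SMILES
parsing and canonicalization, deduplication, ETKDG conformer generation with
per-reaction retention, yield-validity filtering with low-yield subsampling,
stratified 18:1:1 splits, and leak-free component-based out-of-sample
splits), evaluation metrics (MAE/RMSE/R², pair-divergence CDF diagnostics,
histogram distribution-shift metrics), and a seeded synthetic-reaction
generator with planted linear yield signal so everything runs at desk scale
with no downloads. The neural stack runs on a small NumPy reverse-mode
autodiff engine included in the package (`rxnmvp.nn`); no GPU or deep
learning framework is required.

## Worked example

```python
from rxnmvp import (SyntheticSpec, make_synthetic_dataset, stratified_split,
                    TrainConfig, train_yield_model, regression_metrics)
from rxnmvp.tokenizer import build_vocabulary, tokenize_smiles
from rxnmvp.yield_model import _predictions_raw
import numpy as np

data = make_synthetic_dataset(SyntheticSpec(n_reactions=600, noise_sigma=5.0, seed=1))
data = stratified_split(data, (18, 1, 1), n_bins=10, seed=1)
vocab = build_vocabulary(
    (tokenize_smiles(m.smiles) for r in data.records for m in r.molecules()), 1)

model, history = train_yield_model(data, vocab, TrainConfig(epochs=8, seed=0))
test = data.subset("test")
preds = np.clip(_predictions_raw(model, test.records, vocab, 128), 0, 100)
truth = np.array([r.yield_pct for r in test.records])
print(regression_metrics(truth, preds))
```

Output from this exact run:

```
RegressionMetrics(mae=7.5370058306913075, rmse=8.987890542956956, r2=0.7626520854605205)
```

The planted yield signal has a standard deviation of about 18 yield points
with 5 points of Gaussian noise, so an R² of 0.76 after eight epochs means
the two encoders have recovered most of the token-level structure the
generator planted; the MAE and RMSE are in yield percentage points.

The same pipeline is scriptable from the shell:

```bash
rxnmvp make-synthetic --n 600 --seed 1 --out data.csv
rxnmvp prep data.csv --ratio 18:1:1 --seed 1 --out curated.csv
rxnmvp build-vocab curated.csv --min-freq 1 --out vocab.txt
rxnmvp pretrain-align curated.csv --vocab vocab.txt --epochs 30 --out stage1.npz
rxnmvp pretrain-yield curated.csv --vocab vocab.txt --init stage1.npz --out model.npz
rxnmvp evaluate curated.csv --vocab vocab.txt --model model.npz
```

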