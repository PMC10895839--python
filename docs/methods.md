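# Methods

This note records the modeling choices, parameter defaults, numerical
details, and known limitations of `rxnmvp`.

## Problem setting

A reaction is a sample `(M_s, M_c, y)`: the same n molecules in sequence
form (SMILES strings) and conformer form (atoms with Cartesian coordinates
in Å), plus an optional yield percentage y ∈ (0, 100]. n varies per
reaction. The learning task is a mapping from the two views to y.

## Data model and curation

* **Canonical form.** Every molecule is canonicalized with RDKit; within
  each role (reactants, agents, products) molecules are sorted
  lexicographically by canonical SMILES. The duplicate key is the
  role-sorted canonical reaction string `reactants>agents>products`; yields
  are not part of the key. Among duplicates, a record carrying a yield wins
  over one without, else the first occurrence wins, and every drop is
  logged with a reason.
* **Valid yield** means numeric and in (0, 100]; zero, negative, > 100, and
  missing values are invalid and removed by the yield filter. An optional
  low-yield subsampling step keeps a seeded fraction of records with yield
  below a cutoff (default 50%), the mechanism used when augmenting a corpus
  whose yield distribution is biased toward high values.
* **Conformers.** One conformer per molecule, generated by ETKDG (v3) with
  default parameters; hydrogens are added for embedding and stripped
  afterwards. A reaction is retained only if every molecule embeds. The
  per-molecule embedding seed is derived by stable hashing from (global
  seed, canonical SMILES), so results do not depend on record order and
  identical molecules share identical conformers. Coordinates are stored
  rounded to 4 decimal places — the SDF text precision — so datasets
  round-trip bit-exactly through the SDF sidecar. Molecules are never
  re-centered; the encoders are distance-based and do not care.
* **Stratified split.** 18:1:1 train/valid/test by default over 10
  equal-width yield bins. Global sizes are fixed by largest-remainder
  rounding; within each bin the allocation follows the global ratio with
  floor + largest-remainder correction, so per-bin proportions deviate from
  the ratio by at most one record while global totals are exact.
* **Component-based splits** send every reaction containing a held-out
  component (in a given role, or anywhere) to the test set. Zero leakage is
  structural: membership is decided by scanning canonical SMILES, and a
  held-out SMILES absent from the data raises rather than silently produces
  an empty test set.

## Tokenization

Character-level with three exceptions: `%` plus two digits is one
ring-closure token; `Cl`/`Br` outside brackets are single tokens (a lone
aliphatic `l` or `r` is never an atom); inside brackets a maximal element
symbol is one token, which is what distinguishes the bracket caesium atom
`[cs]` from the two aromatic atoms `cs`. The bracket rule is the "element"
dialect (default); a strict "char" dialect splitting brackets per character
is available behind a flag. Four special tokens are reserved at fixed
indices: `[PAD]`=0 (length alignment), `[CLS]`=1 (sequence start), `[SEP]`=2
(molecule separator), `[UNK]`=3 (unknown or below the frequency floor,
default 10 occurrences). Reactions encode as `[CLS] m1 [SEP] m2 [SEP] ...`
over the canonical molecule order; a trailing `[SEP]` closes the last
molecule and no end-of-sequence token is used. Over-length sequences raise
rather than truncate silently. Vocabulary ordering is deterministic
(descending frequency, lexicographic ties), so identical corpora produce
byte-identical vocabulary files.

## Sequence encoder

Token embedding (256-d) → two-layer bidirectional GRU (128-d per direction,
dropout 0.3 on embeddings and between layers, disabled in eval mode).
Padded positions are masked out of the recurrence: the hidden state is
carried through them unchanged, which makes the representation invariant to
the amount of padding. The reaction representation h_s is the concatenation
of the last layer's final hidden states, forward direction first (256-d
total). Reading the final states was chosen over pooling the `[CLS]`
position because it is robust to where the informative tokens sit; `[CLS]`
is still embedded and consumed like any token. Input projections for all
timesteps are computed as one matrix product per layer and direction, which
is what makes CPU training practical.

## Conformer encoder

Per molecule, SchNet: atomic-number embedding (128-d) → K = 4 interaction
blocks → atom-wise two-layer output MLP → mean over atoms. Each interaction
block computes, for every ordered in-cutoff atom pair (u, v), a Gaussian
radial basis expansion of the distance, exp(−γ(d − μ_k)²) with 64 centers
μ_k evenly spaced on [0, 10] Å and γ = 10 Å⁻² (the standard value matched
to that center spacing; configurable); a filter-generating network (dense →
shifted softplus → dense) maps the expansion to a 128-d filter; neighbor
features are modulated elementwise and summed; an atom-wise MLP produces
the update. Blocks are residual by default (`e ← e + MLP(Σ ...)`), with a
non-residual literal form behind a flag. The per-pair filter-network
formulation was adopted because a scalar-Gaussian reading of the
convolution leaves the basis index dangling; the filter network is the
continuous-filter convolution as defined in the SchNet literature. Atom
input features default to the atomic-number embedding; a hook accepts
richer per-atom feature vectors.

Molecule embeddings are then aggregated by a second two-layer bidirectional
GRU (128-d, dropout 0.3, independent parameters from the sequence GRU) over
the reaction's molecule sequence in the canonical order shared with the
sequence view (reactants, agents, products; lexicographic within role —
fixed so that both views always describe the same ordering, since set
inputs have no natural order). h_c is again the concatenated final states
(256-d). Because only distances enter, h_c is invariant to rigid rotations
and translations, and because aggregations are sums/means, to atom
reordering; both are property-tested.

## Stage-I objectives

One shared projection head (256 → 256 → 128, single ReLU) maps both views
into the alignment space; a two-head variant is a config switch. Per batch
of N reactions:

* Alignment: `L_KL = (1/2N) Σ_i [KL(P_i‖Q_i) + KL(Q_i‖P_i)]` with
  `P_i = softmax(x_s_i)`, `Q_i = softmax(x_c_i)` over the d = 128 features,
  computed from log-softmax outputs for stability. This is the Jeffreys
  divergence between the per-sample feature distributions; it is symmetric,
  nonnegative, and zero iff the distributions coincide.
* Contrast: symmetric InfoNCE over raw dot-product similarities
  `s_ik = x_s_i · x_c_k / τ` with in-batch negatives, log-sum-exp
  stabilized. τ defaults to 0.1 and is exposed in config; an optional flag
  L2-normalizes embeddings before the similarity (off by default, matching
  the raw-dot-product objective). Negatives are strictly in-batch; there is
  no memory bank.
* Combined: `L_I = L_KL + λ · L_InfoNCE`, λ = 1.0 by default.

Setting λ = 0 collapses the alignment space — positive and negative pair
divergences both shrink toward zero — which is reproduced as a diagnostic
experiment. Training uses Adam with default parameters (lr 1e-3, β =
(0.9, 0.999)), a held-out validation fraction for best-checkpoint
selection, and a single seed controlling initialization, batching, and
dropout. The projector is kept in the checkpoint for diagnostics but is not
used by the downstream predictor (standard practice for projection heads).

## Stage II and fine-tuning

The predictor is a two-layer perceptron 512 → 256 → 1 with dropout, applied
to `h_s ⊕ h_c` (sequence first). Yields are normalized to [0, 1] for
optimization; every reported metric (MAE, RMSE in yield points, R²) is on
the 0–100 scale, and reported predictions are clipped to [0, 100]. The
objective is the sum of squared errors (absolute errors selectable for
fine-tuning). Training is end to end by default — encoders and predictor —
with encoder freezing as an option; stage-I checkpoints initialize the
encoders exactly (serialization is bit-preserving). A sequence-only
fallback predicts from h_s alone when conformers are unavailable.

Grid search covers learning rate {3e-4, 1e-3, 3e-3} × dropout {0.1, 0.3} ×
weight decay {0, 1e-4, 1e-5} × loss {squared, absolute} (36 cells). Each
cell trains on 90% of the training records and is scored by RMSE on the
held-out 10% (the selection protocol was an open choice; an internal
validation split is the least-surprising default), ties resolving to the
first cell in deterministic grid order; the winner is retrained on the full
training set.

## Synthetic data generator

The generator emulates the structure of curated reaction corpora: variable
molecule counts (2–6) across reactant/agent/product roles, valid SMILES
from a library of small organic fragments (alkanes, alcohols, halides,
carbonyls, simple aromatics) with optional methylene homologation, one
conformer per molecule, and yields in (0, 100]. Conformers come either from
ETKDG or from a deterministic rule-based helical layout (1.5 Å rise,
SMILES-derived phase) that is a pure function of the molecule — geometry
tests run without any embedding step and reproduce bit-identically.

Yields are planted as `y = clip(β · f + N(0, σ), 0.5, 100)` where f are
token-level features computed by the same tokenizer the sequence encoder
consumes: intercept, token count, halogen tokens, ring-closure digits,
heteroatom tokens, molecule count. The default β gives the signal a
standard deviation of about 18 yield points; with the default σ = 5 points
of noise the ordinary-least-squares fit on the true features — the analytic
ceiling no model can beat — sits above R² = 0.9, and about 1% of yields
touch the clip bounds. The floor of 0.5 keeps every label valid under the
(0, 100] rule. The feature definitions and coefficients are exported next
to the dataset so recovery experiments can verify identifiability (at σ = 0
an OLS fit recovers β to well under 5%).

What the generator does **not** emulate: chemical feasibility of the
reactions, realistic conformer geometry (the rule-based mode in
particular), tokenizer vocabularies at corpus scale (a few dozen tokens
versus low hundreds), and long-range yield dependence on reagent identity
beyond token counts. Passing tests therefore demonstrate that the machinery
optimizes, aligns, and recovers planted signal under controlled conditions
— not that the architecture reaches any particular accuracy on real
high-throughput experimentation data.

## Numerical choices

* The whole neural stack runs on a small reverse-mode autodiff engine over
  NumPy arrays (float32 for parameters and activations; float64 is
  preserved end to end when diagnostics feed float64 inputs through the
  losses). Log-softmax uses a detached max shift; softplus and its gradient
  use the stable `max(x,0) + log1p(exp(−|x|))` form.
* Scatter-add aggregation (`np.add.at`) is deterministic on CPU, so two
  identical seeded runs produce byte-identical metrics.
* Problem sizes for the verification experiments: stage-I behavior is
  measured on 200 reactions for 30 epochs at batch 32 (the batch size also
  used for pair-divergence diagnostics); yield recovery on 2000 reactions
  at σ = 5 for 12 epochs at batch 64; invariance sweeps on 20 molecules ×
  50 rigid motions. These sizes are the package's desk-scale defaults;
  larger corpora only change wall time.
* Degenerate inputs: empty agent lists are legal; a reaction needs at least
  one reactant, one product, and two molecules total; R² is refused for
  constant truths; InfoNCE needs N ≥ 2 for negatives (N = 1 gives exactly
  zero); isolated atoms inside the cutoff radius receive the MLP of the
  empty (zero) aggregate.

## Known limitations

* The tokenizer's bracket-element dialect resolves an ambiguity in
  character-level tokenization; corpus token counts are therefore
  vocabulary-dependent and not comparable across dialects.
* The GRU readout (final states) and the grid-search selection protocol are
  reasonable defaults for genuinely open design points; both are isolated
  behind config so alternatives can be tested.
* No uncertainty estimation, no ensembling, no 2D graph view, and no
  name-to-structure resolution (a pluggable hook exists for the latter).
* CPU-only by design; wall time scales linearly with corpus size, so
  million-reaction pre-training is out of scope for this implementation.
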