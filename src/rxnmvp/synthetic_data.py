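"""Seeded generator of synthetic reactions with both views and planted yields.

Molecules are drawn from a library of small organic fragments (alkanes,
alcohols, halides, carbonyls, simple aromatics), optionally homologated by
prepending methylene units, so every SMILES is valid by construction.
Reactions assemble 2-6 molecules into reactant/agent/product roles; chemical
feasibility is deliberately not modeled. Each molecule gets one conformer,
either from the ETKDG embedder or from a deterministic rule-based 3D layout
(a helical chain placement) that needs no embedding toolkit and exercises the
geometry code with exactly reproducible coordinates.

Yields are planted as a linear function of interpretable token-level features
(token count, halogen tokens, ring-closure digits, heteroatom tokens,
molecule count) plus Gaussian noise, clipped to [0.5, 100] so every label is
valid under the (0, 100] curation rule. Because the features are computed by
the same tokenizer the sequence encoder consumes, the signal is learnable by
construction, and an ordinary least-squares fit on the true features gives an
analytic ceiling for what any model can achieve at a given noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_data import Molecule, Reaction, ReactionDataset, canonical_smiles, etkdg_embedder
from .tokenizer import tokenize_smiles

__all__ = [
    "SyntheticSpec", "DEFAULT_FRAGMENTS", "DEFAULT_BETA", "FEATURE_NAMES",
    "rule_based_coords", "generate_synthetic_molecules",
    "assemble_synthetic_reactions", "plant_yield_labels",
    "reaction_features", "feature_matrix", "make_synthetic_dataset",
]

# small, always-valid organic fragments; chain-extendable ones may be
# homologated by prepending carbons
DEFAULT_FRAGMENTS = (
    "C", "CC", "CCC", "CCO", "CCN", "CC=O", "CC(C)O", "CC(=O)O", "CCOC",
    "CCCl", "CCBr", "CCI", "CC(F)F", "c1ccccc1", "Cc1ccccc1", "c1ccncc1",
    "c1ccsc1", "OCc1ccccc1", "CC(=O)N", "C1CCCCC1",
)

FEATURE_NAMES = (
    "intercept", "n_tokens", "n_halogen", "n_ring_digits", "n_hetero", "n_molecules",
)

# planted coefficients, calibrated so the signal standard deviation is about
# 18 yield points for reactions of 2-6 default fragments (comfortably above
# the default 5-point noise, with ~1% of yields touching the clip bounds)
DEFAULT_BETA = (45.0, 1.0, -9.0, 3.2, 4.3, -5.8)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic reaction dataset."""

    n_reactions: int = 200
    fragments: tuple[str, ...] = DEFAULT_FRAGMENTS
    mols_per_reaction: tuple[int, int] = (2, 6)
    beta: tuple[float, ...] = DEFAULT_BETA
    noise_sigma: float = 5.0       # yield points
    conformer_mode: str = "rule-based-3d"   # or "etkdg"
    max_homologation: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.conformer_mode not in ("rule-based-3d", "etkdg"):
            raise ValueError(f"unknown conformer mode {self.conformer_mode!r}")
        if len(self.beta) != len(FEATURE_NAMES):
            raise ValueError(f"beta must have {len(FEATURE_NAMES)} coefficients")
        lo, hi = self.mols_per_reaction
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid mols_per_reaction range {self.mols_per_reaction}")
        for frag in self.fragments:
            canonical_smiles(frag)   # raises on an invalid library entry


def rule_based_coords(mol_smiles: str, n_atoms: int) -> np.ndarray:
    """Deterministic idealized 3D layout: atoms on a helix with 1.5 Å rise.

    A pure function of the SMILES and atom count (a small SMILES-derived
    phase keeps different molecules from being congruent), so coordinates are
    bit-identical across runs with no embedding toolkit involved.
    """
    phase = (sum(ord(c) for c in mol_smiles) % 360) * np.pi / 180.0
    i = np.arange(n_atoms, dtype=np.float64)
    theta = 1.1 * i + phase
    coords = np.stack([1.3 * np.cos(theta), 1.3 * np.sin(theta), 1.5 * i], axis=1)
    return np.round(coords, 4)


def _attach_coords(mol: Molecule, mode: str, seed: int) -> Molecule:
    if mode == "rule-based-3d":
        coords = rule_based_coords(mol.smiles, len(mol.atoms))
    else:
        coords = etkdg_embedder(mol.smiles, seed)
        if coords is None:
            raise ValueError(f"ETKDG failed to embed {mol.smiles!r}")
        coords = np.round(coords, 4)
    return Molecule(mol.smiles, mol.atoms, coords)


def generate_synthetic_molecules(spec: SyntheticSpec, k: int,
                                 rng: np.random.Generator | None = None) -> list[Molecule]:
    """Sample k valid molecules from the fragment library with optional
    methylene homologation, coordinates attached per the conformer mode."""
    rng = rng or np.random.default_rng(spec.seed)
    out = []
    for _ in range(k):
        frag = spec.fragments[rng.integers(len(spec.fragments))]
        if not frag.startswith("c") and spec.max_homologation:
            frag = "C" * int(rng.integers(spec.max_homologation + 1)) + frag
        mol = Molecule.from_smiles(frag)
        out.append(_attach_coords(mol, spec.conformer_mode, seed=int(rng.integers(2**31))))
    return out


def assemble_synthetic_reactions(spec: SyntheticSpec) -> ReactionDataset:
    """Build n_reactions records with 2-6 molecules split across roles."""
    rng = np.random.default_rng(spec.seed)
    records = []
    lo, hi = spec.mols_per_reaction
    for i in range(spec.n_reactions):
        n = int(rng.integers(lo, hi + 1))
        n_products = 1 if n <= 3 else int(rng.integers(1, 3))
        n_agents = 0 if n - n_products < 2 else int(rng.integers(0, min(2, n - n_products - 1) + 1))
        n_reactants = n - n_products - n_agents
        mols = generate_synthetic_molecules(spec, n, rng)
        records.append(
            Reaction(
                reactants=tuple(mols[:n_reactants]),
                agents=tuple(mols[n_reactants : n_reactants + n_agents]),
                products=tuple(mols[n_reactants + n_agents :]),
                record_id=f"synth-{i:05d}",
            )
        )
    return ReactionDataset(records, None, provenance=f"synthetic(seed={spec.seed})")


_HALOGEN_TOKENS = {"F", "Cl", "Br", "I"}
_HETERO_TOKENS = {"O", "N", "S", "o", "n", "s"}


def reaction_features(r: Reaction) -> np.ndarray:
    """Token-level features over the canonical molecule order (the same
    token stream the sequence encoder sees)."""
    tokens: list[str] = []
    for mol in r.canonical_molecule_order():
        tokens.extend(tokenize_smiles(mol.smiles))
    n_tokens = len(tokens)
    n_halogen = sum(t in _HALOGEN_TOKENS for t in tokens)
    n_ring = sum(t.isdigit() or t.startswith("%") for t in tokens)
    n_hetero = sum(t in _HETERO_TOKENS for t in tokens)
    return np.array([1.0, n_tokens, n_halogen, n_ring, n_hetero, r.n_molecules])


def feature_matrix(d: ReactionDataset) -> pd.DataFrame:
    rows = [reaction_features(r) for r in d.records]
    return pd.DataFrame(rows, columns=FEATURE_NAMES,
                        index=[r.record_id for r in d.records])


def plant_yield_labels(d: ReactionDataset, spec: SyntheticSpec) -> ReactionDataset:
    """y = clip(beta . features + N(0, sigma), 0.5, 100), seeded."""
    rng = np.random.default_rng(spec.seed + 7919)
    beta = np.asarray(spec.beta)
    records = []
    for rec in d.records:
        signal = float(beta @ reaction_features(rec))
        y = signal + rng.normal(0.0, spec.noise_sigma) if spec.noise_sigma else signal
        records.append(
            Reaction(rec.reactants, rec.agents, rec.products,
                     yield_pct=float(np.clip(y, 0.5, 100.0)), record_id=rec.record_id)
        )
    return ReactionDataset(records, d.split_labels, d.provenance)


def make_synthetic_dataset(spec: SyntheticSpec) -> ReactionDataset:
    """Convenience: assemble reactions and plant yields in one call."""
    return plant_yield_labels(assemble_synthetic_reactions(spec), spec)
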