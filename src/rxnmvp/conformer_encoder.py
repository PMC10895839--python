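"""Conformer-view encoder: SchNet per molecule, Bi-GRU over the molecule sequence.

Each molecule's atoms are embedded from their atomic numbers and refined by K
continuous-filter convolution (cfconv) blocks: for every in-cutoff atom pair
the interatomic distance is expanded in Gaussian radial basis functions, a
filter-generating network maps the expansion to a feature-dim filter, neighbor
features are modulated elementwise and summed, and an atom-wise MLP updates
the features (with an optional residual connection, on by default). A final
atom-wise MLP and a mean readout give the molecule embedding; a bidirectional
GRU over the reaction's molecule sequence (canonical order, shared with the
sequence view) yields h_c.

Only interatomic distances enter the computation, so the representation is
invariant to rigid rotations/translations, and all aggregations are sums or
means, so it is invariant to atom reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .chem_data import Molecule, Reaction
from .nn import BiGRU, Embedding, Linear, Module, Tensor, concat

__all__ = ["SchNetConfig", "gaussian_rbf_expand", "SchNet", "ConformerEncoder",
           "ATOMIC_NUMBERS"]

# symbol -> atomic number for the organic subset plus common hetero elements
ATOMIC_NUMBERS = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11, "Mg": 12,
    "Si": 14, "P": 15, "S": 16, "Cl": 17, "K": 19, "Ca": 20, "Fe": 26,
    "Cu": 29, "Zn": 30, "Br": 35, "Pd": 46, "Sn": 50, "I": 53, "Cs": 55,
}


@dataclass(frozen=True)
class SchNetConfig:
    num_interactions: int = 4
    num_rbf: int = 64
    cutoff: float = 10.0           # Å; RBF span and neighbor threshold
    feature_dim: int = 128
    rbf_gamma: float = 10.0        # Å^-2
    residual: bool = True          # residual interaction blocks (literal form when False)

    def __post_init__(self):
        if self.num_interactions < 1 or self.cutoff <= 0 or self.rbf_gamma <= 0:
            raise ValueError("invalid SchNet configuration")

    @property
    def rbf_centers(self) -> np.ndarray:
        return np.linspace(0.0, self.cutoff, self.num_rbf)


def gaussian_rbf_expand(distance, cfg: SchNetConfig) -> np.ndarray:
    """Expand distances in Gaussians exp(-gamma (d - mu_k)^2) on [0, cutoff]."""
    d = np.asarray(distance, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    return np.exp(-cfg.rbf_gamma * (d[..., None] - cfg.rbf_centers) ** 2)


def neighbor_pairs(coords: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All ordered pairs (u, v), u != v, with ||r_u - r_v|| <= cutoff."""
    m = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    mask = (dist <= cutoff) & ~np.eye(m, dtype=bool)
    u, v = np.nonzero(mask)
    return u, v, dist[u, v]


class _Interaction(Module):
    """One cfconv block: filter network on the RBF expansion, elementwise
    modulation of neighbor features, sum over neighbors, atom-wise MLP."""

    def __init__(self, cfg: SchNetConfig, rng: np.random.Generator):
        super().__init__()
        self.filter1 = Linear(cfg.num_rbf, cfg.feature_dim, rng)
        self.filter2 = Linear(cfg.feature_dim, cfg.feature_dim, rng)
        self.dense1 = Linear(cfg.feature_dim, cfg.feature_dim, rng)
        self.dense2 = Linear(cfg.feature_dim, cfg.feature_dim, rng)
        self.residual = cfg.residual

    def __call__(self, feats: Tensor, rbf: np.ndarray, u: np.ndarray, v: np.ndarray) -> Tensor:
        filt = self.filter2(self.filter1(Tensor(rbf)).softplus())
        if len(u):
            messages = feats.gather_rows(v) * filt
            agg = messages.scatter_add_rows(u, feats.shape[0])
        else:  # isolated atoms: the empty sum
            agg = Tensor(np.zeros_like(feats.data))
        out = self.dense2(self.dense1(agg).softplus())
        return feats + out if self.residual else out


class SchNet(Module):
    """Per-molecule embedding network; operates on a flat atom batch with a
    molecule index so one call embeds every molecule in a reaction batch."""

    def __init__(self, cfg: SchNetConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.atom_embedding = Embedding(max(ATOMIC_NUMBERS.values()) + 1, cfg.feature_dim, rng)
        self.interactions = [_Interaction(cfg, rng) for _ in range(cfg.num_interactions)]
        self.out1 = Linear(cfg.feature_dim, cfg.feature_dim, rng)
        self.out2 = Linear(cfg.feature_dim, cfg.feature_dim, rng)

    @staticmethod
    def atomic_numbers(mol: Molecule) -> np.ndarray:
        try:
            return np.array([ATOMIC_NUMBERS[s] for s in mol.atoms], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"unsupported element {exc.args[0]!r} in {mol.smiles!r}") from None

    def embed_atoms(self, z: np.ndarray, coords: np.ndarray,
                    mol_index: np.ndarray, n_mols: int) -> Tensor:
        """Embed a flat atom batch -> (n_mols, feature_dim) molecule embeddings."""
        feats = self.atom_embedding(z)
        # neighbor pairs within each molecule only
        us, vs, ds = [], [], []
        offset = 0
        for m in range(n_mols):
            sel = np.flatnonzero(mol_index == m)
            u, v, dist = neighbor_pairs(coords[sel], self.cfg.cutoff)
            us.append(sel[u])
            vs.append(sel[v])
            ds.append(dist)
        u = np.concatenate(us) if us else np.array([], dtype=np.intp)
        v = np.concatenate(vs) if vs else np.array([], dtype=np.intp)
        d = np.concatenate(ds) if ds else np.array([])
        rbf = gaussian_rbf_expand(d, self.cfg).astype(np.float32)
        for block in self.interactions:
            feats = block(feats, rbf, u, v)
        feats = self.out2(self.out1(feats).softplus())
        counts = np.bincount(mol_index, minlength=n_mols).astype(np.float32)
        summed = feats.scatter_add_rows(mol_index, n_mols)
        return summed * Tensor(1.0 / counts[:, None])

    def embed_molecule(self, mol: Molecule) -> Tensor:
        """Embed a single molecule with coordinates -> (feature_dim,) vector."""
        if mol.coords is None:
            raise ValueError(f"molecule {mol.smiles!r} has no conformer")
        z = self.atomic_numbers(mol)
        out = self.embed_atoms(z, np.asarray(mol.coords), np.zeros(len(z), dtype=np.intp), 1)
        return out[0]


class ConformerEncoder(Module):
    """Reaction-level conformer encoder: SchNet + Bi-GRU over molecules."""

    def __init__(self, cfg: SchNetConfig, seed: int = 0, gru_hidden: int = 128,
                 gru_layers: int = 2, gru_dropout: float = 0.3):
        super().__init__()
        self.cfg = cfg
        self.gru_hidden = gru_hidden
        rng = np.random.default_rng(_mix(seed, 1))
        self.schnet = SchNet(cfg, seed=_mix(seed, 2))
        self.gru = BiGRU(cfg.feature_dim, gru_hidden, gru_layers, rng, dropout=gru_dropout)

    @property
    def output_dim(self) -> int:
        return 2 * self.gru_hidden

    def __call__(self, reactions: list[Reaction]) -> Tensor:
        """Encode a batch of reactions with conformers -> (B, 2*gru_hidden) h_c."""
        z_list, coord_list, mol_of_atom = [], [], []
        seq_index: list[list[int]] = []
        mol_counter = 0
        for rec in reactions:
            mols = rec.canonical_molecule_order()
            row = []
            for m in mols:
                if m.coords is None:
                    raise ValueError(f"record {rec.record_id!r}: molecule {m.smiles!r} "
                                     "has no conformer")
                z = self.schnet.atomic_numbers(m)
                z_list.append(z)
                coord_list.append(np.asarray(m.coords))
                mol_of_atom.append(np.full(len(z), mol_counter, dtype=np.intp))
                row.append(mol_counter)
                mol_counter += 1
            seq_index.append(row)
        z = np.concatenate(z_list)
        coords = np.concatenate(coord_list)
        mol_index = np.concatenate(mol_of_atom)
        mol_emb = self.schnet.embed_atoms(z, coords, mol_index, mol_counter)

        B = len(reactions)
        lengths = np.array([len(row) for row in seq_index], dtype=np.int64)
        T = int(lengths.max())
        # pad with an all-zero dummy row at index mol_counter
        padded = concat([mol_emb, Tensor(np.zeros((1, mol_emb.shape[1]), dtype=np.float32))])
        gather_idx = np.full((T, B), mol_counter, dtype=np.intp)
        for b, row in enumerate(seq_index):
            gather_idx[: len(row), b] = row
        x = padded.gather_rows(gather_idx.reshape(-1)).reshape(T, B, mol_emb.shape[1])
        return self.gru(x, lengths)

    def config_dict(self) -> dict:
        d = asdict(self.cfg)
        d.update(gru_hidden=self.gru_hidden)
        return d


def _mix(seed: int, salt: int) -> int:
    return (seed * 1_000_003 + salt) % (2**31)
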