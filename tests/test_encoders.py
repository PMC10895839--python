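"""Sequence and conformer encoders: shapes, determinism, geometric invariance,
and a brute-force oracle for the continuous-filter convolution."""

import numpy as np
import pytest

from rxnmvp.chem_data import Molecule, parse_reaction_smiles, ReactionDataset, attach_conformers
from rxnmvp.conformer_encoder import (
    ConformerEncoder, SchNet, SchNetConfig, gaussian_rbf_expand, neighbor_pairs,
)
from rxnmvp.nn import Tensor
from rxnmvp.sequence_encoder import SeqEncoderConfig, SequenceEncoder
from rxnmvp.synthetic_data import rule_based_coords
from rxnmvp.tokenizer import build_vocabulary, encode_reaction, tokenize_smiles


def random_rotation(rng):
    """Uniform rotation from the QR decomposition of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def with_coords(mol_smiles):
    mol = Molecule.from_smiles(mol_smiles)
    return Molecule(mol.smiles, mol.atoms, rule_based_coords(mol.smiles, len(mol.atoms)))


# -- sequence encoder -------------------------------------------------------

@pytest.fixture(scope="module")
def seq_setup():
    reactions = [
        parse_reaction_smiles("CCO.CCN>>CCOC", record_id="a"),
        parse_reaction_smiles("CCBr>>CCO", record_id="b"),
        parse_reaction_smiles("c1ccccc1.CC=O>O>CC(C)O", record_id="c"),
    ]
    vocab = build_vocabulary(
        (tokenize_smiles(m.smiles) for r in reactions for m in r.molecules()), 1
    )
    encoder = SequenceEncoder(SeqEncoderConfig(vocab_size=len(vocab)), seed=2)
    encoder.eval()
    return reactions, vocab, encoder


def test_sequence_output_dim_and_determinism(seq_setup):
    reactions, vocab, encoder = seq_setup
    enc = [encode_reaction(r, vocab, 64) for r in reactions]
    out1 = encoder(enc).data
    out2 = encoder(enc).data
    assert out1.shape == (3, 256)
    assert np.array_equal(out1, out2)


def test_sequence_padding_invariance(seq_setup):
    reactions, vocab, encoder = seq_setup
    short = [encode_reaction(r, vocab, 40) for r in reactions]
    long = [encode_reaction(r, vocab, 90) for r in reactions]
    assert np.allclose(encoder(short).data, encoder(long).data, atol=1e-6)


def test_sequence_rejects_out_of_range_indices(seq_setup):
    reactions, vocab, encoder = seq_setup
    small = SequenceEncoder(SeqEncoderConfig(vocab_size=4), seed=0)
    enc = [encode_reaction(r, vocab, 64) for r in reactions]
    with pytest.raises(ValueError):
        small(enc)


# -- RBF expansion ----------------------------------------------------------

def test_rbf_closed_form():
    cfg = SchNetConfig()
    centers = cfg.rbf_centers
    out = gaussian_rbf_expand(centers[5], cfg)
    assert out.shape == (64,)
    assert np.isclose(out[5], 1.0)
    delta = 0.3
    out2 = gaussian_rbf_expand(centers[5] + delta, cfg)
    assert np.isclose(out2[5], np.exp(-cfg.rbf_gamma * delta**2))
    # mathematically in (0, 1]; distant centers may underflow to exactly 0
    assert np.all((out >= 0) & (out <= 1))
    with pytest.raises(ValueError):
        gaussian_rbf_expand(-0.1, cfg)


# -- SchNet oracle ----------------------------------------------------------

def brute_force_interaction(block, feats, coords, cfg):
    """Per-pair double loop reference for one cfconv block."""
    m = feats.shape[0]
    agg = np.zeros_like(feats)
    for u in range(m):
        for v in range(m):
            if u == v:
                continue
            d = np.linalg.norm(coords[u] - coords[v])
            if d > cfg.cutoff:
                continue
            rbf = gaussian_rbf_expand(d, cfg).astype(np.float32)
            h = rbf @ block.filter1.weight.data + block.filter1.bias.data
            h = np.logaddexp(0, h)  # softplus
            filt = h @ block.filter2.weight.data + block.filter2.bias.data
            agg[u] += feats[v] * filt
    h = agg @ block.dense1.weight.data + block.dense1.bias.data
    h = np.logaddexp(0, h)
    out = h @ block.dense2.weight.data + block.dense2.bias.data
    return feats + out if block.residual else out


@pytest.mark.parametrize("n_atoms", [2, 5, 8])
def test_interaction_matches_brute_force(n_atoms):
    cfg = SchNetConfig(feature_dim=16, num_rbf=8, cutoff=6.0)
    net = SchNet(cfg, seed=4)
    block = net.interactions[0]
    rng = np.random.default_rng(n_atoms)
    feats = rng.normal(size=(n_atoms, 16)).astype(np.float32)
    coords = rng.uniform(0, 4, size=(n_atoms, 3))
    u, v, d = neighbor_pairs(coords, cfg.cutoff)
    rbf = gaussian_rbf_expand(d, cfg).astype(np.float32)
    fast = block(Tensor(feats), rbf, u, v).data
    slow = brute_force_interaction(block, feats, coords, cfg)
    assert np.allclose(fast, slow, atol=1e-5)


def test_isolated_atom_update_is_mlp_of_zero():
    cfg = SchNetConfig(feature_dim=8, num_rbf=4)
    net = SchNet(cfg, seed=1)
    block = net.interactions[0]
    feats = np.ones((1, 8), dtype=np.float32)
    out = block(Tensor(feats), np.zeros((0, 4), dtype=np.float32),
                np.array([], dtype=np.intp), np.array([], dtype=np.intp)).data
    expected = brute_force_interaction(block, feats, np.zeros((1, 3)), cfg)
    assert np.allclose(out, expected, atol=1e-6)


# -- invariances ------------------------------------------------------------

def test_molecule_embedding_se3_invariance(mol_pool):
    net = SchNet(SchNetConfig(), seed=7)
    net.eval()
    rng = np.random.default_rng(0)
    for mol in mol_pool[:6]:
        base = net.embed_molecule(mol).data
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.uniform(-20, 20, 3)
            moved = Molecule(mol.smiles, mol.atoms, mol.coords @ R.T + t)
            out = net.embed_molecule(moved).data
            assert np.allclose(out, base, rtol=1e-4, atol=1e-5)


def test_molecule_embedding_permutation_invariance(mol_pool):
    net = SchNet(SchNetConfig(), seed=7)
    rng = np.random.default_rng(1)
    for mol in mol_pool[:6]:
        base = net.embed_molecule(mol).data
        perm = rng.permutation(len(mol.atoms))
        permuted = Molecule(mol.smiles, tuple(mol.atoms[i] for i in perm),
                            mol.coords[perm])
        assert np.allclose(net.embed_molecule(permuted).data, base, rtol=1e-4, atol=1e-5)


def test_single_atom_molecule_depends_only_on_element():
    net = SchNet(SchNetConfig(), seed=3)
    a = Molecule("C", ("C",), np.array([[0.0, 0.0, 0.0]]))
    b = Molecule("C", ("C",), np.array([[5.0, -2.0, 1.0]]))
    assert np.array_equal(net.embed_molecule(a).data, net.embed_molecule(b).data)


def test_embedding_continuity_under_small_perturbation(mol_pool):
    net = SchNet(SchNetConfig(), seed=9)
    mol = mol_pool[0]
    base = net.embed_molecule(mol).data
    eps = 1e-3
    coords = mol.coords.copy()
    coords[0, 0] += eps
    out = net.embed_molecule(Molecule(mol.smiles, mol.atoms, coords)).data
    # O(eps) change: bounded by a generous Lipschitz constant
    assert np.linalg.norm(out - base) < 1e3 * eps


def test_conformer_encoder_rigid_motion_invariance():
    reactions = [parse_reaction_smiles("CCO.CCN>>CCOC", record_id="a")]
    d, _ = attach_conformers(ReactionDataset(reactions), seed=2)
    enc = ConformerEncoder(SchNetConfig(), seed=5)
    enc.eval()
    base = enc(d.records).data
    assert base.shape == (1, 256)
    rng = np.random.default_rng(3)
    R, t = random_rotation(rng), rng.uniform(-10, 10, 3)
    moved = []
    for rec in d.records:
        roles = []
        for role in (rec.reactants, rec.agents, rec.products):
            roles.append(tuple(
                Molecule(m.smiles, m.atoms, m.coords @ R.T + t) for m in role
            ))
        from dataclasses import replace
        moved.append(replace(rec, reactants=roles[0], agents=roles[1], products=roles[2]))
    out = enc(moved).data
    assert np.allclose(out, base, rtol=1e-4, atol=1e-5)


def test_conformer_encoder_single_molecule_reaction():
    # degenerate molecule sequence of length 2 (the minimum reaction)
    r = parse_reaction_smiles("CCO>>CC=O", record_id="a")
    d, _ = attach_conformers(ReactionDataset([r]), seed=2)
    enc = ConformerEncoder(SchNetConfig(), seed=5)
    enc.eval()
    out = enc(d.records).data
    assert out.shape == (1, 256) and np.all(np.isfinite(out))


def test_conformer_encoder_missing_coords_errors():
    r = parse_reaction_smiles("CCO>>CC=O", record_id="nocoords")
    enc = ConformerEncoder(SchNetConfig(), seed=5)
    with pytest.raises(ValueError, match="nocoords"):
        enc([r])


def test_pool_bigru_states_concatenation_contract():
    from rxnmvp.sequence_encoder import pool_bigru_states

    u = np.arange(6, dtype=np.float32).reshape(2, 3)
    v = -u
    out = pool_bigru_states(u, v).data
    assert out.shape == (2, 6)
    assert np.array_equal(out[:, :3], u) and np.array_equal(out[:, 3:], v)
    # linearity and the zero case
    assert np.array_equal(pool_bigru_states(2 * u, 2 * v).data, 2 * out)
    zeros = np.zeros((1, 4), dtype=np.float32)
    assert not pool_bigru_states(zeros, zeros).data.any()
    with pytest.raises(ValueError):
        pool_bigru_states(u, np.zeros((2, 4), dtype=np.float32))
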