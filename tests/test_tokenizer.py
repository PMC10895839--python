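"""Tokenizer: segmentation rules, vocabulary, and encode/decode round trips."""

import numpy as np
import pytest

from rxnmvp.chem_data import parse_reaction_smiles
from rxnmvp.synthetic_data import SyntheticSpec, generate_synthetic_molecules
from rxnmvp.tokenizer import (
    CLS, PAD, SEP, UNK, EncodingError, TokenizationError, VocabularyError,
    Vocabulary, build_vocabulary, decode_tokens, encode_reaction, tokenize_smiles,
)


@pytest.mark.parametrize("smiles,expected", [
    ("C%12CC%12", ["C", "%12", "C", "C", "%12"]),
    ("ClCCBr", ["Cl", "C", "C", "Br"]),
    ("c1[cs]cc1", ["c", "1", "[", "cs", "]", "c", "c", "1"]),
    ("cscc", ["c", "s", "c", "c"]),
    ("[Na+].[Cl-]", ["[", "Na", "+", "]", ".", "[", "Cl", "-", "]"]),
    ("C[C@H](N)C(=O)O", ["C", "[", "C", "@", "H", "]", "(", "N", ")",
                         "C", "(", "=", "O", ")", "O"]),
    ("[13CH4]", ["[", "1", "3", "C", "H", "4", "]"]),
    ("[se]1ccc1", ["[", "se", "]", "1", "c", "c", "c", "1"]),
])
def test_segmentation_rules(smiles, expected):
    assert tokenize_smiles(smiles) == expected


def test_char_dialect_splits_bracket_atoms():
    assert tokenize_smiles("[cs]", dialect="char") == ["[", "c", "s", "]"]
    # ring-label and Cl/Br rules hold in both dialects
    assert tokenize_smiles("ClC%11", dialect="char") == ["Cl", "C", "%11"]


@pytest.mark.parametrize("bad", ["C[C", "C]C", "C%1C"])
def test_malformed_strings_raise(bad):
    with pytest.raises(TokenizationError):
        tokenize_smiles(bad)


def test_lossless_segmentation_over_synthetic_corpus():
    """Joining the tokens reproduces the SMILES for >= 1000 generated molecules."""
    rng = np.random.default_rng(42)
    spec = SyntheticSpec(seed=42)
    mols = generate_synthetic_molecules(spec, 1000, rng)
    for mol in mols:
        assert "".join(tokenize_smiles(mol.smiles)) == mol.smiles


def test_vocabulary_frequency_floor_and_order():
    corpus = [["C"] * 100, ["O"] * 100, ["N"] * 9]
    vocab = build_vocabulary(corpus, min_frequency=10)
    assert len(vocab) == 6  # 4 specials + C + O
    assert "N" not in vocab
    assert vocab.index("N") == vocab.token_to_index[UNK]
    assert [vocab.token_to_index[t] for t in (PAD, CLS, SEP, UNK)] == [0, 1, 2, 3]
    # determinism: same corpus twice gives identical mappings
    assert build_vocabulary(corpus, min_frequency=10).token_to_index == vocab.token_to_index


def test_vocabulary_rejects_bad_min_frequency():
    with pytest.raises(VocabularyError):
        build_vocabulary([["C"]], min_frequency=0)


def test_vocabulary_file_round_trip(tmp_path):
    corpus = [tokenize_smiles(s) for s in ("CCO", "CCBr", "c1ccccc1")]
    vocab = build_vocabulary(corpus, min_frequency=1)
    path = tmp_path / "vocab.txt"
    vocab.save(path)
    loaded = Vocabulary.load(path)
    assert loaded.token_to_index == vocab.token_to_index
    assert loaded.content_hash() == vocab.content_hash()
    # byte-identical file from a rebuilt vocabulary
    vocab2 = build_vocabulary(corpus, min_frequency=1)
    path2 = tmp_path / "vocab2.txt"
    vocab2.save(path2)
    assert path.read_bytes() == path2.read_bytes()


def test_encode_layout_and_round_trip():
    r = parse_reaction_smiles("CCO.CCBr>O>CCOC", record_id="x")
    corpus = [tokenize_smiles(m.smiles) for m in r.molecules()]
    vocab = build_vocabulary(corpus, min_frequency=1)
    enc = encode_reaction(r, vocab, max_len=32)
    toks = [vocab.index_to_token[i] for i in enc.indices]
    assert toks[0] == CLS
    assert toks[enc.length - 1] == SEP
    assert all(t == PAD for t in toks[enc.length:])
    mols, lossy = decode_tokens(enc, vocab)
    assert not lossy
    assert mols == [m.smiles for m in r.canonical_molecule_order()]


def test_unknown_token_encodes_as_unk_and_flags_lossy():
    r = parse_reaction_smiles("CCO>>CCI", record_id="x")
    vocab = build_vocabulary([tokenize_smiles("CCO")], min_frequency=1)
    enc = encode_reaction(r, vocab, max_len=16)
    assert vocab.token_to_index[UNK] in enc.indices
    _, lossy = decode_tokens(enc, vocab)
    assert lossy


def test_over_length_sequence_raises_with_record_id():
    r = parse_reaction_smiles("CCCCCCCCCC>>CCCCCCCCCC", record_id="long-1")
    vocab = build_vocabulary([tokenize_smiles("C" * 10)], min_frequency=1)
    with pytest.raises(EncodingError, match="long-1"):
        encode_reaction(r, vocab, max_len=8)


# hypothesis property: any string assembled from plausible SMILES pieces
# (balanced brackets, well-formed ring labels) re-joins losslessly
from hypothesis import given, settings, strategies as st

_PIECES = st.sampled_from(
    ["C", "c", "N", "n", "O", "o", "s", "S", "P", "F", "I", "Cl", "Br",
     "(", ")", "=", "#", "-", "+", ".", "1", "2", "9", "%10", "%99",
     "[Na+]", "[nH]", "[cs]", "[se]", "[13C]", "[C@@H]", "[O-]"]
)


@settings(max_examples=200, derandomize=True)
@given(st.lists(_PIECES, min_size=1, max_size=30))
def test_lossless_segmentation_property(pieces):
    s = "".join(pieces)
    assert "".join(tokenize_smiles(s)) == s
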