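"""Character-level SMILES tokenization, vocabulary building, and reaction encoding.

Tokenization is character level with three exceptions:

* ``%`` followed by two digits (a two-digit ring-closure label) is one token;
* ``Cl`` and ``Br`` outside brackets are single tokens, since a lone aliphatic
  ``l`` or ``r`` is never a valid atom;
* inside ``[...]`` a maximal element symbol is one token, so the caesium atom
  ``[cs]`` tokenizes as ``[ cs ]`` while the aromatic carbon-sulfur fragment
  ``cs`` outside brackets stays two tokens.

Reactions are encoded as ``[CLS] mol1 [SEP] mol2 [SEP] ...`` over the canonical
molecule order shared with the conformer view, padded with ``[PAD]``; tokens
below the vocabulary's frequency floor encode as ``[UNK]``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .chem_data import Reaction

__all__ = [
    "PAD", "CLS", "SEP", "UNK", "SPECIAL_TOKENS",
    "TokenizationError", "VocabularyError", "EncodingError",
    "Vocabulary", "EncodedReaction",
    "tokenize_smiles", "build_vocabulary", "encode_reaction", "decode_tokens",
]

PAD, CLS, SEP, UNK = "[PAD]", "[CLS]", "[SEP]", "[UNK]"
SPECIAL_TOKENS = (PAD, CLS, SEP, UNK)

# two-character element symbols (IUPAC), used to recognize bracket atoms
_TWO_LETTER_ELEMENTS = {
    "He", "Li", "Be", "Ne", "Na", "Mg", "Al", "Si", "Cl", "Ar", "Ca", "Sc",
    "Ti", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se",
    "Br", "Kr", "Rb", "Sr", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag",
    "Cd", "In", "Sn", "Sb", "Te", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf",
    "Ta", "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At",
    "Rn", "Fr", "Ra", "Ac", "Th", "Pa", "Np", "Pu", "Am", "Cm", "Bk", "Cf",
    "Es", "Fm", "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
}
# lowercase two-letter symbols that may appear as aromatic bracket atoms
_TWO_LETTER_LOWER = {s.lower() for s in _TWO_LETTER_ELEMENTS}


class TokenizationError(ValueError):
    pass


class VocabularyError(ValueError):
    pass


class EncodingError(ValueError):
    pass


def tokenize_smiles(s: str, dialect: str = "element") -> list[str]:
    """Segment a SMILES string into tokens; joining the tokens restores ``s``.

    dialect "element" applies the bracket-atom exception; "char" splits
    strictly by character inside brackets (ring-label and Cl/Br rules apply
    in both dialects).
    """
    if not s:
        raise TokenizationError("empty SMILES string")
    if dialect not in ("element", "char"):
        raise TokenizationError(f"unknown tokenizer dialect {dialect!r}")
    tokens: list[str] = []
    i, n = 0, len(s)
    depth = 0
    while i < n:
        c = s[i]
        if c == "[":
            depth += 1
            tokens.append(c)
            i += 1
        elif c == "]":
            depth -= 1
            if depth < 0:
                raise TokenizationError(f"unbalanced ']' at position {i} in {s!r}")
            tokens.append(c)
            i += 1
        elif c == "%" and depth == 0:
            if i + 2 >= n or not (s[i + 1].isdigit() and s[i + 2].isdigit()):
                raise TokenizationError(f"'%' not followed by two digits at position {i} in {s!r}")
            tokens.append(s[i : i + 3])
            i += 3
        elif depth == 0 and c in "CB" and i + 1 < n and s[i : i + 2] in ("Cl", "Br"):
            tokens.append(s[i : i + 2])
            i += 2
        elif depth > 0 and dialect == "element" and c.isalpha():
            pair = s[i : i + 2]
            if c.isupper() and pair in _TWO_LETTER_ELEMENTS:
                tokens.append(pair)
                i += 2
            elif c.islower() and pair in _TWO_LETTER_LOWER:
                tokens.append(pair)
                i += 2
            else:
                tokens.append(c)
                i += 1
        else:
            tokens.append(c)
            i += 1
    if depth != 0:
        raise TokenizationError(f"unbalanced '[' in {s!r}")
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Token-to-index map with reserved specials and a frequency floor."""

    token_to_index: dict[str, int]
    min_frequency: int
    dialect: str = "element"

    def __post_init__(self):
        for i, tok in enumerate(SPECIAL_TOKENS):
            if self.token_to_index.get(tok) != i:
                raise VocabularyError(f"special token {tok} must have index {i}")
        indices = sorted(self.token_to_index.values())
        if indices != list(range(len(indices))):
            raise VocabularyError("vocabulary indices must be dense from 0")

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, self.token_to_index[UNK])

    @property
    def index_to_token(self) -> list[str]:
        out = [""] * len(self.token_to_index)
        for tok, i in self.token_to_index.items():
            out[i] = tok
        return out

    def save(self, path: str | Path) -> None:
        header = json.dumps({"min_frequency": self.min_frequency, "dialect": self.dialect})
        lines = [f"#{header}"] + self.index_to_token
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("#"):
            raise VocabularyError(f"missing vocabulary header in {path}")
        meta = json.loads(lines[0][1:])
        mapping = {tok: i for i, tok in enumerate(lines[1:])}
        return cls(mapping, meta["min_frequency"], meta.get("dialect", "element"))

    def content_hash(self) -> str:
        import hashlib

        payload = json.dumps(
            [self.index_to_token, self.min_frequency, self.dialect], sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def build_vocabulary(corpus: Iterable[Sequence[str]], min_frequency: int = 10,
                     dialect: str = "element") -> Vocabulary:
    """Build a vocabulary from tokenized strings, dropping rare tokens.

    Ordering is deterministic: specials first, then descending frequency with
    lexicographic tie-break.
    """
    if min_frequency < 1:
        raise VocabularyError(f"min_frequency must be >= 1, got {min_frequency}")
    counts: Counter[str] = Counter()
    empty = True
    for tokens in corpus:
        empty = False
        counts.update(tokens)
    if empty:
        raise VocabularyError("empty corpus")
    kept = sorted(
        (tok for tok, c in counts.items() if c >= min_frequency),
        key=lambda tok: (-counts[tok], tok),
    )
    mapping = {tok: i for i, tok in enumerate(SPECIAL_TOKENS)}
    for tok in kept:
        mapping[tok] = len(mapping)
    return Vocabulary(mapping, min_frequency, dialect)


@dataclass(frozen=True)
class EncodedReaction:
    """Padded token-index sequence plus its true length."""

    indices: tuple[int, ...]
    length: int
    record_id: str = ""

    def __post_init__(self):
        if self.length < 1 or self.length > len(self.indices):
            raise EncodingError("invalid true length")


def encode_reaction(r: Reaction, vocab: Vocabulary, max_len: int = 256) -> EncodedReaction:
    """Encode a reaction as [CLS] mol1 [SEP] mol2 [SEP] ... padded to max_len.

    Molecules follow the canonical order shared with the conformer view
    (reactants, agents, products; lexicographic within each role). Sequences
    longer than max_len raise rather than silently truncate.
    """
    tokens: list[str] = [CLS]
    for mol in r.canonical_molecule_order():
        tokens.extend(tokenize_smiles(mol.smiles, dialect=vocab.dialect))
        tokens.append(SEP)
    if len(tokens) > max_len:
        raise EncodingError(
            f"record {r.record_id!r}: encoded length {len(tokens)} exceeds max_len {max_len}"
        )
    indices = [vocab.index(t) for t in tokens]
    length = len(indices)
    indices.extend([vocab.index(PAD)] * (max_len - length))
    return EncodedReaction(tuple(indices), length, r.record_id)


def decode_tokens(e: EncodedReaction, vocab: Vocabulary) -> tuple[list[str], bool]:
    """Invert encode_reaction: per-molecule SMILES strings and a lossy flag.

    The flag is True when the sequence contains [UNK] (the original characters
    are unrecoverable).
    """
    table = vocab.index_to_token
    size = len(table)
    mols: list[str] = []
    current: list[str] = []
    lossy = False
    for idx in e.indices[: e.length]:
        if idx < 0 or idx >= size:
            raise EncodingError(f"token index {idx} out of range for vocabulary of size {size}")
        tok = table[idx]
        if tok == CLS or tok == PAD:
            continue
        if tok == SEP:
            mols.append("".join(current))
            current = []
            continue
        if tok == UNK:
            lossy = True
        current.append(tok)
    if current:
        mols.append("".join(current))
    return mols, lossy
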