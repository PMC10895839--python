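import numpy as np
import pytest

from rxnmvp.synthetic_data import SyntheticSpec, make_synthetic_dataset
from rxnmvp.tokenizer import build_vocabulary, tokenize_smiles


@pytest.fixture(scope="session")
def small_dataset():
    """64 synthetic reactions with planted yields and rule-based conformers."""
    return make_synthetic_dataset(SyntheticSpec(n_reactions=64, seed=11))


@pytest.fixture(scope="session")
def small_vocab(small_dataset):
    return build_vocabulary(
        (tokenize_smiles(m.smiles) for r in small_dataset.records for m in r.molecules()),
        min_frequency=1,
    )


@pytest.fixture(scope="session")
def mol_pool():
    """A pool of synthetic molecules with coordinates for geometry tests."""
    from rxnmvp.synthetic_data import generate_synthetic_molecules

    spec = SyntheticSpec(seed=5)
    return generate_synthetic_molecules(spec, 20, np.random.default_rng(5))
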