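import numpy as np
import pytest

from fragretro.synthetic import (default_rules, fixture_vocabulary,
                                 make_molecule_corpus, make_reaction_corpus)


@pytest.fixture(scope="session")
def molecules():
    return make_molecule_corpus(600, seed=11)


@pytest.fixture(scope="session")
def vocab(molecules):
    return fixture_vocabulary(molecules)


@pytest.fixture(scope="session")
def rules(vocab):
    return default_rules(vocab)


@pytest.fixture(scope="session")
def clean_corpus(molecules, vocab, rules):
    return make_reaction_corpus(150, rules, seed=7, vocab=vocab,
                                molecules=molecules)


@pytest.fixture(scope="session")
def contaminated_corpus(vocab, rules):
    return make_reaction_corpus(
        250, rules, seed=19, vocab=vocab,
        dup_rate=0.06, twin_rate=0.05, multi_reactant_rate=0.04,
        long_rate=0.03, inject_rate=0.05)


def random_keysets(rng: np.random.Generator, n: int, lo: int = 1, hi: int = 166,
                   min_size: int = 1, max_size: int = 40):
    """Seeded random MACCS-style key sets for property tests."""
    from fragretro.keys import KeySet
    out = []
    for _ in range(n):
        size = int(rng.integers(min_size, max_size + 1))
        out.append(KeySet(rng.choice(np.arange(lo, hi + 1), size=size,
                                     replace=False)))
    return out
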