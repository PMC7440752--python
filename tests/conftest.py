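import random

import numpy as np
import pytest

from treewarp.characters import PatternMatrix
from treewarp.mcmc import random_tree
from treewarp.simulate import lba_fixture


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def nprng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def lba_data():
    """Five-taxon long-branch-attraction alignment (10 kb, K80 kappa=4)."""
    tree, seqs = lba_fixture(rng=np.random.default_rng(42))
    return tree, seqs


def random_alignment(labels, n_sites, rng):
    return PatternMatrix.from_sequences(
        {lab: "".join(rng.choice("ACGT") for _ in range(n_sites)) for lab in labels}
    )


@pytest.fixture
def tree6(rng):
    return random_tree([f"t{i}" for i in range(6)], rng)
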