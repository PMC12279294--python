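import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from abensemble.fixtures import FixtureSpec, make_planted_ensemble, make_toy_chain


@pytest.fixture(scope="session")
def three_cluster_ensemble():
    """Shuffled 15-member ensemble with 3 well-separated planted conformations."""
    spec = FixtureSpec(
        seed=7,
        n_conformations=3,
        members_per_conformation=(5, 5, 5),
        intra_noise_sigma=0.1,
        inter_conformation_shift=6.0,
    )
    return make_planted_ensemble(spec)


@pytest.fixture(scope="session")
def toy_pair():
    """Two noiseless chains one planted conformation apart, plus regions."""
    spec = FixtureSpec(
        seed=1, n_conformations=2, members_per_conformation=(1, 1),
        intra_noise_sigma=0.0, inter_conformation_shift=6.0,
    )
    a, regions = make_toy_chain(spec, conformation_id=0)
    b, _ = make_toy_chain(spec, conformation_id=1)
    return a, b, regions


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
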