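import numpy as np
import pytest

from chemlens import FixtureSpec, generate, make_two_group_dataset
from chemlens.fingerprints import FingerprintResult


@pytest.fixture(scope="session")
def small_fixture():
    """Deterministic 12-compound dataset with fingerprints and attributions."""
    return generate(FixtureSpec(n_compounds=12, seed=3))


@pytest.fixture(scope="session")
def two_group_small():
    """Two planted scaffold groups, 15 compounds each."""
    return make_two_group_dataset(15, seed=0)


@pytest.fixture
def toy_fp():
    """Hand-built 4-bit fingerprint on a 3-atom molecule.

    feature 0 -> atoms {0, 1}; feature 1 -> atoms {1, 2};
    feature 2 -> two occurrences {0} and {2}; feature 3 unset.
    """
    return FingerprintResult(
        bits=np.array([1, 1, 2, 0]),
        feature_atoms={0: [frozenset({0, 1})],
                       1: [frozenset({1, 2})],
                       2: [frozenset({0}), frozenset({2})]},
        n_atoms=3,
        counts=True,
    )
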