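import numpy as np
import pytest

from zindelta.synthetic import SyntheticSpec, generate_dataset, toy_fixtures


@pytest.fixture(scope="session")
def toy_dataset():
    return toy_fixtures()


@pytest.fixture(scope="session")
def small_synthetic():
    """60 synthetic molecules with the default deviation rule."""
    return generate_dataset(SyntheticSpec(n_molecules=60, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
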