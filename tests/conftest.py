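import warnings

import numpy as np
import pytest

from shallowbp.synth import SyntheticConfig, generate

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def clean_store():
    """60 clean synthetic records with ground truth."""
    return generate(SyntheticConfig(n_records=60, seed=11))


@pytest.fixture(scope="session")
def mixed_store():
    """100 records, 20 deliberately distorted."""
    return generate(SyntheticConfig(n_records=100, distortion_fraction=0.2, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
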