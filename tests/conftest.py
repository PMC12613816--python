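import numpy as np
import pytest

from phoreseek import synthetic_data as syn


@pytest.fixture(scope="session")
def reference_model():
    """The 5-feature synthetic reference pharmacophore (HBA, PI, 3x HYD)."""
    return syn.gen_reference_model(seed=7)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.Philox(1234))
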