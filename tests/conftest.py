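import numpy as np
import pytest

from nephromorph import MaskSpec, generate_mask


@pytest.fixture(scope="session")
def small_mask():
    """One deterministic synthetic mask shared by read-only tests."""
    return generate_mask(MaskSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
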