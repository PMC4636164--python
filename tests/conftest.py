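import numpy as np
import pytest

from crisprdyn import params as pp


@pytest.fixture(scope="session")
def benchmark_simple():
    """Nondimensional simple-model benchmark parameters (A_P = 2, G_V = 10)."""
    return pp.nondimensionalize_simple(pp.preset("benchmark-simple"))


@pytest.fixture(scope="session")
def reference_detailed():
    """Nondimensional detailed-model reference parameters (A_P = 1e6)."""
    return pp.nondimensionalize_detailed(pp.preset("reference-detailed"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20151106)
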