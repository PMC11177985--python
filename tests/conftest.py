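import numpy as np
import pytest

from strain2infarct.library import GeneratorConfig, build_library


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_library():
    """24-heart low-fidelity library used by several training tests."""
    return build_library(GeneratorConfig(n_examples=24, seed=0))


@pytest.fixture()
def float64_backend(monkeypatch):
    """Run the autodiff backend in float64 for tight numeric checks."""
    from strain2infarct.nn import autodiff

    monkeypatch.setattr(autodiff, "DTYPE", np.float64)
    yield
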