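import numpy as np
import pytest

from hexalig import (
    AssemblyParameters,
    BindingParameters,
    SpectrumModel,
    build_topology,
    default_topologies,
)


@pytest.fixture(scope="session")
def topologies():
    """Open-chain lattices for monomer through hexamer."""
    return default_topologies()


@pytest.fixture(scope="session")
def hexamer_six_site():
    return {6: build_topology(6, "uniform_linear")}


@pytest.fixture
def binding():
    """Study-scale binding parameters: Kd 10 / 100 uM, negative coupling."""
    return BindingParameters.with_shared_partial(1e5, 1e4, 0.5)


@pytest.fixture
def apo_binding():
    return BindingParameters.with_shared_partial(0.0, 0.0, 1.0)


@pytest.fixture
def assembly():
    """Nucleated-cooperative ladder with apo crossover near 0.1 uM."""
    return AssemblyParameters.nucleated(2e8, 0.1)


@pytest.fixture
def noiseless_model():
    return SpectrumModel()


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)
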