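import numpy as np
import pytest

from sizehom.simdata import adder_preset, simulate_lineages, sizer_preset


@pytest.fixture(scope="session")
def sizer_records():
    """Wild-type-like sizer population, ~900 completed cycles."""
    return simulate_lineages(sizer_preset(n_founders=130, seed=11))


@pytest.fixture(scope="session")
def adder_records():
    """Adder mutant population, ~900 completed cycles."""
    return simulate_lineages(adder_preset(n_founders=130, seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
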