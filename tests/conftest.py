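import numpy as np
import pytest

import phaseseed as ps


@pytest.fixture(scope="session")
def p21_dataset():
    """10-atom P2₁ structure with noise-free 0.9 Å data."""
    spec = ps.SynthSpec(n_asym=10, spacegroup="P21", d_min=0.9, rng_seed=1)
    return ps.make_dataset(spec)


@pytest.fixture(scope="session")
def p1_dataset():
    """10-atom P1 (acentric-only) structure with noise-free 0.9 Å data."""
    spec = ps.SynthSpec(n_asym=10, spacegroup="P1", d_min=0.9, rng_seed=1)
    return ps.make_dataset(spec)


@pytest.fixture(scope="session")
def p21_refs(p21_dataset):
    return p21_dataset[1]


@pytest.fixture(scope="session")
def p1_refs(p1_dataset):
    return p1_dataset[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
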