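import numpy as np
import pytest

from crystherm.harmonic import PhononSpectrum
from crystherm.synthetic import (
    DEFAULT_DSC_SPEC,
    DEFAULT_ENANTIOTROPIC_SPEC,
    DEFAULT_POLYTYPE_SPEC,
    make_cp_dataset,
    make_dsc_dataset,
    make_phonon_pair,
    make_polytype_pair,
)


@pytest.fixture(scope="session")
def phonon_pair():
    """Default enantiotropic pair with its exact crossing temperature."""
    return make_phonon_pair(DEFAULT_ENANTIOTROPIC_SPEC, seed=1)


@pytest.fixture(scope="session")
def cp_table():
    return make_cp_dataset(noise_sd=1.0, seed=11)


@pytest.fixture(scope="session")
def dsc_table():
    return make_dsc_dataset(DEFAULT_DSC_SPEC, seed=13)


@pytest.fixture(scope="session")
def polytype_pair():
    return make_polytype_pair(DEFAULT_POLYTYPE_SPEC)


@pytest.fixture
def toy_spectrum():
    return PhononSpectrum([40.0, 90.0, 200.0, 650.0, 1500.0],
                          [2.0, 3.0, 1.0, 2.0, 4.0], z=2,
                          lattice_energy=-100.0, label="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
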