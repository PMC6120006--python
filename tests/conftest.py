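import numpy as np
import pytest

from cgblob import MorsePotential, build_c60, point_blob
from cgblob.tensors import BlobTemplate
from cgblob.units import C60_MOLAR_MASS


@pytest.fixture(scope="session")
def c60():
    return build_c60(1.450, 1.386)


@pytest.fixture(scope="session")
def atomic_morse():
    """Atomic carbon-carbon Morse of the fullerene force field."""
    return MorsePotential(de=0.074, alpha=1.3, r0=4.1)


@pytest.fixture(scope="session")
def cg3_effective():
    """Fitted third-order effective single-site Morse, 3600-scaled."""
    return MorsePotential(de=3600 * 0.00177, alpha=1.3, r0=9.65)


@pytest.fixture(scope="session")
def cg0_effective():
    """Fitted zeroth-order effective single-site Morse, 3600-scaled."""
    return MorsePotential(de=3600 * 0.0017, alpha=1.3, r0=9.5)


@pytest.fixture(scope="session")
def united_atom():
    return point_blob(C60_MOLAR_MASS, label="C60-united-atom")


@pytest.fixture()
def make_blob():
    """Factory for reproducible random blob templates."""

    def _make(n_atoms, scale=1.5, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.0, scale, (n_atoms, 3))
        return BlobTemplate(pos, np.full(n_atoms, 12.0))

    return _make
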