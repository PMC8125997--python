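import numpy as np
import pytest

from ringeit.configs import ElectrodeRing, enumerate_dedicated
from ringeit.fem import ConductivityField, build_disk_mesh


@pytest.fixture(scope="session")
def ring16():
    return ElectrodeRing(L=16)


@pytest.fixture(scope="session")
def cfg_dedicated16():
    return enumerate_dedicated(16)


@pytest.fixture(scope="session")
def small_mesh(ring16):
    """Coarse disk mesh (256 elements) for brute-force oracles."""
    return build_disk_mesh(1.0, 200, ring16)


@pytest.fixture(scope="session")
def medium_mesh(ring16):
    """2k-element disk mesh for profile and phantom checks."""
    return build_disk_mesh(1.0, 2000, ring16)


@pytest.fixture(scope="session")
def homogeneous_small(small_mesh):
    return ConductivityField.homogeneous(small_mesh)


@pytest.fixture(scope="session")
def homogeneous_medium(medium_mesh):
    return ConductivityField.homogeneous(medium_mesh)
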