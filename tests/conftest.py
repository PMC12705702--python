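import numpy as np
import pytest

from filarch.helical import HelicalParams
from filarch.lattice import extract_honeycomb
from filarch.synthetic import (
    IFI16_PRESET,
    LatticePreset,
    ToyProtomerSpec,
    make_filament_fixture,
    make_toy_protomer,
)


@pytest.fixture(scope="session")
def toy_protomer():
    return make_toy_protomer(ToyProtomerSpec())


@pytest.fixture(scope="session")
def pyd_fixture():
    """Noise-free 30-subunit filament on the reported pyrin-domain lattice."""
    filament, truth = make_filament_fixture(IFI16_PRESET, n=30)
    return filament, truth


@pytest.fixture(scope="session")
def pyd_honeycomb(pyd_fixture):
    filament, _ = pyd_fixture
    return extract_honeycomb(filament, len(filament) // 2)


@pytest.fixture(scope="session")
def ring_fixture():
    """C3 ring lattice (two rings per protomer height) for base-count tests."""
    preset = LatticePreset("ring3", HelicalParams(twist_deg=40.0, rise_A=8.0, cn=3),
                           provenance="user")
    return make_filament_fixture(preset, n=30)


def brute_force_contacts(filament, cutoff):
    """O(N^2) oracle: inter-protomer heavy-atom contact counts and minima."""
    edges = {}
    protos = filament.protomers
    for i in range(len(protos)):
        ci = protos[i].coords()
        for j in range(i + 1, len(protos)):
            cj = protos[j].coords()
            d = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=2)
            n = int((d < cutoff).sum())
            if n:
                edges[(i, j)] = (n, float(d.min()))
    return edges


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix()
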