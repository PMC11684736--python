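import numpy as np
import pytest

from molcage.cspace import VerifyParams
from molcage.fixtures import make_dumbbell_guest, make_guest_ball, make_shell_cage
from molcage.mol_io import load_radii_table


@pytest.fixture(scope="session")
def radii():
    return load_radii_table()


@pytest.fixture(scope="session")
def closed_shell():
    """Sealed shell cage: cavity clearance 3.0 A, straight-ray passage bound
    certified below 0.5 A."""
    host, spec = make_shell_cage(4.0, 1.0, 100, target_passage=0.5)
    return host, spec


@pytest.fixture(scope="session")
def apertured_shell():
    """Shell with a polar aperture wide enough for the standard ball guest."""
    host, spec = make_shell_cage(4.0, 1.0, 100, aperture=0.7)
    return host, spec


@pytest.fixture(scope="session")
def small_shell():
    """Small cheap shell for screening-level tests (cavity clearance 1.7 A)."""
    host, spec = make_shell_cage(2.5, 0.8, 40, probe_directions=256)
    return host, spec


@pytest.fixture(scope="session")
def ball_guest():
    return make_guest_ball(1.2)


@pytest.fixture(scope="session")
def dumbbell_guest():
    return make_dumbbell_guest(0.9, 0.3)


@pytest.fixture(scope="session")
def fast_params():
    """Coarse resolution for throughput-oriented tests."""
    return VerifyParams(h=0.6, n_orientations=8, refine_levels=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sphere_set(rng, n, box=5.0, rmin=0.5, rmax=1.5):
    from molcage.geometry import SphereSet

    centers = rng.uniform(-box, box, size=(n, 3))
    radii = rng.uniform(rmin, rmax, size=n)
    return SphereSet(centers, radii)


def random_configuration(rng, tmax=3.0):
    from molcage.geometry import Configuration

    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    return Configuration(rng.uniform(-tmax, tmax, 3), q)
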