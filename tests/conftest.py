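import numpy as np
import pytest

from uisnr.dipole_cloud import build_shell
from uisnr.phantom import (DielectricVolumes, FieldSpec, TissueDielectric,
                           make_sphere_phantom)


@pytest.fixture(scope="session")
def saline():
    return TissueDielectric.constant(6, "saline", eps_r=78.0, sigma=1.0)


@pytest.fixture(scope="session")
def small_sphere(saline):
    """Tiny saline sphere: 4-voxel radius, ample air margin."""
    return make_sphere_phantom(0.048, 0.012, saline, margin=0.048)


@pytest.fixture(scope="session")
def small_cloud(small_sphere):
    return build_shell(small_sphere, 0.024, 0.036)


@pytest.fixture(scope="session")
def spec_3t():
    return FieldSpec(B0=3.0)


def tiny_dielectrics(shape, eps, sigma, frequency=127.7e6,
                     voxel_size=0.005, body=None):
    """Helper: dielectric volumes with a given interior region."""
    e = np.ones(shape)
    s = np.zeros(shape)
    if body is None:
        body = tuple(slice(1, n - 1) for n in shape)
    e[body] = eps
    s[body] = sigma
    return DielectricVolumes(eps_r=e, sigma=s, frequency=frequency,
                             voxel_size=voxel_size)
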