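import numpy as np
import pytest

from gliomech.phantom import (PhantomSpec, make_ball_mesh, make_indicator,
                              make_synthetic_dti)
from gliomech.tensors import voxel_to_cell


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast phantom used by the solver unit tests."""
    return PhantomSpec(brain_radius=25.0, h=9.0, tumour_radius=5.0,
                       interface_width=1.0)


@pytest.fixture(scope="session")
def small_mesh(small_spec):
    return make_ball_mesh(small_spec)


@pytest.fixture(scope="session")
def small_inputs(small_spec, small_mesh):
    """(mesh, chi, D0_cells) for the small isotropic phantom."""
    chi = make_indicator(small_mesh, small_spec.tumour_centre,
                         small_spec.tumour_radius, small_spec.interface_width)
    D0 = voxel_to_cell(make_synthetic_dti(small_spec), small_mesh)
    return small_mesh, chi, D0


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_deformation(rng, scale=0.3):
    """Random invertible F = I + scale*H with det > 0 guaranteed by rejection."""
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.2:
            return F
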