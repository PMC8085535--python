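import numpy as np
import pytest
import trimesh

from tkrfem.contact import build_synthetic_contact_model
from tkrfem.gait import synth_gait
from tkrfem.geometry import TriSurface
from tkrfem.synthetic import SyntheticGeomParams, make_synthetic_tkr


@pytest.fixture
def unit_cube() -> TriSurface:
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriSurface(np.asarray(box.vertices), np.asarray(box.faces), "cube")


@pytest.fixture
def icosphere() -> TriSurface:
    s = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
    return TriSurface(np.asarray(s.vertices), np.asarray(s.faces), "icosphere")


@pytest.fixture(scope="session")
def default_params() -> SyntheticGeomParams:
    return SyntheticGeomParams()


@pytest.fixture(scope="session")
def coarse_params() -> SyntheticGeomParams:
    """Low-resolution assembly for volume meshing / model-building tests."""
    return SyntheticGeomParams(insert_grid=(17, 11), sphere_subdivisions=1)


@pytest.fixture(scope="session")
def synthetic_parts(default_params):
    return make_synthetic_tkr(default_params)


@pytest.fixture(scope="session")
def normal_bc():
    return synth_gait("normal", seed=1)


@pytest.fixture
def contact_model():
    return build_synthetic_contact_model()
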