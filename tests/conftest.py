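import numpy as np
import pytest

from breastfem.volume import LabelMap, Volume, Label
from breastfem.materials import MaterialParams
from breastfem import meshing, fem
from breastfem.phantom import PhantomSpec, make_supine_phantom


def hemisphere_labels(radius: float = 20.0, spacing: float = 2.0,
                      wall: float = 4.0) -> LabelMap:
    """All-adipose hemisphere on a chest-wall slab (no gland, no lesion)."""
    xs = np.arange(-radius - 4, radius + 5, spacing)
    ys = np.arange(-wall, radius + 5, spacing)
    zs = xs.copy()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    lab = np.zeros(X.shape, dtype=np.int64)
    lab[Y < 0] = Label.CHEST_WALL
    lab[(X ** 2 + Y ** 2 + Z ** 2 <= radius ** 2) & (Y >= 0)] = Label.ADIPOSE
    return LabelMap(data=lab, spacing=[spacing] * 3,
                    origin=[xs[0], ys[0], zs[0]])


def cube_labels(n_vox: int = 5, spacing: float = 2.0) -> LabelMap:
    pad = 2
    m = n_vox + 2 * pad
    lab = np.zeros((m, m, m), dtype=np.int64)
    lab[pad:pad + n_vox, pad:pad + n_vox, pad:pad + n_vox] = Label.ADIPOSE
    return LabelMap(data=lab, spacing=[spacing] * 3, origin=np.zeros(3))


@pytest.fixture(scope="session")
def hemi_labels():
    return hemisphere_labels(radius=20.0, spacing=2.0)


@pytest.fixture(scope="session")
def hemi_mesh(hemi_labels):
    return meshing.voxel_to_hex_mesh(hemi_labels, 4.0,
                                     nipple_mm=np.array([0.0, 20.0, 0.0]))


@pytest.fixture(scope="session")
def single_element_mesh():
    return meshing.voxel_to_hex_mesh(cube_labels(n_vox=1, spacing=2.0), 2.0)


@pytest.fixture(scope="session")
def materials():
    return MaterialParams()


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast phantom with genuinely large deformation.

    At 28 mm radius the gravity number rho*g*R/mu is ~0.8 for a 1 kPa
    adipose modulus, i.e. several millimetres of nipple sag — enough for
    the inverse search and the registration comparison to be meaningful
    while each forward solve stays in the seconds range.
    """
    return PhantomSpec(breast_radius=28.0, voxel_spacing=2.0,
                       volumetric_density_target=0.15, lesion_radius=4.0,
                       lesion_location_ratio_target=0.5, true_E_adipose=1.0,
                       seed=7)


@pytest.fixture(scope="session")
def small_case(small_spec):
    return make_supine_phantom(small_spec)


@pytest.fixture(scope="session")
def fast_fem_config():
    """Slightly looser reference tolerance for the small test meshes."""
    return fem.FemConfig(reference_tol=0.3)
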