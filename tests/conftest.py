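import numpy as np
import pytest

from beadforce import _sh
from beadforce.fixtures import GroundTruthShape, render_field, render_sh_shape, sphere_coeffs
from beadforce.imgseg import SegParams, voronoi_otsu_label
from beadforce.shape import SurfaceCloud

VOXEL = 0.5
GRID = (64, 64, 64)
CENTER = np.array([16.0, 16.0, 16.0])

#: parameters matched to the reference fixtures (objects of ~5 um radius
#: rendered at 0.5 um voxels)
SEG = SegParams(spot_sigma=2.0, outline_sigma=0.5)


@pytest.fixture(scope="session")
def sphere_truth():
    return GroundTruthShape(coeffs=sphere_coeffs(5.0), center=CENTER.copy())


@pytest.fixture(scope="session")
def sphere_image(sphere_truth):
    return render_sh_shape(sphere_truth, VOXEL, GRID)


@pytest.fixture(scope="session")
def sphere_labels(sphere_image):
    return voronoi_otsu_label(sphere_image, SEG)


@pytest.fixture(scope="session")
def deformed_truth():
    c = sphere_coeffs(5.0, 3)
    c[_sh.mode_index(2, 0)] = -0.8
    c[_sh.mode_index(3, 2)] = 0.3
    return GroundTruthShape(coeffs=c, center=CENTER.copy())


@pytest.fixture(scope="session")
def deformed_labels(deformed_truth):
    img = render_sh_shape(deformed_truth, VOXEL, GRID)
    return voronoi_otsu_label(img, SEG)


@pytest.fixture(scope="session")
def bead_field():
    """Five well-separated deformed beads with ground truth, no noise."""
    return render_field(
        5, radius_range=(4.0, 6.0), deformation_amplitude=0.1,
        l_range=(2, 4), grid_shape=(96, 96, 96), voxel_size=VOXEL, seed=7,
    )


def exact_surface_cloud(coeffs, center=None, n_points=2000, label_id=1):
    """Noise-free surface samples of a band-limited radius function."""
    center = np.zeros(3) if center is None else np.asarray(center, float)
    i = np.arange(n_points) + 0.5
    z = 1.0 - 2.0 * i / n_points
    golden = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([s * np.cos(golden), s * np.sin(golden), z])
    theta = np.arccos(np.clip(dirs[:, 2], -1, 1))
    phi = np.mod(np.arctan2(dirs[:, 1], dirs[:, 0]), 2 * np.pi)
    r = _sh.evaluate(coeffs, theta, phi)
    return SurfaceCloud(points=center + r[:, None] * dirs, center=center, label_id=label_id)
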