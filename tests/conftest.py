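"""Shared synthetic fixtures (everything is generated at test time)."""

import numpy as np
import pytest

from isletmorph.segmentation import CellMask
from isletmorph.synthetic import CellSpec, SceneSpec, render_scene

SPACING = (1.0, 0.3, 0.3)


def digitized_sphere(radius_um=5.0, spacing=SPACING, pad_um=2.0):
    """Noiseless, unblurred solid sphere rendered through the scene generator."""
    extent = 2 * (radius_um + pad_um)
    shape = tuple(max(8, int(np.ceil(extent / s))) for s in spacing)
    # snap the center onto the voxel grid so digitization is symmetric
    center = tuple(((n - 1) // 2) * s for n, s in zip(shape, spacing))
    spec = SceneSpec(
        grid_shape=shape,
        cells=[CellSpec(center=center, semi_axes=(radius_um,) * 3)],
        voxel_spacing=spacing,
        psf_sigma=(0.0, 0.0, 0.0),
        noise=None,
        seed=1,
    )
    return render_scene(spec)


@pytest.fixture
def make_sphere():
    """Factory fixture for digitized spheres of arbitrary radius."""
    return digitized_sphere


@pytest.fixture(scope="session")
def sphere_scene():
    """(image, truth) for a noiseless r=5 μm sphere at anisotropic spacing."""
    return digitized_sphere()


@pytest.fixture
def ball_mask():
    """Plain boolean ball mask (r=4 μm) built directly, for mask-level tests."""
    shape = (14, 40, 40)
    sp = np.asarray(SPACING)
    zz, yy, xx = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, SPACING)], indexing="ij")
    center = np.array([6.0, 6.0, 6.0])
    data = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= 16.0
    return CellMask(data, SPACING)
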