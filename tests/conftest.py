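import numpy as np
import pytest

from nephroscore.io_volumes import LabelMask, VoxelVolume


def mask_from(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelMask(np.asarray(arr), spacing)


def cube_mask(shape, lo, size, spacing=(1.0, 1.0, 1.0)):
    """Axis-aligned solid cube of `size` voxels starting at index `lo`."""
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(l, l + s) for l, s in zip(np.broadcast_to(lo, 3),
                                               np.broadcast_to(size, 3)))
    m[sl] = True
    return LabelMask(m, spacing)


def sphere_mask(radius_mm, spacing_mm, pad_vox=7):
    """Digitized sphere (voxel centers within radius) on an isotropic grid."""
    n = int(round(2 * radius_mm / spacing_mm)) + 2 * pad_vox
    ax = np.arange(n) * spacing_mm
    c = ax[n // 2]
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    m = (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= radius_mm ** 2
    return LabelMask(m, (spacing_mm,) * 3)


@pytest.fixture(scope="session")
def flat_cap_case():
    """Slab phantom, r = 20 mm, depth 35 mm, 0.5 mm voxels (shared: slow)."""
    from nephroscore.phantom import flat_cap_spec, generate_phantom

    return generate_phantom(flat_cap_spec(spacing_mm=0.5))


@pytest.fixture(scope="session")
def ellipsoid_case():
    """Default realistic ellipsoid phantom at 1 mm voxels."""
    from nephroscore.phantom import ellipsoid_spec, generate_phantom

    return generate_phantom(ellipsoid_spec(seed=11))
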