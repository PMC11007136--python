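import numpy as np
import pytest

import digispec as ds


@pytest.fixture(scope="session")
def offset_phantom():
    """Mid-resolution phantom with an off-center tumor; shared read-only."""
    cfg = ds.PhantomConfig(spacing_mm=0.8, tumor_center_mm=(1.0, 2.0, -2.0))
    return ds.generate_phantom(cfg)


@pytest.fixture(scope="session")
def offset_specimen(offset_phantom):
    return ds.make_digital_specimen(offset_phantom.volume, role="ground-truth")


@pytest.fixture(scope="session")
def offset_partition(offset_phantom, offset_specimen):
    plane = ds.fit_mucosa_plane(offset_specimen)
    cone = ds.build_deep_cone(offset_specimen, plane)
    return ds.partition_surface(
        offset_specimen,
        cone,
        offset_phantom.anterior_point_mm,
        offset_phantom.posterior_point_mm,
        offset_phantom.craniomedial_hint,
    )


def random_small_volume(rng, shape=None, spacing=None, n_labels=4):
    """A random labeled grid on a tiny lattice for brute-force oracles."""
    if shape is None:
        shape = tuple(rng.integers(8, 20, 3))
    if spacing is None:
        spacing = rng.uniform(0.4, 2.0, 3)
    grid = rng.integers(0, n_labels, shape).astype(np.int16)
    return grid, np.asarray(spacing), rng.uniform(-5, 5, 3)


def voxel_ball(radius_mm, spacing_mm, margin_mm=2.0, center=(0.0, 0.0, 0.0), extent_mm=None):
    """Digitized ball mask + geometry; ``extent_mm`` pins the grid size so
    two balls can share one grid."""
    h = float(spacing_mm)
    if extent_mm is None:
        extent_mm = radius_mm + margin_mm + max(np.abs(center))
    n = int(np.ceil(extent_mm / h))
    ax = np.arange(-n, n + 1) * h
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius_mm**2
    origin = np.array([ax[0]] * 3)
    return mask, np.array([h, h, h]), origin
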