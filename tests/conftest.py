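"""Shared fixtures: phantoms, a compact volume grid, distance fields.

Phantom geometry is deterministic (no RNG in construction), so
session-scoped fixtures are safe.  The compact grid covers the whole
phantom (bone shell included) at the study's 0.8-mm spacing with a
smaller field of view than the full acquisition grid, which keeps the
distance-transform-heavy fixtures fast.
"""

import numpy as np
import pytest

from navmargin.imaging import signed_distance
from navmargin.phantoms import PRESETS, VolumeSpec, build_phantom, rasterize, synthesize_volume


@pytest.fixture(scope="session")
def models():
    return {pid: build_phantom(p) for pid, p in PRESETS.items()}


@pytest.fixture(scope="session")
def s2_model(models):
    return models["S2"]


@pytest.fixture(scope="session")
def small_spec():
    return VolumeSpec(dims=(160, 184, 160), spacing=0.8)


@pytest.fixture(scope="session")
def s2_masks(s2_model, small_spec):
    return rasterize(s2_model, small_spec)


@pytest.fixture(scope="session")
def s2_volume(s2_model, small_spec):
    return synthesize_volume(s2_model, small_spec)


@pytest.fixture(scope="session")
def s2_fields(s2_masks):
    return signed_distance(s2_masks["tumor"]), signed_distance(s2_masks["ica"])


def sphere_mask(radius_mm, spacing=0.8, pad_voxels=4):
    """Voxelized origin-centered sphere with an odd grid (center on a voxel)."""
    from navmargin.grids import LabelMask

    n = 2 * (int(np.ceil(radius_mm / spacing)) + pad_voxels) + 1
    ax = (np.arange(n) - n // 2) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    vox = X**2 + Y**2 + Z**2 <= radius_mm**2
    return LabelMask(spacing=spacing, origin=np.array([ax[0]] * 3), voxels=vox)
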