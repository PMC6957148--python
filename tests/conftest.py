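"""Shared fixtures and builders for the test suite.

All imaging fixtures are generated programmatically: small analytic masks
(rods, cubes, rasterized balls) and seeded random regions.
"""

from __future__ import annotations

import numpy as np
import pytest

from pantex.volumes import CTVolume, ROIMask, SegmentedRegion, extract_region


def make_region(values, shape=None, spacing=(1.0, 1.0, 1.0)) -> SegmentedRegion:
    """SegmentedRegion holding exactly ``values`` (full-grid mask)."""
    values = np.asarray(values, dtype=float)
    if shape is None:
        shape = (values.size, 1, 1)
    vol = CTVolume(voxels=values.reshape(shape), spacing=spacing)
    mask = ROIMask(voxels=np.ones(shape, dtype=np.uint8), spacing=spacing)
    return extract_region(vol, mask)


def make_masked_region(voxels, mask_voxels, spacing=(1.0, 1.0, 1.0)) -> SegmentedRegion:
    vol = CTVolume(voxels=np.asarray(voxels, dtype=float), spacing=spacing)
    mask = ROIMask(voxels=np.asarray(mask_voxels), spacing=spacing)
    return extract_region(vol, mask)


def rect_mask(shape, spacing=(1.0, 1.0, 1.0), pad=0) -> ROIMask:
    """Solid box mask of ``shape`` foreground voxels, optionally padded."""
    full = tuple(s + 2 * pad for s in shape)
    vox = np.zeros(full, dtype=np.uint8)
    sl = tuple(slice(pad, pad + s) for s in shape)
    vox[sl] = 1
    return ROIMask(voxels=vox, spacing=spacing)


def ball_mask(radius_mm, spacing=(1.0, 1.0, 1.0), margin=2) -> ROIMask:
    """Rasterized ball: voxel centres within ``radius_mm`` of the centre."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.ceil(radius_mm / spacing).astype(int) + margin
    shape = 2 * half + 1
    grids = np.meshgrid(
        *[(np.arange(n) - n // 2) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    return ROIMask(voxels=(dist2 <= radius_mm**2).astype(np.uint8), spacing=tuple(spacing))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
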