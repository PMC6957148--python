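"""Data model and I/O for CT volumes and binary regions of interest.

A CT study enters the pipeline as a 3D scalar field of Hounsfield units (HU)
on an anisotropic voxel grid (venous-phase abdominal CT typically has
sub-millimetre in-plane spacing and 2.5–5 mm slices), together with a
co-registered binary mask marking the segmented pancreas.  All physical
feature computations downstream use the header voxel spacing in millimetres
and never assume isotropy.

Masks are strictly binary: any nonzero label is foreground.  Volumes and
masks must live on the same grid — resampling is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "ROIMask",
    "SegmentedRegion",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "extract_region",
]

#: relative tolerance for grid-compatibility checks (spacing agreement)
SPACING_RTOL = 1e-4


@dataclass(frozen=True)
class CTVolume:
    """A 3D CT image in Hounsfield units on a regular anisotropic grid.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU values, float. Must be finite.
    spacing : tuple of float
        Voxel edge lengths ``(sx, sy, sz)`` in mm; strictly positive.
    origin : tuple of float
        Physical offset of the first voxel centre in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise ValueError(f"expected 3D volume, got {vox.ndim}D array")
        if not np.all(np.isfinite(vox)):
            raise ValueError("volume contains non-finite HU values")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass(frozen=True)
class ROIMask:
    """Binary region-of-interest mask on the same grid as its CTVolume.

    Nonzero voxels are foreground.  Stored as uint8 in {0, 1}.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected 3D mask, got {vox.ndim}D array")
        binary = (vox != 0).astype(np.uint8)
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", binary)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def indices(self) -> np.ndarray:
        """Foreground voxel indices, shape (n, 3), in C order."""
        return np.argwhere(self.voxels != 0)


@dataclass(frozen=True)
class SegmentedRegion:
    """A CT volume restricted to its ROI: the carrier object for all features."""

    volume: CTVolume
    mask: ROIMask
    voxel_values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        vals = self.volume.voxels[self.mask.voxels != 0]
        object.__setattr__(self, "voxel_values", vals)

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_values.size)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volume.spacing


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    # get_fdata applies scl_slope/scl_inter from the header, so stored
    # integers come back as calibrated HU
    data = np.asanyarray(img.get_fdata(dtype=np.float64))
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D image in {path}")
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) for z in zooms)
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return data, spacing, origin


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI CT volume; header rescale slope/intercept are applied.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the image is not 3D or contains non-finite values.
    """
    data, spacing, origin = _load_nifti(path)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains non-finite values")
    return CTVolume(voxels=data, spacing=spacing, origin=origin)


def read_mask(path: str | Path) -> ROIMask:
    """Read a NIfTI label image as a binary ROI mask (nonzero -> foreground).

    Raises
    ------
    ValueError
        If the mask has no foreground voxels.
    """
    data, spacing, origin = _load_nifti(path)
    mask = ROIMask(voxels=data, spacing=spacing, origin=origin)
    if mask.n_foreground == 0:
        raise ValueError(f"mask has no foreground voxels: {path}")
    return mask


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a CTVolume as float32 NIfTI-1."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), _affine_from(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: ROIMask, path: str | Path) -> None:
    """Write an ROIMask as uint8 NIfTI-1."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine_from(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def extract_region(volume: CTVolume, mask: ROIMask) -> SegmentedRegion:
    """Pair a CT volume with its ROI mask after grid-compatibility checks.

    The two images must share the grid shape exactly and the voxel spacing
    within relative tolerance 1e-4 (native-grid analysis; no resampling).
    """
    if volume.shape != mask.shape:
        raise ValueError(f"volume/mask shape mismatch: {volume.shape} vs {mask.shape}")
    vs = np.asarray(volume.spacing)
    ms = np.asarray(mask.spacing)
    if not np.allclose(vs, ms, rtol=SPACING_RTOL, atol=0.0):
        raise ValueError(f"volume/mask spacing mismatch: {volume.spacing} vs {mask.spacing}")
    if mask.n_foreground == 0:
        raise ValueError("mask has no foreground voxels")
    return SegmentedRegion(volume=volume, mask=mask)
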