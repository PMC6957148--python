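"""3D gray-level co-occurrence matrix (GLCM) and second-order features.

The GLCM tabulates how often pairs of quantized gray levels co-occur at a
given voxel displacement inside the ROI.  Second-order features derived
from it (contrast, entropy, angular second moment, inverse difference
moment, difference moments) measure the *spatial* structure of the texture,
unlike the first-order histogram statistics which ignore neighbourhoods.

Defaults
--------
* Quantization: 1-HU bins anchored at the region minimum
  (``level = floor((HU − min) / w)``) — fine quantization of noisy CT.
* Offsets: the 13 unique direction vectors of the 26-neighbourhood at
  Chebyshev distance 1, applied in index space, accumulated into a single
  symmetric matrix.  On anisotropic grids the z-neighbour is physically
  farther than in-plane neighbours; ``offsets="inplane"`` restricts to the
  4 in-plane directions.
* Symmetrization: each ordered pair contributes to both (i, j) and (j, i);
  the matrix is normalized to sum to 1.
* Entropy in nats by default (configurable log base).
* "Moments" is the mean absolute gray-level difference Σ p(i,j)·|i−j|^k
  with k = 1 by default (difference moment of order k).

Contrast is reported on the HU² scale of the quantized levels, i.e.
Σ p(i,j)·(i−j)²·w².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import ROIMask, SegmentedRegion

__all__ = [
    "QuantizedRegion",
    "GLCM",
    "GLCMFeatures",
    "default_offsets",
    "quantize",
    "build_glcm",
    "glcm_feature_set",
    "glcm_features",
]

_LOG = {"ln": np.log, "log2": np.log2, "log10": np.log10}

#: the 13 unique displacement directions of the 26-neighbourhood
OFFSETS_3D_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: the 4 unique in-plane directions (z fixed)
OFFSETS_INPLANE_4 = ((1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 0))


def default_offsets(name: str = "3d13") -> tuple[tuple[int, int, int], ...]:
    """Named offset sets: ``"3d13"`` (full 3D) or ``"inplane"``."""
    if name == "3d13":
        return OFFSETS_3D_13
    if name == "inplane":
        return OFFSETS_INPLANE_4
    raise ValueError(f"unknown offset set {name!r}; expected '3d13' or 'inplane'")


@dataclass(frozen=True)
class QuantizedRegion:
    """Gray levels on the grid; background voxels hold the sentinel −1."""

    levels: np.ndarray  # int array, −1 outside the mask
    n_levels: int       # number of distinct occupied levels
    n_levels_total: int  # size of the level range [0, max_level]
    bin_width: float


@dataclass(frozen=True)
class GLCM:
    """Symmetric, normalized co-occurrence matrix over gray levels."""

    matrix: np.ndarray
    offsets: tuple[tuple[int, int, int], ...]
    counts_total: int
    bin_width: float


@dataclass(frozen=True)
class GLCMFeatures:
    contrast: float   # HU² of the quantized scale
    entropy: float    # nats by default
    asm: float
    idm: float
    moments: float

    def as_dict(self) -> dict[str, float]:
        return {
            "glcm_contrast": self.contrast,
            "glcm_entropy": self.entropy,
            "glcm_asm": self.asm,
            "glcm_idm": self.idm,
            "glcm_moments": self.moments,
        }


def quantize(region: SegmentedRegion, bin_width: float = 1.0) -> QuantizedRegion:
    """Quantize ROI voxel values to integer gray levels.

    ``level = floor((HU − min_HU) / bin_width)``; the region minimum is the
    anchor, making the levels (hence all GLCM features) invariant to adding
    a constant HU offset to the whole region.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if region.n_voxels == 0:
        raise ValueError("empty region")
    fg = region.mask.voxels != 0
    values = region.volume.voxels
    vmin = values[fg].min()
    levels = np.full(values.shape, -1, dtype=np.int64)
    levels[fg] = np.floor((values[fg] - vmin) / bin_width).astype(np.int64)
    occupied = np.unique(levels[fg])
    return QuantizedRegion(
        levels=levels,
        n_levels=int(occupied.size),
        n_levels_total=int(levels[fg].max()) + 1,
        bin_width=float(bin_width),
    )


def build_glcm(
    q: QuantizedRegion,
    mask: ROIMask,
    offsets: tuple[tuple[int, int, int], ...] | str = "3d13",
) -> GLCM:
    """Accumulate co-occurrences over all offsets into one symmetric matrix.

    Both voxels of a pair must be foreground; pairs crossing the mask or the
    grid boundary are skipped.  Each pair is counted in both (i, j) and
    (j, i) before normalization.

    Raises
    ------
    ValueError
        If the offset set is empty or no valid co-occurring pair exists
        (e.g. a single isolated voxel).
    """
    if isinstance(offsets, str):
        offsets = default_offsets(offsets)
    offsets = tuple(tuple(int(c) for c in off) for off in offsets)
    if len(offsets) == 0:
        raise ValueError("empty offset set")
    n = q.n_levels_total
    fg = mask.voxels != 0
    lv = q.levels
    shape = lv.shape
    counts = np.zeros((n, n), dtype=np.float64)
    total_pairs = 0
    for off in offsets:
        src = []
        dst = []
        for axis, d in enumerate(off):
            size = shape[axis]
            if abs(d) >= size:
                src = None
                break
            if d >= 0:
                src.append(slice(0, size - d))
                dst.append(slice(d, size))
            else:
                src.append(slice(-d, size))
                dst.append(slice(0, size + d))
        if src is None:
            continue
        a = lv[tuple(src)]
        b = lv[tuple(dst)]
        valid = fg[tuple(src)] & fg[tuple(dst)]
        ai = a[valid]
        bi = b[valid]
        if ai.size:
            np.add.at(counts, (ai, bi), 1.0)
            np.add.at(counts, (bi, ai), 1.0)
            total_pairs += int(ai.size)
    if total_pairs == 0:
        raise ValueError("no co-occurring pairs in region for the given offsets")
    counts /= counts.sum()
    return GLCM(matrix=counts, offsets=offsets, counts_total=total_pairs, bin_width=q.bin_width)


def glcm_feature_set(
    g: GLCM,
    log_base: str = "ln",
    moment_order: int = 1,
) -> GLCMFeatures:
    """Second-order features of a normalized GLCM.

    contrast = Σ p·(i−j)²·w² ; entropy = −Σ p·log p ; asm = Σ p² ;
    idm = Σ p / (1 + (i−j)²) ; moments = Σ p·|i−j|^k (k = ``moment_order``).
    """
    log = _LOG[log_base]
    p = g.matrix
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    diff = (i - j).astype(float)
    w = g.bin_width
    contrast = float(np.sum(p * diff**2) * w * w)
    nz = p[p > 0]
    entropy = float(-np.sum(nz * log(nz))) if nz.size > 1 else 0.0
    asm = float(np.sum(p * p))
    idm = float(np.sum(p / (1.0 + diff**2)))
    moments = float(np.sum(p * np.abs(diff) ** moment_order))
    return GLCMFeatures(contrast=contrast, entropy=entropy, asm=asm, idm=idm, moments=moments)


def glcm_features(
    region: SegmentedRegion,
    bin_width: float = 1.0,
    offsets: tuple[tuple[int, int, int], ...] | str = "3d13",
    log_base: str = "ln",
    moment_order: int = 1,
) -> GLCMFeatures:
    """Quantize, build the GLCM and compute all five features in one call."""
    q = quantize(region, bin_width=bin_width)
    g = build_glcm(q, region.mask, offsets=offsets)
    return glcm_feature_set(g, log_base=log_base, moment_order=moment_order)
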