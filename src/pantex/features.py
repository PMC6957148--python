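"""The 17-feature vector of a segmented region, in canonical column order.

Order follows the reporting convention of the analysis: seven first-order
histogram features, five volumetric/shape features, five GLCM texture
features.  The column names are a frozen public contract used by every CSV
the pipeline writes and reads.
"""

from __future__ import annotations

from .config import DEFAULT_CONFIG, RunConfig
from .first_order import first_order
from .glcm import glcm_features
from .shape import shape_features
from .volumes import CTVolume, ROIMask, extract_region

__all__ = ["FEATURE_NAMES", "extract_features"]

FEATURE_NAMES: tuple[str, ...] = (
    # first order
    "mean_attenuation",
    "sd",
    "variance",
    "skewness",
    "kurtosis",
    "entropy",
    "homogeneity",
    # shape
    "surface_area_mm2",
    "effective_diameter_mm",
    "volume_cm3",
    "sphericity",
    "discrete_compactness",
    # GLCM
    "glcm_contrast",
    "glcm_entropy",
    "glcm_asm",
    "glcm_idm",
    "glcm_moments",
)


def extract_features(
    volume: CTVolume,
    mask: ROIMask,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Extract all 17 features of a volume/mask pair.

    Returns a dict keyed by :data:`FEATURE_NAMES` in canonical order.
    """
    region = extract_region(volume, mask)
    fo = first_order(
        region,
        bin_width=config.bin_width_first_order,
        log_base=config.log_base,
        skewness_convention=config.skewness_convention,
        kurtosis_convention=config.kurtosis_convention,
    )
    sh = shape_features(mask)
    gl = glcm_features(
        region,
        bin_width=config.bin_width_glcm,
        offsets=config.glcm_offsets,
        log_base=config.log_base,
        moment_order=config.glcm_moment_order,
    )
    row = {**fo.as_dict(), **sh.as_dict(), **gl.as_dict()}
    return {name: row[name] for name in FEATURE_NAMES}
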