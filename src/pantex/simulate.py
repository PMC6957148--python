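"""Synthetic pancreas-like CT phantoms and two-group cohorts.

No imaging data ship with the package; this module generates them.  A
phantom is a lobulated ellipsoid mask (elongated like a pancreas: caliper
length ≈ 100–145 mm, volume ≈ 40–70 cm³) on an anisotropic CT grid, filled
with a spatially correlated Gaussian random field whose within-mask mean
and SD are controlled exactly and whose correlation length tunes the
neighbourhood similarity that second-order (GLCM) features measure.

The cohort generator draws per-subject phantom parameters around a control
profile (between-subject SDs included) and applies an *effect profile* of
additive/multiplicative shifts to the case group.  The default
:data:`PAPER_EFFECT_PROFILE` moves the generator in the directions reported
for diabetic pancreata: lower mean attenuation, higher HU variance, reduced
elongation (higher sphericity), and a longer correlation length (lower
GLCM contrast).

Determinism: one master seed; per-subject substreams are derived with
``np.random.SeedSequence(master, spawn_key=(group_index, subject_index))``
so a cohort is bit-reproducible and individual subjects are stable when
``n_per_group`` changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import DEFAULT_CONFIG, RunConfig
from .features import FEATURE_NAMES, extract_features
from .volumes import CTVolume, ROIMask, write_mask, write_volume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "Subject",
    "PAPER_EFFECT_PROFILE",
    "DEFAULT_PHANTOM",
    "REDUCED_PHANTOM",
    "generate_phantom",
    "generate_cohort",
    "realize_subject",
    "simulate_feature_table",
    "write_cohort",
]

BACKGROUND_HU = -1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one pancreas-like phantom.

    half_axes : (a, b, c) mm of the base ellipsoid (a = long axis).
    lobulation_amplitude : relative radial perturbation in [0, 0.5].
    lobulation_count : number of surface bumps.
    mean_hu, sd_hu : within-mask first-order mean and SD of the HU field.
    correlation_length : Gaussian smoothing scale of the noise field, mm.
    spacing : voxel spacing (sx, sy, sz) mm; default mirrors thick-slice
        venous-phase CT (0.7 mm in-plane, 5 mm sections).
    grid_margin : background voxels padded around the shape on each side.
    """

    half_axes: tuple[float, float, float] = (65.0, 22.0, 10.0)
    lobulation_amplitude: float = 0.15
    lobulation_count: int = 12
    mean_hu: float = 110.0
    sd_hu: float = 32.0
    correlation_length: float = 0.7
    spacing: tuple[float, float, float] = (0.7, 0.7, 5.0)
    grid_margin: int = 2

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.half_axes):
            raise ValueError("half_axes must be positive")
        if not 0.0 <= self.lobulation_amplitude <= 0.5:
            raise ValueError("lobulation_amplitude must be in [0, 0.5]")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")


#: study-scale phantom (native CT resolution)
DEFAULT_PHANTOM = PhantomSpec()

#: reduced-resolution phantom for large simulation batteries (coarser
#: in-plane grid, same organ geometry and noise model)
REDUCED_PHANTOM = PhantomSpec(spacing=(1.4, 1.4, 5.0))


def _lobulation_field(u: np.ndarray, directions: np.ndarray, sharpness: float = 10.0) -> np.ndarray:
    """Smooth bump pattern on the unit sphere, centred and scaled to [-1, 1].

    ``u``: (..., 3) unit vectors; ``directions``: (k, 3) bump centres.
    """
    dots = np.tensordot(u, directions.T, axes=1)  # (..., k)
    bumps = np.exp(sharpness * (dots - 1.0)).sum(axis=-1)
    lo, hi = float(bumps.min()), float(bumps.max())
    if hi - lo < 1e-12:
        return np.zeros(bumps.shape)
    g = (bumps - lo) / (hi - lo)  # [0, 1]
    return 2.0 * g - 1.0


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[CTVolume, ROIMask]:
    """Rasterize one lobulated-ellipsoid phantom with correlated HU noise.

    The mask is the set of voxel centres with normalized radius
    ρ ≤ 1 + amplitude·g(û), where g is a seeded bump pattern on the sphere.
    The HU field is white Gaussian noise smoothed at ``correlation_length``
    and affinely renormalized so the within-mask sample mean and SD equal
    ``mean_hu`` and ``sd_hu`` exactly; background is −1000 HU.

    Raises
    ------
    ValueError
        If the shape touches the grid boundary (grid too small).
    """
    rng = np.random.default_rng(seed)
    a, b, c = spec.half_axes
    sx, sy, sz = spec.spacing
    pad = 1.0 + spec.lobulation_amplitude
    shape = tuple(
        int(math.ceil(2.0 * ax * pad / s)) + 2 * spec.grid_margin
        for ax, s in zip((a, b, c), (sx, sy, sz))
    )
    centre = [(n - 1) / 2.0 for n in shape]
    xs = (np.arange(shape[0]) - centre[0]) * sx
    ys = (np.arange(shape[1]) - centre[1]) * sy
    zs = (np.arange(shape[2]) - centre[2]) * sz
    gx, gy, gz = np.meshgrid(xs / a, ys / b, zs / c, indexing="ij")
    norm_coords = np.stack([gx, gy, gz], axis=-1)
    rho = np.linalg.norm(norm_coords, axis=-1)

    if spec.lobulation_amplitude > 0 and spec.lobulation_count > 0:
        directions = rng.standard_normal((spec.lobulation_count, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(rho[..., None] > 0, norm_coords / np.maximum(rho, 1e-12)[..., None], 0.0)
        boundary = 1.0 + spec.lobulation_amplitude * _lobulation_field(u, directions)
    else:
        boundary = np.ones_like(rho)
    fg = rho <= boundary

    if not fg.any():
        raise ValueError("phantom mask is empty; half_axes too small for the grid spacing")
    hull = np.argwhere(fg)
    if (hull.min(axis=0) == 0).any() or (hull.max(axis=0) == np.array(shape) - 1).any():
        raise ValueError("phantom mask touches the grid boundary; increase grid_margin")

    noise = rng.standard_normal(shape)
    if spec.correlation_length > 0:
        sigma_vox = [spec.correlation_length / s for s in spec.spacing]
        noise = gaussian_filter(noise, sigma=sigma_vox, mode="nearest")
    voxels = np.full(shape, BACKGROUND_HU)
    inside = noise[fg]
    if spec.sd_hu == 0 or inside.std() == 0:
        voxels[fg] = spec.mean_hu
    else:
        voxels[fg] = spec.mean_hu + (inside - inside.mean()) / inside.std() * spec.sd_hu

    volume = CTVolume(voxels=voxels, spacing=spec.spacing)
    mask = ROIMask(voxels=fg.astype(np.uint8), spacing=spec.spacing)
    return volume, mask


# ---------------------------------------------------------------------------
# cohorts


#: effect directions of the diabetic group: attenuation down, HU variance
#: up, long axis shortened at constant volume (sphericity up), correlation
#: length up (GLCM contrast down)
PAPER_EFFECT_PROFILE: dict[str, dict[str, float]] = {
    "mean_hu": {"add": -17.1},
    "sd_hu": {"add": 5.2},
    "length_scale": {"mul": 0.93},
    "correlation_length": {"mul": 3.1},
}

#: between-subject means and SDs of the control population; the HU means
#: and SDs follow the control-group summary statistics of a matched
#: non-diabetic cohort, geometry gives ~60 cm³ volume and ~135 mm length
DEFAULT_CONTROL_PROFILE: dict[str, tuple[float, float]] = {
    "mean_hu": (110.3, 20.4),
    "sd_hu": (31.8, 6.1),
    "correlation_length": (0.7, 0.1),
    "length_scale": (1.0, 0.07),
    "thickness_scale": (1.0, 0.06),
    "lobulation_amplitude": (0.15, 0.04),
}

_PROFILE_KEYS = set(DEFAULT_CONTROL_PROFILE)
_BOUNDS = {
    "mean_hu": (-500.0, 500.0),
    "sd_hu": (1.0, 200.0),
    "correlation_length": (0.0, 20.0),
    "length_scale": (0.5, 2.0),
    "thickness_scale": (0.5, 2.0),
    "lobulation_amplitude": (0.0, 0.5),
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a seeded two-group phantom cohort."""

    n_per_group: int = 30
    seed: int = 0
    base_phantom: PhantomSpec = DEFAULT_PHANTOM
    control_profile: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_PROFILE)
    )
    effect_profile: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in PAPER_EFFECT_PROFILE.items()}
    )

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        bad = set(self.control_profile) - _PROFILE_KEYS
        if bad:
            raise ValueError(f"unknown control_profile keys {sorted(bad)}; allowed: {sorted(_PROFILE_KEYS)}")
        bad = set(self.effect_profile) - _PROFILE_KEYS
        if bad:
            raise ValueError(f"unknown effect_profile keys {sorted(bad)}; allowed: {sorted(_PROFILE_KEYS)}")
        for key, eff in self.effect_profile.items():
            if set(eff) - {"add", "mul"}:
                raise ValueError(f"effect for {key!r} must use 'add' and/or 'mul' keys")


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str                 # "case" or "control"
    phantom: PhantomSpec
    phantom_seed: int
    params: dict[str, float]   # the drawn profile parameters


def _draw_params(rng: np.random.Generator, profile: dict[str, tuple[float, float]]) -> dict[str, float]:
    params = {}
    # fixed iteration order keeps the stream stable
    for key in sorted(_PROFILE_KEYS):
        mean, sd = profile.get(key, DEFAULT_CONTROL_PROFILE[key])
        lo, hi = _BOUNDS[key]
        params[key] = float(np.clip(rng.normal(mean, sd), lo, hi))
    return params


def _apply_effect(params: dict[str, float], effect: dict[str, dict[str, float]]) -> dict[str, float]:
    out = dict(params)
    for key, eff in effect.items():
        val = out[key] * eff.get("mul", 1.0) + eff.get("add", 0.0)
        lo, hi = _BOUNDS[key]
        out[key] = float(np.clip(val, lo, hi))
    return out


def _phantom_from_params(base: PhantomSpec, params: dict[str, float]) -> PhantomSpec:
    a, b, c = base.half_axes
    ls, ts = params["length_scale"], params["thickness_scale"]
    return replace(
        base,
        half_axes=(a * ls, b * ts, c * ts),
        lobulation_amplitude=params["lobulation_amplitude"],
        mean_hu=params["mean_hu"],
        sd_hu=params["sd_hu"],
        correlation_length=params["correlation_length"],
    )


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Draw per-subject phantom specs for both groups, in randomized order."""
    subjects: list[Subject] = []
    for group_idx, group in enumerate(("control", "case")):
        for subj_idx in range(spec.n_per_group):
            ss = np.random.SeedSequence(spec.seed, spawn_key=(group_idx, subj_idx))
            rng = np.random.default_rng(ss)
            params = _draw_params(rng, spec.control_profile)
            if group == "case":
                params = _apply_effect(params, spec.effect_profile)
            phantom_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
            subjects.append(
                Subject(
                    subject_id=f"{group[:4]}{subj_idx:03d}",
                    group=group,
                    phantom=_phantom_from_params(spec.base_phantom, params),
                    phantom_seed=phantom_seed,
                    params=params,
                )
            )
    order_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(99,)))
    order = order_rng.permutation(len(subjects))
    return [subjects[i] for i in order]


def realize_subject(subject: Subject) -> tuple[CTVolume, ROIMask]:
    """Generate the subject's CT volume and mask from its stored spec."""
    return generate_phantom(subject.phantom, subject.phantom_seed)


def simulate_feature_table(
    spec: CohortSpec,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort, extract all features, return (table, manifest).

    ``table`` has the CohortTable layout (subject_id, group, 17 features);
    ``manifest`` records each subject's true generator parameters for
    parameter-recovery checks.
    """
    subjects = generate_cohort(spec)
    rows, manifest = [], []
    for s in subjects:
        volume, mask = realize_subject(s)
        feats = extract_features(volume, mask, config)
        rows.append({"subject_id": s.subject_id, "group": s.group, **feats})
        manifest.append(
            {"subject_id": s.subject_id, "group": s.group,
             "phantom_seed": s.phantom_seed, **s.params}
        )
    table = pd.DataFrame(rows, columns=["subject_id", "group", *FEATURE_NAMES])
    return table, pd.DataFrame(manifest)


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write every subject's volume/mask as NIfTI plus a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for s in generate_cohort(spec):
        volume, mask = realize_subject(s)
        vol_path = out / f"{s.subject_id}_ct.nii.gz"
        mask_path = out / f"{s.subject_id}_mask.nii.gz"
        write_volume(volume, vol_path)
        write_mask(mask, mask_path)
        records.append(
            {"subject_id": s.subject_id, "group": s.group,
             "volume_path": vol_path.name, "mask_path": mask_path.name,
             "phantom_seed": s.phantom_seed, **s.params}
        )
    manifest = pd.DataFrame(records)
    manifest.to_csv(out / "manifest.csv", index=False, float_format="%.10g")
    return manifest
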