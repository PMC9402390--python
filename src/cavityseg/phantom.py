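"""Synthetic brain phantoms with known ground-truth resection cavities.

The generator emulates, at desk scale, the imaging substrate the pipeline is
meant for: a brain-like ellipsoid with tissue-intensity bands (cortex ribbon,
white-matter interior, CSF-dark ventricles), a hypointense ellipsoidal cavity
standing in for the CSF-filled resection, optional failure-mode artifacts
(a hyperintense inclusion emulating blood product / ablation necrosis, and a
thin surgical tract from cavity to brain surface), control volumes with no
cavity, and a toy geometric parcellation that includes a designated
"hippocampus" region near the default cavity site.

Everything is deterministic given (spec, seed); the ground-truth mask is by
construction exactly the set of voxels whose intensity was replaced by the
cavity value before noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError
from .volume_io import BinaryMask, Parcellation, VolumeImage

__all__ = [
    "PhantomSpec",
    "DEFAULT_COHORT_RANGES",
    "sample_cohort_specs",
    "generate_phantom",
    "add_artifacts",
    "generate_control",
    "generate_cohort",
    "analytic_region_overlap_pct",
]

# Octant-based region names for the toy parcellation (RAS axes:
# x<0 left / x>=0 right; y>=0 anterior; z>=0 superior).
_OCTANT_NAMES = {
    (0, 1, 1): "frontal_left",
    (1, 1, 1): "frontal_right",
    (0, 1, 0): "temporal_left",
    (1, 1, 0): "temporal_right",
    (0, 0, 1): "parietal_left",
    (1, 0, 1): "parietal_right",
    (0, 0, 0): "occipital_left",
    (1, 0, 0): "occipital_right",
}
HIPPOCAMPUS_LABEL = 9

#: Semi-axes (mm) and position (fractions of the brain semi-axes) of the toy
#: hippocampus; placed lateral-inferior, i.e. at the default cavity site.
_HIPPO_AXES_MM = (9.0, 7.0, 6.0)
_HIPPO_CENTER_FRAC = (0.45, -0.15, -0.1)


@dataclass
class PhantomSpec:
    """Full description of one synthetic phantom.

    Intensities are on the [0, 1] scale used throughout the pipeline; all
    lengths are in mm.  ``cavity_center_frac`` positions the cavity center as
    fractions of the brain ellipsoid semi-axes (0 = brain center).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_axes_mm: tuple[float, float, float] = (26.0, 30.0, 24.0)
    tissue_levels: dict[str, float] = field(
        default_factory=lambda: {"cortex": 0.55, "white": 0.75, "ventricle": 0.2}
    )
    cavity_center_frac: tuple[float, float, float] = (0.45, -0.15, -0.1)
    cavity_radius_mm: float | tuple[float, float, float] = 10.0
    cavity_intensity: float = 0.05
    noise_sd: float = 0.03
    artifact_flags: dict[str, bool] = field(
        default_factory=lambda: {"hyperintense_inclusion": False, "surgical_tract": False}
    )
    seed: int = 0

    @property
    def cavity_axes_mm(self) -> tuple[float, float, float]:
        r = self.cavity_radius_mm
        if np.isscalar(r):
            return (float(r),) * 3  # type: ignore[return-value]
        return tuple(float(v) for v in r)  # type: ignore[return-value]

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing_mm) or any(n < 8 for n in self.grid_shape):
            raise SpecError("grid must be at least 8 voxels per axis with positive spacing")
        if any(a <= 0 for a in self.brain_axes_mm):
            raise SpecError("brain semi-axes must be positive")
        axes = self.cavity_axes_mm
        if any(a < 0 for a in axes):
            raise SpecError(f"cavity radius must be non-negative, got {axes}")
        bad = [v for v in self.tissue_levels.values() if not 0 < v <= 1]
        if bad or not 0 <= self.cavity_intensity <= 1:
            raise SpecError("intensities must lie in [0, 1] before noise")
        if max(axes) > 0:
            # conservative containment check in brain-normalized coordinates
            center_norm = float(np.linalg.norm(self.cavity_center_frac))
            reach = max(a / b for a, b in zip(axes, self.brain_axes_mm))
            if center_norm + reach > 1.0:
                raise SpecError(
                    f"cavity (center fraction norm {center_norm:.2f}, normalized reach "
                    f"{reach:.2f}) does not fit inside the brain ellipsoid"
                )


def _grid_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Physical coordinates (mm) of voxel centers, origin at grid center."""
    axes = [
        (np.arange(n, dtype=np.float64) - (n - 1) / 2.0) * s
        for n, s in zip(spec.grid_shape, spec.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")  # type: ignore[return-value]


def _affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.diag(list(spec.spacing_mm) + [1.0])
    aff[:3, 3] = [-(n - 1) / 2.0 * s for n, s in zip(spec.grid_shape, spec.spacing_mm)]
    return aff


def _ellipsoid(coords, center_mm, axes_mm) -> np.ndarray:
    q = sum(((c - m) / a) ** 2 for c, m, a in zip(coords, center_mm, axes_mm))
    return q <= 1.0


def _cavity_center_mm(spec: PhantomSpec) -> np.ndarray:
    return np.asarray(spec.cavity_center_frac) * np.asarray(spec.brain_axes_mm)


def _build_noiseless(spec: PhantomSpec):
    """Noise-free intensity field, brain mask, cavity mask."""
    coords = _grid_mm(spec)
    zero = (0.0, 0.0, 0.0)
    brain = _ellipsoid(coords, zero, spec.brain_axes_mm)
    rho2 = sum((c / a) ** 2 for c, a in zip(coords, spec.brain_axes_mm))

    vol = np.zeros(spec.grid_shape, dtype=np.float32)
    vol[brain] = spec.tissue_levels["white"]
    vol[brain & (rho2 > 0.85**2)] = spec.tissue_levels["cortex"]
    # two small para-median ventricles
    for sx in (-1.0, 1.0):
        vent = _ellipsoid(coords, (sx * 7.0, 5.0, 4.0), (4.0, 10.0, 6.0))
        vol[vent & brain] = spec.tissue_levels["ventricle"]

    axes = spec.cavity_axes_mm
    if max(axes) > 0:
        cavity = _ellipsoid(coords, _cavity_center_mm(spec), axes)
    else:
        cavity = np.zeros(spec.grid_shape, dtype=bool)
    vol[cavity] = spec.cavity_intensity
    return vol, brain, cavity


def _build_parcellation(spec: PhantomSpec, brain: np.ndarray) -> Parcellation:
    coords = _grid_mm(spec)
    octant = (
        1
        + (coords[0] >= 0).astype(np.int32)
        + 2 * (coords[1] >= 0).astype(np.int32)
        + 4 * (coords[2] >= 0).astype(np.int32)
    )
    data = np.where(brain, octant, 0).astype(np.int32)
    hippo_center = np.asarray(_HIPPO_CENTER_FRAC) * np.asarray(spec.brain_axes_mm)
    hippo = _ellipsoid(coords, hippo_center, _HIPPO_AXES_MM) & brain
    data[hippo] = HIPPOCAMPUS_LABEL
    labels = {
        1 + xs + 2 * ys + 4 * zs: _OCTANT_NAMES[(xs, ys, zs)]
        for xs in (0, 1)
        for ys in (0, 1)
        for zs in (0, 1)
    }
    labels[HIPPOCAMPUS_LABEL] = "hippocampus"
    return Parcellation(data=data, affine=_affine(spec), labels=labels)


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, BinaryMask, Parcellation]:
    """Generate one phantom: image, ground-truth cavity mask, parcellation.

    The returned mask is exactly the voxel set whose intensity was set to
    ``cavity_intensity`` before additive noise; for a nonzero radius it is a
    single 26-connected ellipsoid.  Artifacts are *not* applied here; see
    :func:`add_artifacts`.
    """
    spec.validate()
    vol, brain, cavity = _build_noiseless(spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = np.clip(
            vol + rng.normal(0.0, spec.noise_sd, size=vol.shape).astype(np.float32),
            0.0,
            1.0,
        )
    aff = _affine(spec)
    return (
        VolumeImage(data=vol.astype(np.float32), affine=aff),
        BinaryMask(data=cavity.astype(np.uint8), affine=aff),
        _build_parcellation(spec, brain),
    )


def add_artifacts(
    vol: VolumeImage, mask: BinaryMask, spec: PhantomSpec
) -> tuple[VolumeImage, BinaryMask]:
    """Apply the requested failure-mode artifacts to a phantom.

    ``hyperintense_inclusion`` places a bright blob (intensity 0.95, above
    every tissue level) strictly inside the cavity mask.  ``surgical_tract``
    draws a thin (1-voxel-radius) hypointense tube from the cavity surface to
    the brain surface and *adds* the tube voxels to the ground-truth mask,
    matching the manual-segmentation convention for tracts.

    Returns new (volume, mask) objects; inputs are not modified.
    """
    flags = spec.artifact_flags
    data = vol.data.copy()
    mdata = mask.data.copy().astype(bool)
    coords = _grid_mm(spec)
    brain = _ellipsoid(coords, (0.0, 0.0, 0.0), spec.brain_axes_mm)

    if flags.get("hyperintense_inclusion"):
        if not mdata.any():
            raise SpecError("hyperintense inclusion requested but cavity mask is empty")
        center = _cavity_center_mm(spec)
        inner = tuple(max(a * 0.4, 1.0) for a in spec.cavity_axes_mm)
        blob = _ellipsoid(coords, center, inner) & mdata
        if not blob.any():  # cavity too small for an interior blob: use its center voxel
            idx = np.unravel_index(
                np.argmin(sum((c - m) ** 2 for c, m in zip(coords, center))), data.shape
            )
            blob = np.zeros_like(mdata)
            blob[idx] = mdata[idx]
        data[blob] = 0.95

    if flags.get("surgical_tract"):
        if not mdata.any():
            raise SpecError("surgical tract requested but cavity mask is empty")
        center = _cavity_center_mm(spec)
        direction = center.copy()
        if np.linalg.norm(direction) < 1e-9:
            direction = np.array([1.0, 0.0, 0.0])
        direction /= np.linalg.norm(direction)
        # segment from cavity center out to just past the brain ellipsoid surface
        b = np.asarray(spec.brain_axes_mm)
        # solve ||(center + t*d)/b||^2 = 1 for t > 0
        dn, cn = direction / b, center / b
        a2, a1, a0 = dn @ dn, 2 * dn @ cn, cn @ cn - 1.0
        t = (-a1 + np.sqrt(a1**2 - 4 * a2 * a0)) / (2 * a2)
        end = center + (t + 2.0) * direction
        # distance of every voxel center to the segment [center, end]
        pts = np.stack([c.ravel() for c in coords], axis=1)
        seg = end - center
        proj = np.clip((pts - center) @ seg / (seg @ seg), 0.0, 1.0)
        nearest = center + proj[:, None] * seg
        dist = np.linalg.norm(pts - nearest, axis=1).reshape(data.shape)
        tube = (dist <= max(spec.spacing_mm)) & brain
        data[tube & ~mdata] = spec.cavity_intensity
        mdata |= tube

    return (
        VolumeImage(data=data, affine=vol.affine.copy()),
        BinaryMask(data=mdata.astype(np.uint8), affine=mask.affine.copy()),
    )


def generate_control(spec: PhantomSpec) -> VolumeImage:
    """A cavity-free brain phantom (same noise realization as ``spec`` would give)."""
    ctrl_spec = dataclasses.replace(spec, cavity_radius_mm=0.0)
    vol, _, _ = generate_phantom(ctrl_spec)
    return vol


#: Default cohort sampling ranges: cavity radii 7–18 mm give true volumes of
#: roughly 1.4–24.4 ml, spanning both sides of the 17.92 ml size-stratification
#: threshold and the 0.5 ml detection-screening threshold with a wide margin.
DEFAULT_COHORT_RANGES: dict = {"cavity_radius_mm": (7.0, 18.0)}


def sample_cohort_specs(
    n: int,
    spec_ranges: dict | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[PhantomSpec, str]]:
    """Draw ``n`` (spec, subject_id) pairs with cavity size/position from ranges.

    ``spec_ranges`` may contain ``cavity_radius_mm: (lo, hi)`` and
    ``artifact_p: {flag: probability}``.  Subject ids are unique and the
    draw is reproducible from ``seed``.
    """
    if n < 1:
        raise SpecError("cohort size must be >= 1")
    ranges = dict(DEFAULT_COHORT_RANGES)
    if spec_ranges:
        ranges.update(spec_ranges)
    lo, hi = ranges["cavity_radius_mm"]
    if lo > hi or lo < 0:
        raise SpecError(f"invalid cavity radius range ({lo}, {hi})")
    artifact_p = ranges.get("artifact_p", {})
    base = base_spec or PhantomSpec()

    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        r = float(rng.uniform(lo, hi))
        # keep the cavity inside the brain with a 5% normalized margin
        cmax = max(0.0, (1.0 - r / min(base.brain_axes_mm) - 0.05)) / np.sqrt(3.0)
        frac = tuple(float(rng.uniform(-cmax, cmax)) for _ in range(3))
        flags = {
            flag: bool(rng.random() < p) for flag, p in artifact_p.items()
        }
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        spec = dataclasses.replace(
            base,
            cavity_radius_mm=r,
            cavity_center_frac=frac,
            artifact_flags={**base.artifact_flags, **flags},
            seed=sub_seed,
        )
        out.append((spec, f"sub-{i:03d}"))
    return out


def generate_cohort(
    n: int,
    spec_ranges: dict | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[VolumeImage, BinaryMask, Parcellation, str]]:
    """Generate ``n`` phantoms with cavity size/position drawn from ranges.

    See :func:`sample_cohort_specs` for the sampling scheme; artifacts are
    applied for subjects whose sampled flags are set.
    """
    out = []
    for spec, sid in sample_cohort_specs(n, spec_ranges, seed, base_spec):
        vol, mask, parc = generate_phantom(spec)
        if any(spec.artifact_flags.values()):
            vol, mask = add_artifacts(vol, mask, spec)
        out.append((vol, mask, parc, sid))
    return out


def analytic_region_overlap_pct(
    spec: PhantomSpec,
    region_center_frac=_HIPPO_CENTER_FRAC,
    region_axes_mm=_HIPPO_AXES_MM,
    oversample: int = 4,
) -> float:
    """Percent of a parcellation region's volume covered by the cavity,
    computed from the continuous ellipsoid geometry on an ``oversample``-times
    finer grid (independent of the phantom voxelization)."""
    fine = dataclasses.replace(
        spec,
        grid_shape=tuple(int(n) * oversample for n in spec.grid_shape),
        spacing_mm=tuple(s / oversample for s in spec.spacing_mm),
    )
    coords = _grid_mm(fine)
    brain = _ellipsoid(coords, (0.0, 0.0, 0.0), fine.brain_axes_mm)
    center = np.asarray(region_center_frac) * np.asarray(fine.brain_axes_mm)
    region = _ellipsoid(coords, center, region_axes_mm) & brain
    axes = fine.cavity_axes_mm
    if max(axes) == 0 or not region.any():
        return 0.0
    cavity = _ellipsoid(coords, _cavity_center_mm(fine), axes)
    return 100.0 * float((region & cavity).sum()) / float(region.sum())
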