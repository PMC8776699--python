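"""Synthetic spine phantom: paired planning-CT / CT-myelogram with ground truth.

The study's patient scans are not public, so the pipeline is exercised on a
digital phantom that reproduces the features the registration actually relies
on: a stack of vertebral bodies and posterior arches at bone HU around a
spinal canal holding cord and CSF, bilateral pedicle screws (metal HU) at the
fixation levels above and below the lesion, a lytic lesion where tumour has
replaced bone with soft tissue, Gaussian CT noise, and a known rigid
misalignment between the two volumes.  The myelogram differs from the planning
CT only in its CSF intensity: intrathecal iodinated contrast raises the CSF
from near-water to several hundred HU, which is the entire clinical point of
the second scan.

The generator is deterministic given ``(spec, seed)`` and returns, besides the
two volumes, a :class:`PhantomTruth` holding the true transform, per-structure
masks and the craniocaudal extent of every vertebral level — the ground truth
the tests and the acceptance run measure against.

Anatomy is straight (no spinal curvature) and there is no metal-artifact
streak model; the contour restriction is exercised purely by geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .geometry import RigidTransform, invert, make_rigid
from .io_formats import AIR_HU, ImageVolume

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom_pair", "apply_rigid_resample"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue HU palette and noise model of one phantom pair.

    HU defaults: soft tissue 40, trabecular/cortical bone 700, implant metal
    3000, cord 30, plain CSF 15, contrast-enhanced CSF 600 (iohexol), air
    -1000.  Grid defaults mirror the study's acquisition: in-plane 1.074 mm,
    1 mm slices.
    """

    n_levels: int = 8
    level_height: float = 20.0  # mm per vertebral level (body + disc space)
    lesion_levels: tuple[int, ...] = (3,)
    fixation_extent: int = 2  # instrumented levels above/below the lesion
    hu_soft: float = 40.0
    hu_bone: float = 700.0
    hu_metal: float = 3000.0
    hu_cord: float = 30.0
    hu_csf_plain: float = 15.0
    hu_csf_contrast: float = 600.0
    noise_sd: float = 15.0
    true_transform: RigidTransform = field(default_factory=make_rigid)
    spacing: tuple[float, float, float] = (1.074, 1.074, 1.0)
    grid_xy: int = 96
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 1 or self.level_height <= 0 or self.grid_xy < 16:
            raise InvalidParameterError("degenerate phantom geometry")
        if not self.lesion_levels or not all(
            0 <= lv < self.n_levels for lv in self.lesion_levels
        ):
            raise InvalidParameterError(
                f"lesion levels {self.lesion_levels} outside [0, {self.n_levels})"
            )
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not (
            self.hu_metal > self.hu_bone > self.hu_csf_contrast > self.hu_soft > self.hu_cord
        ):
            raise InvalidParameterError(
                "tissue HU must satisfy metal > bone > contrast CSF > soft > cord"
            )
        if any(s <= 0 for s in self.spacing):
            raise InvalidParameterError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        nz = int(round(self.n_levels * self.level_height / self.spacing[2]))
        return (self.grid_xy, self.grid_xy, nz)

    def with_transform(self, t: RigidTransform) -> "PhantomSpec":
        return replace(self, true_transform=t)


@dataclass
class PhantomTruth:
    """Ground truth: the applied misalignment, structure masks, level extents."""

    true_transform: RigidTransform
    structure_masks: dict[str, np.ndarray]
    level_boundaries: list[tuple[float, float]]
    volume_center_mm: np.ndarray


# fixed anatomical layout (mm, relative to the volume's x-center)
_BODY_Y = 40.0      # vertebral body center, anterior
_BODY_R0 = 12.0     # body radius of the topmost level ...
_BODY_R_STEP = 0.8  # ... growing caudally, as real vertebrae do (breaks the
                    # craniocaudal periodicity that would alias registration)
_CANAL_Y = 62.0     # spinal canal center, posterior to the body
_CANAL_R = 5.5
_CORD_R = 2.5
_ARCH_R = 11.0      # outer radius of the posterior arch annulus
_DISC_GAP = 4.0     # soft-tissue gap between adjacent bodies
_SCREW_DX = 9.0     # bilateral pedicle-screw offset from midline
_SCREW_R = 2.0
_SCREW_Y = (44.0, 70.0)  # screw extent along AP, arch through body


def _fixation_levels(spec: PhantomSpec) -> set[int]:
    """Instrumented levels: fixation_extent above and below the lesion span."""
    lo, hi = min(spec.lesion_levels), max(spec.lesion_levels)
    levels = set(range(lo - spec.fixation_extent, lo)) | set(
        range(hi + 1, hi + 1 + spec.fixation_extent)
    )
    return {lv for lv in levels if 0 <= lv < spec.n_levels}


def _render(spec: PhantomSpec):
    """Noise-free anatomy plus exclusive structure masks, on the primary grid."""
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    x = np.arange(nx)[:, None, None] * sx
    y = np.arange(ny)[None, :, None] * sy
    z = np.arange(nz)[None, None, :] * sz
    cx = (nx - 1) * sx / 2.0

    body_ellipse = ((x - cx) / 45.0) ** 2 + ((y - 52.0) / 40.0) ** 2 <= 1.0

    in_level_body = np.zeros((1, 1, nz), dtype=bool)
    body = np.zeros((nx, ny, nz), dtype=bool)
    boundaries: list[tuple[float, float]] = []
    r2_body = (x - cx) ** 2 + (y - _BODY_Y) ** 2
    for lv in range(spec.n_levels):
        z0, z1 = lv * spec.level_height, (lv + 1) * spec.level_height
        boundaries.append((z0, z1))
        in_this = (z >= z0 + _DISC_GAP / 2) & (z < z1 - _DISC_GAP / 2)
        in_level_body |= in_this
        r_body = _BODY_R0 + _BODY_R_STEP * lv
        body |= (r2_body <= r_body**2) & in_this

    r2_canal = (x - cx) ** 2 + (y - _CANAL_Y) ** 2
    arch = (r2_canal >= _CANAL_R**2) & (r2_canal <= _ARCH_R**2) & in_level_body
    canal = np.broadcast_to(r2_canal < _CANAL_R**2, (nx, ny, nz)).copy()
    cord = np.broadcast_to(r2_canal < _CORD_R**2, (nx, ny, nz)).copy()
    csf = canal & ~cord
    bone = (body | arch) & ~canal

    metal = np.zeros((nx, ny, nz), dtype=bool)
    in_screw_y = (y >= _SCREW_Y[0]) & (y <= _SCREW_Y[1])
    for lv in sorted(_fixation_levels(spec)):
        zmid = (lv + 0.5) * spec.level_height
        for sign in (-1.0, 1.0):
            r2_screw = (x - (cx + sign * _SCREW_DX)) ** 2 + (z - zmid) ** 2
            metal |= (r2_screw <= _SCREW_R**2) & in_screw_y

    # lytic lesion: seeded spherical blob of soft tissue carved out of the bone
    rng = np.random.default_rng([spec.seed, 9173])
    lesion = np.zeros((nx, ny, nz), dtype=bool)
    for lv in sorted(spec.lesion_levels):
        zmid = (lv + 0.5) * spec.level_height
        ctr = np.array([cx, _BODY_Y, zmid]) + rng.uniform(-1, 1, 3) * (6.0, 6.0, 4.0)
        rad = rng.uniform(6.0, 9.0)
        blob = ((x - ctr[0]) ** 2 + (y - ctr[1]) ** 2 + (z - ctr[2]) ** 2) <= rad**2
        # the lytic defect belongs to this vertebra: clip to its CC extent
        z0, z1 = boundaries[lv]
        lesion |= blob & (z >= z0) & (z < z1)

    bone &= ~lesion
    bone &= ~metal
    cord &= ~metal
    csf &= ~metal

    hu = np.full((nx, ny, nz), AIR_HU, dtype=np.float32)
    hu[body_ellipse & np.ones((1, 1, nz), dtype=bool)] = spec.hu_soft
    hu[bone] = spec.hu_bone
    hu[csf] = spec.hu_csf_plain
    hu[cord] = spec.hu_cord
    hu[metal] = spec.hu_metal

    masks = {"bone": bone, "hardware": metal, "cord": cord, "csf": csf}
    center = np.array([(nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz]) / 2.0
    return hu, masks, boundaries, center


def apply_rigid_resample(
    vol: ImageVolume, t: RigidTransform, interpolation: str = "trilinear"
) -> ImageVolume:
    """Resample a volume under a rigid transform, on the same grid.

    Each output voxel at physical position ``p`` takes the value of ``vol`` at
    ``t^{-1}(p)``; samples falling outside the volume are filled with air
    (-1000 HU).
    """
    orders = {"nearest": 0, "trilinear": 1}
    if interpolation not in orders:
        raise InvalidParameterError(
            f"unknown interpolation {interpolation!r}; expected one of {sorted(orders)}"
        )
    nx, ny, nz = vol.shape
    idx = np.indices((nx, ny, nz), dtype=float).reshape(3, -1).T
    pts = vol.voxel_centers_mm(idx)
    src = vol.mm_to_index(invert(t).apply(pts))
    out = ndimage.map_coordinates(
        vol.voxels, src.T, order=orders[interpolation], mode="constant", cval=AIR_HU
    ).reshape(nx, ny, nz)
    return ImageVolume(out, vol.spacing.copy(), vol.origin.copy())


def generate_phantom_pair(
    spec: PhantomSpec,
) -> tuple[ImageVolume, ImageVolume, PhantomTruth]:
    """Generate a (planning CT, CT-myelogram, truth) triple.

    The planning CT is the rendered anatomy with plain CSF plus Gaussian noise.
    The myelogram is the same anatomy with contrast-enhanced CSF, resampled
    under ``spec.true_transform`` (trilinear) to realize the known
    misalignment, plus independent Gaussian noise.  Identical spec (including
    seed) gives bit-identical volumes.
    """
    hu, masks, boundaries, center = _render(spec)
    spacing = np.asarray(spec.spacing, dtype=float)

    primary_hu = hu.copy()
    secondary_hu = hu.copy()
    secondary_hu[masks["csf"]] = spec.hu_csf_contrast

    secondary_vol = apply_rigid_resample(
        ImageVolume(secondary_hu, spacing), spec.true_transform, "trilinear"
    )

    if spec.noise_sd > 0:
        rng_p = np.random.default_rng([spec.seed, 1])
        rng_s = np.random.default_rng([spec.seed, 2])
        primary_hu = primary_hu + rng_p.normal(0, spec.noise_sd, hu.shape).astype(np.float32)
        secondary_vol.voxels += rng_s.normal(0, spec.noise_sd, hu.shape).astype(np.float32)

    primary = ImageVolume(primary_hu, spacing)
    truth = PhantomTruth(
        true_transform=spec.true_transform,
        structure_masks=masks,
        level_boundaries=boundaries,
        volume_center_mm=center,
    )
    return primary, secondary_vol, truth
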