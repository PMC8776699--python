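"""Automatic landmark-contour extraction.

The contour-focused registration does not compare whole images: its similarity
metric is restricted to a mask covering the registration landmarks — the
lesioned vertebrae and the surgical hardware — following the in-house
protocol:

* lesion limited to one or two vertebrae: extend the landmarks by one
  vertebral level on each side (3-4 vertebrae in total, capturing the intact
  bone and the pedicle screws above/below);
* lesion spanning three or more vertebrae: the lesioned vertebrae themselves.

Vertebral level identification is deliberately not automated here: level
boundaries arrive in the lesion annotation, and the mask is built on the
primary (planning CT) grid by HU thresholding within the selected levels'
craniocaudal range, followed by morphological closing and dilation.  A single
threshold captures both landmarks because implant metal sits far above
cortical bone, which sits above every soft tissue; the default (650 HU) also
exceeds iohexol-enhanced CSF so contrast can never leak into a landmark mask
even if one were extracted from a myelogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ExtractionFailureError, InvalidAnnotationError
from .io_formats import ImageVolume

__all__ = [
    "ContourMask",
    "LesionAnnotation",
    "select_landmark_levels",
    "extract_landmark_mask",
]

DEFAULT_HU_THRESHOLD = 650.0
DEFAULT_DILATION_MM = 2.0
DEFAULT_CLOSING_MM = 1.0


@dataclass
class ContourMask:
    """Binary landmark mask on the primary grid."""

    mask: np.ndarray
    level_range: tuple[float, float]  # CC extent covered (mm, incl. dilation margin)
    voxel_count: int

    def centroid_mm(self, vol: ImageVolume) -> np.ndarray:
        idx = np.argwhere(self.mask)
        return vol.voxel_centers_mm(idx).mean(axis=0)


@dataclass(frozen=True)
class LesionAnnotation:
    """Which vertebral levels are treated, and where each level sits along CC."""

    lesion_levels: tuple[int, ...]
    level_boundaries_mm: tuple[tuple[float, float], ...]

    @classmethod
    def from_json(cls, path) -> "LesionAnnotation":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(int(v) for v in d["lesion_levels"]),
            tuple((float(a), float(b)) for a, b in d["level_boundaries_mm"]),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "lesion_levels": list(self.lesion_levels),
                    "level_boundaries_mm": [list(b) for b in self.level_boundaries_mm],
                },
                indent=2,
            )
            + "\n"
        )


def select_landmark_levels(lesion_levels, n_levels: int) -> set[int]:
    """Apply the landmark-extension protocol (see module docstring)."""
    levels = sorted(set(int(lv) for lv in lesion_levels))
    if not levels:
        raise InvalidAnnotationError("empty lesion level set")
    if any(lv < 0 or lv >= n_levels for lv in levels):
        raise InvalidAnnotationError(f"lesion levels {levels} outside [0, {n_levels})")
    if levels != list(range(levels[0], levels[-1] + 1)):
        raise InvalidAnnotationError(f"lesion levels must be contiguous, got {levels}")
    if len(levels) <= 2:
        extended = set(levels) | {levels[0] - 1, levels[-1] + 1}
        return {lv for lv in extended if 0 <= lv < n_levels}
    return set(levels)


def extract_landmark_mask(
    ct: ImageVolume,
    levels,
    level_boundaries,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
    dilation_mm: float = DEFAULT_DILATION_MM,
    closing_mm: float = DEFAULT_CLOSING_MM,
) -> ContourMask:
    """Threshold bone+hardware within the selected levels' CC range.

    The raw mask (HU >= threshold, CC position inside the union of the
    selected levels' ranges) is morphologically closed by ``closing_mm`` so
    thin cortical shells survive noise, then dilated by ``dilation_mm`` to add
    a safety margin of adjacent context.  Raises
    :class:`ExtractionFailureError` when nothing exceeds the threshold —
    typically a wrong threshold or an empty field of view.
    """
    levels = sorted(set(int(lv) for lv in levels))
    if not levels or any(lv < 0 or lv >= len(level_boundaries) for lv in levels):
        raise InvalidAnnotationError(
            f"levels {levels} invalid against {len(level_boundaries)} boundaries"
        )
    z0 = min(level_boundaries[lv][0] for lv in levels)
    z1 = max(level_boundaries[lv][1] for lv in levels)

    z_mm = ct.origin[2] + np.arange(ct.shape[2]) * ct.spacing[2]
    in_range = (z_mm >= z0) & (z_mm < z1)
    mask = (ct.voxels >= hu_threshold) & in_range[None, None, :]
    if not mask.any():
        raise ExtractionFailureError(
            f"no voxels >= {hu_threshold} HU within CC range [{z0}, {z1}) mm"
        )

    def ball(radius_mm: float) -> np.ndarray | None:
        r_vox = radius_mm / ct.spacing
        if np.all(r_vox < 0.5):
            return None
        half = np.maximum(np.floor(r_vox).astype(int), 0)
        grids = np.ogrid[tuple(slice(-h, h + 1) for h in half)]
        dist2 = sum(
            (g * s) ** 2 for g, s in zip(grids, ct.spacing)
        )
        return dist2 <= radius_mm**2

    if (selem := ball(closing_mm)) is not None:
        mask = ndimage.binary_closing(mask, structure=selem)
    if (selem := ball(dilation_mm)) is not None:
        mask = ndimage.binary_dilation(mask, structure=selem)

    return ContourMask(
        mask=mask,
        level_range=(z0 - dilation_mm, z1 + dilation_mm),
        voxel_count=int(mask.sum()),
    )
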