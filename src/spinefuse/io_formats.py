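"""Volume, mask and table I/O.

Volumes live in memory as :class:`ImageVolume`: a 3-D float32 array of HU
values indexed ``(x, y, z)`` in the LPS patient frame, plus voxel spacing (mm)
and the mm position of the center of voxel ``(0, 0, 0)``.  On disk the sole
supported container is NIfTI-1 (read and written through nibabel); NIfTI
affines are RAS-based, so axes are flipped on the way in and out to keep the
internal frame LPS.  Oblique acquisitions are rejected rather than silently
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError, VolumeIOError

__all__ = ["ImageVolume", "read_volume", "write_volume", "write_results_table"]

AIR_HU = -1000.0


@dataclass
class ImageVolume:
    """3-D scalar grid of HU values with spacing/origin metadata (LPS frame)."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame: str = "LPS"

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise FormatError(f"volume must be 3-D, got {vox.ndim}-D")
        if any(s < 2 for s in vox.shape):
            raise FormatError(f"each axis needs >= 2 voxels, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise InvalidParameterError("volume contains non-finite HU values")
        self.voxels = np.ascontiguousarray(vox, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise InvalidParameterError(f"spacing must be 3 positive mm: {self.spacing}")
        if self.origin.shape != (3,) or not np.all(np.isfinite(self.origin)):
            raise InvalidParameterError(f"invalid origin: {self.origin}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_centers_mm(self, index_array: np.ndarray) -> np.ndarray:
        """Physical LPS positions (mm) of an (N, 3) array of voxel indices."""
        return self.origin + np.asarray(index_array, dtype=float) * self.spacing

    def mm_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of an (N, 3) array of mm points."""
        return (np.asarray(points_mm, dtype=float) - self.origin) / self.spacing


def _lps_affine(vol: ImageVolume, nx: int, ny: int) -> np.ndarray:
    """RAS affine for the x/y-flipped array written to NIfTI."""
    sx, sy, sz = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    # voxel (0,0,0) of the flipped array is internal voxel (nx-1, ny-1, 0);
    # RAS = (-L, -P, S)
    affine[0, 3] = -(vol.origin[0] + (nx - 1) * sx)
    affine[1, 3] = -(vol.origin[1] + (ny - 1) * sy)
    affine[2, 3] = vol.origin[2]
    return affine


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI-1.

    Values that are integral and fit in int16 are stored as signed 16-bit
    (exact for HU in the clinical range, air at -1000 included); anything else
    is stored as float32.
    """
    data = vol.voxels[::-1, ::-1, :]  # LPS -> RAS axis orientation
    integral = np.all(data == np.round(data)) and np.all(np.abs(data) < 32767)
    out = np.round(data).astype(np.int16) if integral else data.astype(np.float32)
    img = nib.Nifti1Image(out, _lps_affine(vol, *vol.shape[:2]))
    img.header.set_zooms(tuple(vol.spacing))
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise VolumeIOError(f"cannot write volume to {path}: {exc}") from exc


def read_volume(path) -> ImageVolume:
    """Read a NIfTI-1 volume into the internal LPS frame.

    Axis-aligned acquisitions in any of the 48 canonical orientations are
    reoriented; oblique affines raise :class:`FormatError`.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError as exc:
        raise VolumeIOError(f"volume not found: {path}") from exc
    except Exception as exc:  # nibabel raises its own hierarchy
        raise FormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise FormatError(f"expected a 3-D image, got shape {img.shape}: {path}")
    try:
        canon = nib.as_closest_canonical(img)  # reorient to +R +A +S
    except Exception as exc:
        raise FormatError(f"unsupported orientation in {path}: {exc}") from exc
    affine = canon.affine
    rot = affine[:3, :3]
    if np.max(np.abs(rot - np.diag(np.diag(rot)))) > 1e-4 * np.max(np.abs(np.diag(rot))):
        raise FormatError(
            f"oblique orientation not supported (off-diagonal affine) in {path}: "
            f"orientation codes {nib.orientations.aff2axcodes(img.affine)}"
        )
    data = np.asarray(canon.dataobj, dtype=np.float32)
    spacing = np.abs(np.diag(rot))
    # RAS position of canonical voxel (0,0,0); internal (0,0,0) after flip is
    # canonical (nx-1, ny-1, 0)
    nx, ny = data.shape[:2]
    origin = np.array(
        [
            -(affine[0, 3] + (nx - 1) * spacing[0]),
            -(affine[1, 3] + (ny - 1) * spacing[1]),
            affine[2, 3],
        ]
    )
    return ImageVolume(data[::-1, ::-1, :], spacing, origin)


def write_results_table(records, path) -> None:
    """Write a list of flat record dicts (shared schema) as a headed CSV."""
    records = list(records)
    if not records:
        raise InvalidParameterError("no records to write")
    keys = list(records[0].keys())
    for rec in records:
        if list(rec.keys()) != keys:
            raise InvalidParameterError("records do not share a schema")
    try:
        pd.DataFrame.from_records(records, columns=keys).to_csv(
            path, index=False, float_format="%.17g"
        )
    except OSError as exc:
        raise VolumeIOError(f"cannot write table to {path}: {exc}") from exc
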