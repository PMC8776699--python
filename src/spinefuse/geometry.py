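"""Rigid transforms in patient (LPS) coordinates.

A :class:`RigidTransform` is the 6-DOF object both registrations produce: three
translations in mm along the left-right (LR, x), anterior-posterior (AP, y) and
craniocaudal (CC, z) patient axes, and three rotations in degrees in the axial
(about z), coronal (about y) and sagittal (about x) planes, applied about a
stated rotation center.

Conventions, fixed and documented here once:

* Patient frame is LPS: +x = patient left, +y = posterior, +z = superior.
* Euler angles are intrinsic, applied axial (z) first, then coronal (y), then
  sagittal (x); the composed matrix is ``Rz @ Ry @ Rx``.  At the sub-degree
  rotations this package reports, the ordering effect is O(theta^2) and
  numerically irrelevant, but it must be pinned for reproducibility.
* A transform acts on a point p as ``R @ (p - center) + center + t``.

Angles are stored in degrees because that is how clinical systems report them;
all trigonometry is delegated to :class:`scipy.spatial.transform.Rotation`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidParameterError

__all__ = [
    "RigidTransform",
    "TransformError",
    "make_rigid",
    "compose",
    "invert",
    "decompose_difference",
    "read_transform",
    "write_transform",
]

#: intrinsic Euler order: axial (z) -> coronal (y) -> sagittal (x)
EULER_ORDER = "ZYX"
FRAME = "LPS"


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid transform; translations in mm, rotations in degrees."""

    tx: float
    ty: float
    tz: float
    rx: float
    ry: float
    rz: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        params = (self.tx, self.ty, self.tz, self.rx, self.ry, self.rz)
        if not all(np.isfinite(params)):
            raise InvalidParameterError(f"non-finite transform parameters: {params}")
        center = np.asarray(self.center, dtype=float)
        if center.shape != (3,) or not np.all(np.isfinite(center)):
            raise InvalidParameterError(f"invalid rotation center: {self.center}")
        object.__setattr__(self, "center", center)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    @property
    def angles_deg(self) -> np.ndarray:
        """(rx, ry, rz) in degrees."""
        return np.array([self.rx, self.ry, self.rz], dtype=float)

    def rotation_matrix(self) -> np.ndarray:
        """3x3 orthonormal matrix, intrinsic z-y-x composition."""
        return Rotation.from_euler(
            EULER_ORDER, [self.rz, self.ry, self.rx], degrees=True
        ).as_matrix()

    def as_matrix_offset(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (R, o) such that the action is ``p -> R @ p + o``."""
        rot = self.rotation_matrix()
        offset = self.center - rot @ self.center + self.translation
        return rot, offset

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) or (3,) array of mm points."""
        rot, offset = self.as_matrix_offset()
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ rot.T + offset
        return out[0] if np.ndim(points) == 1 else out

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(
            np.all(np.abs(self.translation) <= tol)
            and np.all(np.abs(self.angles_deg) <= tol)
        )


@dataclass(frozen=True)
class TransformError:
    """Per-axis decomposition of the difference between two registrations.

    Signed translations (mm) along AP/LR/CC, the absolute 3-D translation
    (their Euclidean norm), and signed rotations (degrees) per anatomical
    plane.
    """

    dt_ap: float
    dt_lr: float
    dt_cc: float
    dt_abs: float
    dr_axial: float
    dr_coronal: float
    dr_sagittal: float


def make_rigid(
    tx: float = 0.0,
    ty: float = 0.0,
    tz: float = 0.0,
    rx: float = 0.0,
    ry: float = 0.0,
    rz: float = 0.0,
    center=(0.0, 0.0, 0.0),
) -> RigidTransform:
    """Build a rigid transform; see module docstring for conventions."""
    return RigidTransform(tx, ty, tz, rx, ry, rz, np.asarray(center, dtype=float))


IDENTITY = make_rigid()


def _from_matrix_offset(
    rot: np.ndarray, offset: np.ndarray, center: np.ndarray
) -> RigidTransform:
    """Re-express the affine action (R, o) as a RigidTransform about *center*."""
    rz, ry, rx = Rotation.from_matrix(rot).as_euler(EULER_ORDER, degrees=True)
    translation = offset - center + rot @ center
    return RigidTransform(
        translation[0], translation[1], translation[2], rx, ry, rz, np.asarray(center, float)
    )


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Transform acting as ``outer(inner(p))``, expressed about outer's center."""
    ra, oa = outer.as_matrix_offset()
    rb, ob = inner.as_matrix_offset()
    return _from_matrix_offset(ra @ rb, ra @ ob + oa, outer.center)


def invert(t: RigidTransform) -> RigidTransform:
    """Functional inverse, expressed about the same center."""
    rot, offset = t.as_matrix_offset()
    rinv = rot.T
    return _from_matrix_offset(rinv, -rinv @ offset, t.center)


def decompose_difference(
    t_a: RigidTransform, t_b: RigidTransform, center=None
) -> TransformError:
    """Error components of the correction taking ``t_b`` onto ``t_a``.

    Computes ``D = invert(t_b) o t_a`` (so ``t_b o D == t_a``) and reads off
    its per-axis translations and per-plane Euler angles about *center*
    (default: ``t_a.center``).  Both transforms must live in the same patient
    frame.  ``dt_abs`` is the Euclidean norm of the three translations.
    """
    if center is None:
        center = t_a.center
    diff = compose(invert(t_b), t_a)
    diff = _from_matrix_offset(*diff.as_matrix_offset(), np.asarray(center, float))
    t = diff.translation
    return TransformError(
        dt_ap=float(t[1]),
        dt_lr=float(t[0]),
        dt_cc=float(t[2]),
        dt_abs=float(np.linalg.norm(t)),
        dr_axial=float(diff.rz),
        dr_coronal=float(diff.ry),
        dr_sagittal=float(diff.rx),
    )


# ---------------------------------------------------------------------------
# serialization

def transform_to_dict(t: RigidTransform) -> dict:
    return {
        "tx": t.tx,
        "ty": t.ty,
        "tz": t.tz,
        "rx": t.rx,
        "ry": t.ry,
        "rz": t.rz,
        "center": [float(c) for c in t.center],
        "frame": FRAME,
        "euler_order": EULER_ORDER.lower(),
    }


def transform_from_dict(d: dict) -> RigidTransform:
    frame = d.get("frame", FRAME)
    order = d.get("euler_order", EULER_ORDER.lower())
    if frame != FRAME or order != EULER_ORDER.lower():
        raise InvalidParameterError(
            f"unsupported frame/euler_order: {frame}/{order} (need {FRAME}/{EULER_ORDER.lower()})"
        )
    return make_rigid(
        d["tx"], d["ty"], d["tz"], d["rx"], d["ry"], d["rz"], d.get("center", (0, 0, 0))
    )


def write_transform(t: RigidTransform, path) -> None:
    Path(path).write_text(json.dumps(transform_to_dict(t), indent=2) + "\n")


def read_transform(path) -> RigidTransform:
    return transform_from_dict(json.loads(Path(path).read_text()))
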