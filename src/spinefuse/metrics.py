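"""Joint-histogram similarity metrics: MI, normalized MI and Pearson r.

Mutual information measures how much knowing one image's intensity reduces
uncertainty about the other's; it is the standard similarity measure for
multi-modality rigid registration because it assumes no functional intensity
relationship between the scans.  Here MI is normalized to

    NMI = (H(A) + H(B) - H(A,B)) / H(A,B) = MI / H(A,B)

which ranges over [0, 1] and equals 1 when the two images are identical and
perfectly aligned.  (The Studholme overlap-invariant measure
(H(A)+H(B))/H(A,B) ranges over [1, 2]; the quantity above is that measure
minus one, matching the 0-1 range and unit maximum this package reports.)

Sampling rule shared by all metrics: for every primary voxel inside the mask
(or all voxels when no mask is given), the secondary is sampled at the
transform-mapped physical location with trilinear interpolation; pairs mapping
outside the secondary volume are dropped.  For the histogram, both intensities
are clipped to a fixed HU window (default -200..1500, soft tissue through
hardware with extreme metal compressed into the top bin) and binned uniformly
(default 64 bins per axis).  Entropies are computed in nats; NMI, as a ratio
of entropies, is independent of the logarithm base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .contour import ContourMask
from .errors import DegenerateOverlapError, InvalidParameterError, UndefinedCorrelationError
from .geometry import RigidTransform
from .io_formats import ImageVolume

__all__ = [
    "JointHistogram",
    "joint_histogram",
    "entropies",
    "mutual_information",
    "nmi",
    "pearson_cc",
    "sample_pairs",
]

DEFAULT_BINS = 64
DEFAULT_CLIP_RANGE = (-200.0, 1500.0)


@dataclass
class JointHistogram:
    """B x B paired-intensity counts inside the mask, plus bin edges."""

    counts: np.ndarray
    edges_primary: np.ndarray
    edges_secondary: np.ndarray
    n: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or min(counts.shape) < 2:
            raise InvalidParameterError("joint histogram must be at least 2x2")
        if np.any(counts < 0):
            raise InvalidParameterError("joint histogram counts must be non-negative")
        if self.n < 1:
            raise InvalidParameterError("joint histogram needs n >= 1 samples")
        self.counts = counts


def sample_pairs(
    primary: ImageVolume,
    secondary: ImageVolume,
    t: RigidTransform,
    mask: ContourMask | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (primary, secondary) intensities under transform ``t``.

    Primary voxels are taken inside ``mask`` (everywhere if None); the
    secondary is sampled at ``t(p)`` by trilinear interpolation and pairs
    landing outside the secondary grid are dropped.
    """
    if isinstance(mask, ContourMask):
        mask = mask.mask
    if mask is None:
        idx = np.indices(primary.shape, dtype=float).reshape(3, -1).T
        values_p = primary.voxels.ravel()
    else:
        if mask.shape != primary.shape:
            raise InvalidParameterError(
                f"mask shape {mask.shape} != primary shape {primary.shape}"
            )
        idx = np.argwhere(mask).astype(float)
        values_p = primary.voxels[mask]
    pts = primary.voxel_centers_mm(idx)
    src = secondary.mm_to_index(t.apply(pts))
    upper = np.array(secondary.shape, dtype=float) - 1.0
    inside = np.all((src >= 0.0) & (src <= upper), axis=1)
    if not inside.any():
        raise DegenerateOverlapError(
            "transform maps every sampled voxel outside the secondary volume"
        )
    values_s = ndimage.map_coordinates(
        secondary.voxels, src[inside].T, order=1, mode="nearest"
    )
    return values_p[inside], values_s


def joint_histogram(
    primary: ImageVolume,
    secondary: ImageVolume,
    t: RigidTransform,
    mask: ContourMask | np.ndarray | None = None,
    bins: int = DEFAULT_BINS,
    clip_range: tuple[float, float] = DEFAULT_CLIP_RANGE,
) -> JointHistogram:
    """Accumulate the paired intensities into a B x B joint histogram."""
    if bins < 2:
        raise InvalidParameterError(f"need >= 2 bins, got {bins}")
    lo, hi = clip_range
    if not lo < hi:
        raise InvalidParameterError(f"clip range must be increasing, got {clip_range}")
    vp, vs = sample_pairs(primary, secondary, t, mask)
    vp = np.clip(vp, lo, hi)
    vs = np.clip(vs, lo, hi)
    counts, ep, es = np.histogram2d(vp, vs, bins=bins, range=[(lo, hi), (lo, hi)])
    return JointHistogram(counts=counts, edges_primary=ep, edges_secondary=es, n=len(vp))


def entropies(jh: JointHistogram) -> tuple[float, float, float]:
    """Shannon entropies (nats) of the marginals and the joint distribution."""
    p = jh.counts / jh.counts.sum()

    def h(dist: np.ndarray) -> float:
        nz = dist[dist > 0]
        return float(-(nz * np.log(nz)).sum())

    return h(p.sum(axis=1)), h(p.sum(axis=0)), h(p.ravel())


def mutual_information(jh: JointHistogram) -> float:
    h_a, h_b, h_ab = entropies(jh)
    return max(h_a + h_b - h_ab, 0.0)


def nmi(jh: JointHistogram) -> float:
    """Normalized mutual information, MI / H(A,B), clamped to [0, 1].

    When the joint entropy is zero both images are constant over the mask —
    degenerate but perfectly matched — and the metric returns 1 by convention.
    """
    h_a, h_b, h_ab = entropies(jh)
    if h_ab == 0.0:
        return 1.0
    return float(np.clip((h_a + h_b - h_ab) / h_ab, 0.0, 1.0))


def pearson_cc(
    primary: ImageVolume,
    secondary: ImageVolume,
    t: RigidTransform,
    mask: ContourMask | np.ndarray | None = None,
) -> float:
    """Sample Pearson correlation of the paired intensities (unbinned)."""
    vp, vs = sample_pairs(primary, secondary, t, mask)
    if len(vp) < 2:
        raise DegenerateOverlapError("need >= 2 paired samples for correlation")
    if np.ptp(vp) == 0 or np.ptp(vs) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    return float(np.corrcoef(vp, vs)[0, 1])
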