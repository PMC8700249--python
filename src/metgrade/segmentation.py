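"""User-independent lesion segmentation.

Two segmentations are produced per study, both seeded from the voxel of
maximum SUV inside an operator-supplied bounding box:

* a **threshold VOI**: voxels inside the box at or above a fraction (default
  40%) of SUVmax, restricted to the 26-connected component containing the
  SUVmax voxel (disconnecting stray hot spots elsewhere in the box);
* a **fixed ROI** of exactly 81 voxels centred on the SUVmax voxel — the 81
  voxels nearest in physical (mm) distance, an approximately spherical,
  spacing-aware neighbourhood. A 9x9 single-slice square alternative is
  available via ``roi_shape="square2d"``.

Tie-breaking everywhere is lexicographic on (z, y, x) so results are fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import RegionMask, SuvVolume, ValidationError

__all__ = [
    "BoundingBox",
    "SegmentationParams",
    "find_suvmax",
    "threshold_voi",
    "fixed_roi",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box of voxel indices, corners inclusive."""

    min_corner: tuple[int, int, int]
    max_corner: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.min_corner)
        hi = tuple(int(v) for v in self.max_corner)
        if any(a < 0 for a in lo) or any(a > b for a, b in zip(lo, hi)):
            raise ValidationError(f"degenerate bounding box {lo}:{hi}")
        object.__setattr__(self, "min_corner", lo)
        object.__setattr__(self, "max_corner", hi)

    def validate_for(self, vol: SuvVolume) -> None:
        if any(b >= s for b, s in zip(self.max_corner, vol.shape)):
            raise ValidationError(
                f"bounding box {self.min_corner}:{self.max_corner} exceeds volume shape {vol.shape}"
            )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b + 1) for a, b in zip(self.min_corner, self.max_corner))


@dataclass(frozen=True)
class SegmentationParams:
    threshold_fraction: float = 0.40
    fixed_roi_size: int = 81
    roi_shape: str = "ball3d"  # or "square2d": 9x9x1 in-plane square

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction <= 1.0:
            raise ValidationError("threshold_fraction must lie in (0, 1]")
        if self.fixed_roi_size < 1:
            raise ValidationError("fixed_roi_size must be positive")
        if self.roi_shape not in ("ball3d", "square2d"):
            raise ValidationError(f"unknown roi_shape {self.roi_shape!r}")


def _zyx_first(candidates: np.ndarray) -> np.ndarray:
    """Return the candidate (rows of x,y,z) that is first in (z, y, x) order."""
    order = np.lexsort((candidates[:, 0], candidates[:, 1], candidates[:, 2]))
    return candidates[order[0]]


def find_suvmax(vol: SuvVolume, box: BoundingBox) -> tuple[tuple[int, int, int], float]:
    """Voxel index and value of the maximum SUV inside ``box``.

    Ties are broken by lexicographic (z, y, x) order.
    """
    box.validate_for(vol)
    sub = vol.values[box.slices]
    peak = float(sub.max())
    cand = np.argwhere(sub == peak) + np.asarray(box.min_corner)
    winner = _zyx_first(cand)
    return tuple(int(v) for v in winner), peak


def threshold_voi(
    vol: SuvVolume, box: BoundingBox, params: SegmentationParams = SegmentationParams()
) -> RegionMask:
    """Fractional-SUVmax threshold VOI inside the operator box.

    Keeps voxels with ``SUV >= threshold_fraction * SUVmax(box)`` belonging to
    the 26-connected component that contains the SUVmax voxel. The comparison
    is inclusive, so the mask always contains at least the SUVmax voxel.
    """
    peak_idx, peak = find_suvmax(vol, box)
    thresh = params.threshold_fraction * peak
    inside = np.zeros(vol.shape, dtype=bool)
    inside[box.slices] = vol.values[box.slices] >= thresh
    labels, _ = ndimage.label(inside, structure=_CONN26)
    keep = labels == labels[peak_idx]
    return RegionMask.from_dense(keep, kind="threshold_voi")


def fixed_roi(
    vol: SuvVolume, box: BoundingBox, params: SegmentationParams = SegmentationParams()
) -> RegionMask:
    """Fixed-size ROI centred on the SUVmax voxel.

    Default shape is the ``fixed_roi_size`` voxels nearest the SUVmax voxel by
    physical Euclidean distance (ties broken in (z, y, x) order), which for
    anisotropic spacing yields a flattened, approximately ellipsoidal ball of
    exactly the requested count.
    """
    peak_idx, _ = find_suvmax(vol, box)
    n = params.fixed_roi_size
    if params.roi_shape == "square2d":
        side = int(round(n ** 0.5))
        if side * side != n:
            raise ValidationError("square2d roi_shape needs a square fixed_roi_size")
        half = side // 2
        x0, y0, z0 = peak_idx
        if (
            x0 - half < 0
            or y0 - half < 0
            or x0 + half >= vol.shape[0]
            or y0 + half >= vol.shape[1]
        ):
            raise ValidationError("square2d ROI does not fit inside the volume")
        xs, ys = np.meshgrid(
            np.arange(x0 - half, x0 + half + 1),
            np.arange(y0 - half, y0 + half + 1),
            indexing="ij",
        )
        idx = np.stack([xs.ravel(), ys.ravel(), np.full(n, z0)], axis=1)
        return RegionMask(indices=idx, kind="fixed_roi", shape=vol.shape)

    if int(np.prod(vol.shape)) < n:
        raise ValidationError(
            f"volume has {int(np.prod(vol.shape))} voxels, fewer than the {n} required"
        )
    dx, dy, dz = vol.spacing
    ax = (np.arange(vol.shape[0]) - peak_idx[0]) * dx
    ay = (np.arange(vol.shape[1]) - peak_idx[1]) * dy
    az = (np.arange(vol.shape[2]) - peak_idx[2]) * dz
    d2 = (
        ax[:, None, None] ** 2 + ay[None, :, None] ** 2 + az[None, None, :] ** 2
    ).ravel()
    xg, yg, zg = np.unravel_index(np.arange(d2.size), vol.shape)
    order = np.lexsort((xg, yg, zg, d2))[:n]
    idx = np.stack([xg[order], yg[order], zg[order]], axis=1)
    return RegionMask(indices=idx, kind="fixed_roi", shape=vol.shape)
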