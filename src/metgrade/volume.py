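"""Core grid types and NIfTI I/O.

Conventions shared by every stage of the workflow:

* volumes are 3-D scalar grids of SUV (standardized uptake value) intensities;
* voxel indices are 0-based ``(x, y, z)`` triples with ``x`` the fastest-varying
  (on-disk) axis, matching the NIfTI array layout nibabel exposes;
* voxel spacing is given in millimetres per axis and may be anisotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ValidationError",
    "DimensionalityError",
    "NonFiniteVoxelsError",
    "SuvVolume",
    "RegionMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


class ValidationError(ValueError):
    """An input violated one of the package's data contracts."""


class DimensionalityError(ValidationError):
    """A volume was not a 3-D scalar grid."""


class NonFiniteVoxelsError(ValidationError):
    """A volume contained NaN or infinite voxels."""


@dataclass(frozen=True)
class SuvVolume:
    """A 3-D grid of SUV values with anisotropic voxel spacing.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)`` holding finite SUV intensities.
    spacing
        Voxel edge lengths ``(dx, dy, dz)`` in millimetres.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D scalar grid, got {values.ndim}-D data"
            )
        bad = int(np.size(values) - np.isfinite(values).sum())
        if bad:
            raise NonFiniteVoxelsError(
                f"volume contains {bad} non-finite voxel(s)"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"voxel spacing must be three positive mm values, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class RegionMask:
    """A set of voxel indices into one :class:`SuvVolume`.

    ``kind`` records the segmentation that produced the mask
    (``"threshold_voi"`` or ``"fixed_roi"``).
    """

    indices: np.ndarray
    kind: str
    shape: tuple[int, int, int] = field(default=(0, 0, 0))

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 2 or idx.shape[1] != 3 or idx.shape[0] == 0:
            raise ValidationError("mask must be a nonempty (N, 3) array of voxel indices")
        shape = tuple(int(s) for s in self.shape)
        if (idx < 0).any() or (idx >= np.asarray(shape)).any():
            raise ValidationError("mask indices fall outside the source volume shape")
        if len(np.unique(idx, axis=0)) != len(idx):
            raise ValidationError("mask contains duplicate voxel indices")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "shape", shape)

    def __len__(self) -> int:
        return int(self.indices.shape[0])

    def to_dense(self) -> np.ndarray:
        """Return the mask as a boolean array of ``shape``."""
        dense = np.zeros(self.shape, dtype=bool)
        dense[tuple(self.indices.T)] = True
        return dense

    @classmethod
    def from_dense(cls, dense: np.ndarray, kind: str) -> "RegionMask":
        dense = np.asarray(dense, dtype=bool)
        return cls(indices=np.argwhere(dense), kind=kind, shape=dense.shape)

    def index_set(self) -> set[tuple[int, int, int]]:
        return {tuple(int(v) for v in row) for row in self.indices}


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def read_volume(path: str | Path) -> SuvVolume:
    """Load a 3-D scalar NIfTI volume as a :class:`SuvVolume`.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    DimensionalityError
        For 4-D (or otherwise non-3-D) inputs.
    NonFiniteVoxelsError
        If any voxel is NaN or infinite (the message names the count).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3-D scalar volume, got shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SuvVolume(values=np.asarray(data, dtype=np.float64), spacing=spacing)


def write_volume(vol: SuvVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (float64, spacing carried in pixdim)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.values.astype(np.float64), affine=_affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def write_mask(mask: RegionMask, like: SuvVolume, path: str | Path) -> Path:
    """Write a binary NIfTI (1 inside the mask) with the geometry of ``like``."""
    if mask.shape != like.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match volume shape {like.shape}"
        )
    dense = mask.to_dense().astype(np.uint8)
    img = nib.Nifti1Image(dense, affine=_affine(like.spacing))
    img.header.set_zooms(like.spacing)
    nib.save(img, str(Path(path)))
    return Path(path)


def read_mask(path: str | Path, kind: str = "threshold_voi") -> RegionMask:
    """Load a binary NIfTI mask; voxels > 0.5 are inside."""
    vol = read_volume(path)
    return RegionMask.from_dense(vol.values > 0.5, kind=kind)
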