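"""Fixed-bound intensity resampling of SUV values to discrete grey levels.

Histogram and texture features are computed on grey levels obtained by
resampling SUV intensities onto ``n_bins`` levels spanning a fixed absolute
range (default 64 levels between 0 and 20 SUV, the usual oncology window).
The bin width uses the ``(max - min) / (n_bins - 1)`` convention, which for
the default window gives 20/63 = 0.317 SUV per level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import RegionMask, SuvVolume, ValidationError

__all__ = ["BinningConfig", "bin_width", "discretize", "discretize_values"]


@dataclass(frozen=True)
class BinningConfig:
    """Grey-level resampling parameters (absolute / fixed-bound mode)."""

    n_bins: int = 64
    bound_min: float = 0.0
    bound_max: float = 20.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("n_bins must be at least 2")
        if not self.bound_min < self.bound_max:
            raise ValidationError("bound_min must be strictly below bound_max")

    @property
    def bin_width(self) -> float:
        return (self.bound_max - self.bound_min) / (self.n_bins - 1)


def bin_width(config: BinningConfig) -> float:
    """Width of one grey-level bin in SUV units."""
    return config.bin_width


def discretize_values(values: np.ndarray, config: BinningConfig) -> np.ndarray:
    """Map SUV values to integer grey levels in ``[1, n_bins]``.

    ``level = floor((suv - bound_min) / bin_width) + 1`` clipped into range,
    so values at or below ``bound_min`` map to 1 and values at or above
    ``bound_max`` map to ``n_bins``. Clipping (rather than exclusion) keeps
    region sizes identical before and after resampling.
    """
    values = np.asarray(values, dtype=np.float64)
    levels = np.floor((values - config.bound_min) / config.bin_width).astype(np.int64) + 1
    return np.clip(levels, 1, config.n_bins)


def discretize(vol: SuvVolume, mask: RegionMask, config: BinningConfig) -> np.ndarray:
    """Grey-level grid for ``vol`` restricted to ``mask``.

    Returns an integer array of the volume's shape with levels 1..n_bins at
    in-mask voxels and 0 elsewhere.
    """
    if mask.shape != vol.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match volume shape {vol.shape}"
        )
    out = np.zeros(vol.shape, dtype=np.int64)
    ix = tuple(mask.indices.T)
    out[ix] = discretize_values(vol.values[ix], config)
    return out
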