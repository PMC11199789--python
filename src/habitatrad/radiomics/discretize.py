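"""Fixed-bin-width grey-level discretization restricted to a mask."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedVolume", "discretize", "bin_width_for"]

DEFAULT_BIN_WIDTH_HU = 25.0
DERIVED_IMAGE_LEVELS = 32  # fallback level count for arbitrary dynamic ranges


@dataclass
class DiscretizedVolume:
    """Integer grey levels 1..Ng on the in-mask voxels (0 elsewhere)."""

    levels: np.ndarray  # int grid, 0 outside mask
    mask: np.ndarray  # bool grid
    ng: int
    bin_width: float

    def inmask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def bin_width_for(name: str, arr: np.ndarray, mask: np.ndarray,
                  bin_width: float = DEFAULT_BIN_WIDTH_HU) -> float:
    """Bin width policy: fixed HU width on the original image; for derived
    images with arbitrary dynamic range, range/32."""
    if name == "original":
        return bin_width
    vals = arr[mask]
    rng = float(vals.max() - vals.min())
    return rng / DERIVED_IMAGE_LEVELS if rng > 0 else 1.0


def discretize(arr: np.ndarray, mask: np.ndarray, bin_width: float) -> DiscretizedVolume:
    """level(v) = floor((v - min_in_mask) / bin_width) + 1; Ng = max level."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(arr, dtype=np.float64)
    lo = vals[mask].min()
    levels = np.zeros(mask.shape, dtype=np.int32)
    levels[mask] = np.floor((vals[mask] - lo) / bin_width).astype(np.int32) + 1
    ng = int(levels[mask].max())
    return DiscretizedVolume(levels=levels, mask=mask, ng=ng, bin_width=float(bin_width))
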