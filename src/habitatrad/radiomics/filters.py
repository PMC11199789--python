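"""The 20-volume filter bank applied before feature extraction.

Composition: the original image (1), the eight single-level 3D stationary
wavelet bands (8), Laplacian-of-Gaussian responses at sigma 1..6 mm (6), and
five intensity transforms (square, square root, logarithm, exponential,
gradient magnitude).  All derived volumes live on the source grid, so one
mask serves every image type.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from ..imaging import ImageVolume

__all__ = ["apply_filter_bank", "FILTER_NAMES", "LOG_SIGMAS_MM", "WAVELET"]

LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
WAVELET = "coif1"

_WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

FILTER_NAMES: tuple[str, ...] = (
    ("original",)
    + tuple(f"wavelet-{b}" for b in _WAVELET_BANDS)
    + tuple(f"log-sigma-{int(s)}mm" for s in LOG_SIGMAS_MM)
    + ("square", "squareroot", "logarithm", "exponential", "gradient")
)


def _swt_bands(arr: np.ndarray) -> dict[str, np.ndarray]:
    """Single-level undecimated 3D wavelet decomposition on the source grid.

    SWT needs even extents; odd axes are edge-padded by one voxel and the
    pad is cropped off the responses.
    """
    pad = [(0, n % 2) for n in arr.shape]
    padded = np.pad(arr, pad, mode="edge")
    coeffs = pywt.swtn(padded, WAVELET, level=1)[0]
    out = {}
    for key, band in coeffs.items():
        # pywt keys use 'a'/'d' per axis; map a->L, d->H
        name = "".join("L" if c == "a" else "H" for c in key)
        crop = tuple(slice(0, n) for n in arr.shape)
        out[f"wavelet-{name}"] = band[crop]
    return out


def _intensity_transforms(arr: np.ndarray, spacing) -> dict[str, np.ndarray]:
    absmax = max(float(np.abs(arr).max()), 1.0)
    grads = np.gradient(arr, *spacing)
    return {
        "square": arr**2,
        "squareroot": np.sign(arr) * np.sqrt(np.abs(arr)),
        # shifted log admits the negative HU range without error
        "logarithm": np.sign(arr) * np.log(np.abs(arr) + 1.0),
        # argument scaled to [-3, 3] to keep the response in a sane range
        "exponential": np.exp(3.0 * arr / absmax),
        "gradient": np.sqrt(sum(g**2 for g in grads)),
    }


def apply_filter_bank(image: ImageVolume) -> dict[str, np.ndarray]:
    """Return exactly the 20 named derived volumes, all on the source grid."""
    arr = np.asarray(image.voxels, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    out: dict[str, np.ndarray] = {"original": arr}
    out.update(_swt_bands(arr))
    for sigma_mm in LOG_SIGMAS_MM:
        sigma_vox = tuple(sigma_mm / s for s in image.spacing)
        out[f"log-sigma-{int(sigma_mm)}mm"] = ndimage.gaussian_laplace(
            arr, sigma=sigma_vox
        )
    out.update(_intensity_transforms(arr, image.spacing))
    assert len(out) == 20 and tuple(out) == FILTER_NAMES
    return out
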