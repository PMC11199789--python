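"""Volume/mask containers, NIfTI & DICOM I/O, resampling and ROI cropping.

Arrays are stored in (x, y, z) axis order so that ``spacing[i]`` is the
physical step (mm) along array axis ``i``.  SimpleITK is used for file I/O
and for grid resampling; its native (z, y, x) array layout is transposed at
the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "GeometryMismatchError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample_pair",
    "crop_to_roi",
    "check_geometry",
]

_IDENTITY = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


class GeometryMismatchError(ValueError):
    """Raised when an image and mask do not live on the same voxel grid."""


@dataclass
class ImageVolume:
    """A 3D scalar field (HU) with physical geometry.

    Attributes
    ----------
    voxels : (nx, ny, nz) float array
    spacing : mm per voxel along each array axis
    origin : world coordinate (mm) of voxel (0, 0, 0)
    direction : row-major 3x3 direction cosines, default identity
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def geometry(self) -> tuple:
        return (self.shape, tuple(np.round(self.spacing, 6)),
                tuple(np.round(self.origin, 4)), tuple(np.round(self.direction, 6)))

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.voxels.T))
        img.SetSpacing(tuple(float(s) for s in self.spacing))
        img.SetOrigin(tuple(float(o) for o in self.origin))
        img.SetDirection(tuple(float(d) for d in self.direction))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        arr = sitk.GetArrayFromImage(img).T.astype(np.float64)
        return cls(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()),
                   tuple(img.GetDirection()))


@dataclass
class BinaryMask(ImageVolume):
    """A {0,1} membership grid sharing the geometry of its paired image."""

    def __post_init__(self) -> None:
        self.voxels = (np.asarray(self.voxels) != 0).astype(np.uint8)
        super().__post_init__()

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def require_nonempty(self) -> None:
        if self.n_foreground == 0:
            raise ValueError("mask has no foreground voxels")


def check_geometry(image: ImageVolume, mask: ImageVolume) -> None:
    """Raise :class:`GeometryMismatchError` unless the two grids coincide."""
    if image.geometry() != mask.geometry():
        raise GeometryMismatchError(
            f"image grid {image.geometry()} does not match mask grid {mask.geometry()}"
        )


def _read_sitk(path: str | Path) -> sitk.Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():  # DICOM series directory
        reader = sitk.ImageSeriesReader()
        names = reader.GetGDCMSeriesFileNames(str(path))
        if not names:
            raise ValueError(f"no DICOM series found in {path}")
        reader.SetFileNames(names)
        return reader.Execute()
    return sitk.ReadImage(str(path))


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI file or a DICOM series directory."""
    return ImageVolume.from_sitk(_read_sitk(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a mask; any nonzero label maps to foreground 1."""
    vol = ImageVolume.from_sitk(_read_sitk(Path(path)))
    return BinaryMask(vol.voxels, vol.spacing, vol.origin, vol.direction)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(volume.to_sitk(), str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = mask.to_sitk()
    sitk.WriteImage(sitk.Cast(img, sitk.sitkUInt8), str(path))


def write_labelmap(labels: np.ndarray, like: ImageVolume, path: str | Path) -> None:
    """Write an integer label volume (e.g. a habitat map) on ``like``'s grid."""
    vol = ImageVolume(labels.astype(np.int16), like.spacing, like.origin, like.direction)
    sitk.WriteImage(sitk.Cast(vol.to_sitk(), sitk.sitkInt16), str(path))


def resample_pair(
    image: ImageVolume,
    mask: BinaryMask,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[ImageVolume, BinaryMask]:
    """Resample an image/mask pair onto a common grid at ``target_spacing``.

    The image is interpolated with cubic B-splines; the mask with nearest
    neighbour and re-binarized, so binarity is preserved exactly.
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    check_geometry(image, mask)
    mask.require_nonempty()
    if tuple(np.round(image.spacing, 6)) == tuple(np.round(target_spacing, 6)):
        return image, mask

    src = image.to_sitk()
    new_size = [
        max(1, int(np.ceil(n * s / t)))
        for n, s, t in zip(image.shape, image.spacing, target_spacing)
    ]
    resampler = sitk.ResampleImageFilter()
    resampler.SetOutputSpacing(tuple(float(t) for t in target_spacing))
    resampler.SetSize(new_size)
    resampler.SetOutputOrigin(src.GetOrigin())
    resampler.SetOutputDirection(src.GetDirection())
    resampler.SetInterpolator(sitk.sitkBSpline)
    out_img = ImageVolume.from_sitk(resampler.Execute(src))

    resampler.SetInterpolator(sitk.sitkNearestNeighbor)
    out_mask_img = resampler.Execute(sitk.Cast(mask.to_sitk(), sitk.sitkUInt8))
    out_mask = BinaryMask.from_sitk_mask(out_mask_img)
    if out_mask.n_foreground == 0:
        raise ValueError(
            "resampling emptied the mask; choose a finer target spacing than "
            f"{target_spacing}"
        )
    return out_img, out_mask


def _from_sitk_mask(img: sitk.Image) -> BinaryMask:
    arr = sitk.GetArrayFromImage(img).T
    return BinaryMask(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()),
                      tuple(img.GetDirection()))


BinaryMask.from_sitk_mask = staticmethod(_from_sitk_mask)


def crop_to_roi(
    image: ImageVolume, mask: BinaryMask, margin_voxels: int = 0
) -> tuple[ImageVolume, BinaryMask]:
    """Crop both grids to the mask bounding box plus a margin, clipped to grid."""
    check_geometry(image, mask)
    mask.require_nonempty()
    idx = np.argwhere(mask.voxels > 0)
    lo = np.maximum(idx.min(axis=0) - margin_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + margin_voxels + 1, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    offset = lo * np.asarray(image.spacing)
    # origin moves with the crop along the direction cosines
    dirmat = np.asarray(image.direction).reshape(3, 3)
    new_origin = tuple(np.asarray(image.origin) + dirmat @ offset)
    img = ImageVolume(image.voxels[sl].copy(), image.spacing, new_origin, image.direction)
    msk = BinaryMask(mask.voxels[sl].copy(), mask.spacing, new_origin, mask.direction)
    return img, msk
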