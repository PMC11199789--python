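"""The 14 three-dimensional shape descriptors of the whole-ROI mask.

Volume and surface area come from a marching-cubes mesh of the binary mask
(spacing-aware); axis lengths from the eigenvalues of the physical
coordinate covariance; maximum diameters from the convex hull of surface
voxels.  Shape is computed once per patient on the original mask only —
habitat subregions get no shape features.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

__all__ = ["shape_features", "SHAPE_NAMES"]

SHAPE_NAMES: tuple[str, ...] = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _mesh(mask: np.ndarray, spacing) -> tuple[float, float]:
    """(mesh volume, surface area) via marching cubes at level 0.5.

    The binary mask is lightly smoothed (1-voxel Gaussian) before meshing:
    the staircase surface of a raw binary mesh overestimates surface area
    by ~8% on a digital sphere, while the smoothed mesh recovers both the
    analytic area and volume to within ~3%.  Small masks where smoothing
    would sink the 0.5 level fall back to the raw binary mesh.
    """
    from scipy import ndimage

    padded = np.pad(mask.astype(np.float64), 2)
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    if smoothed.max() <= 0.5:
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=spacing)
    v0 = verts[faces[:, 0]]
    v1 = verts[faces[:, 1]]
    v2 = verts[faces[:, 2]]
    # divergence theorem: V = |sum of signed tetrahedron volumes|
    volume = float(np.abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)
    area = float(np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1).sum() / 2.0)
    return volume, area


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 8:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points).max())


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = float(np.prod(spacing))
    n = int(mask.sum())

    mesh_volume, surface_area = _mesh(mask, spacing)
    if mesh_volume <= 0:  # single-voxel style degeneracy
        mesh_volume = voxel_volume * n

    coords = np.argwhere(mask) * np.asarray(spacing)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]  # descending
    eig = np.maximum(eig, 0.0)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    # surface voxels: foreground with at least one 6-neighbour outside
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask)
    surface = np.argwhere(mask & ~eroded) * np.asarray(spacing)
    if len(surface) == 0:
        surface = coords
    d3 = _max_pairwise(surface)
    d_slice = _max_pairwise(surface[:, [0, 1]])  # in-plane (x, y)
    d_column = _max_pairwise(surface[:, [0, 2]])  # (x, z)
    d_row = _max_pairwise(surface[:, [1, 2]])  # (y, z)

    sphericity = float((36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area)
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume * n,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": sphericity,
        "Maximum3DDiameter": d3,
        "Maximum2DDiameterSlice": d_slice,
        "Maximum2DDiameterColumn": d_column,
        "Maximum2DDiameterRow": d_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }
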