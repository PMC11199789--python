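"""Voxel-wise feature maps, K-means habitat partitioning and per-habitat features.

Each tumor is treated independently: voxel-level radiomics maps are computed
over a cubic neighbourhood intersected with the ROI, z-scored across the
tumor's voxels, clustered with K-means, and the number of subregions is
chosen from the Calinski-Harabasz (CH) score over a candidate range of K.
Habitat indices are deterministic: clusters are re-ordered h1..hK by
descending mean original intensity, so the pipeline is invariant to the
clusterer's arbitrary label permutation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .imaging import BinaryMask, ImageVolume, check_geometry

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelFeatureMatrix",
    "HabitatLabeling",
    "voxel_feature_maps",
    "kmeans_cluster",
    "calinski_harabasz",
    "select_optimal_k",
    "cluster_habitats",
    "build_habitat_masks",
    "labeling_to_map",
    "extract_habitat_features",
    "DEFAULT_VOXEL_FEATURES",
    "EXTRA_VOXEL_FEATURES",
]

DEFAULT_VOXEL_FEATURES = ("intensity", "local_mean")

#: richer kernel statistics available via ``feature_names``; on lesions with
#: thin subregions their boundary response can dominate the z-scored metric,
#: so they are opt-in rather than default
EXTRA_VOXEL_FEATURES = (
    "local_variance",
    "local_log_variance",
    "local_energy",
    "local_entropy",
    "local_uniformity",
)

_LOCAL_HIST_LEVELS = 16  # grey levels for the local entropy/uniformity maps


@dataclass
class VoxelFeatureMatrix:
    """Per-voxel feature rows for one tumor.

    ``values`` holds the z-scored matrix used for clustering; ``raw`` the
    untransformed feature maps.  ``coords`` are the (x, y, z) voxel indices
    of each row, in mask scan order.
    """

    coords: np.ndarray  # (n, 3) int
    values: np.ndarray  # (n, p) float, z-scored
    raw: np.ndarray  # (n, p) float
    feature_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


@dataclass
class HabitatLabeling:
    """Result of habitat partitioning for one tumor."""

    k: int
    labels: np.ndarray  # (n,) in 1..k, aligned with VoxelFeatureMatrix rows
    ch_curve: dict[int, float] = field(default_factory=dict)
    ordering_rule: str = "descending_mean_intensity"
    seed: int = 0


def _masked_box_sums(arr: np.ndarray, kernel: int) -> np.ndarray:
    """Sum of ``arr`` over a centered cubic window (zero-padded)."""
    return ndimage.uniform_filter(arr, size=kernel, mode="constant", cval=0.0) * kernel**3


def voxel_feature_maps(
    image: ImageVolume,
    mask: BinaryMask,
    kernel_radius: int = 1,
    feature_names: tuple[str, ...] = DEFAULT_VOXEL_FEATURES,
) -> VoxelFeatureMatrix:
    """Compute voxel-level radiomics maps over a (2r+1)^3 neighbourhood.

    The neighbourhood is intersected with the ROI, so boundary voxels use
    only in-mask neighbours.  Columns are z-scored across the tumor's
    voxels; zero-variance columns become all-zero.
    """
    if kernel_radius < 1:
        raise ValueError("kernel_radius must be >= 1")
    check_geometry(image, mask)
    mask.require_nonempty()
    m = mask.voxels.astype(np.float64)
    x = image.voxels * m
    kernel = 2 * kernel_radius + 1

    cnt = _masked_box_sums(m, kernel)
    s1 = _masked_box_sums(x, kernel)
    s2 = _masked_box_sums(x * x, kernel)
    with np.errstate(invalid="ignore", divide="ignore"):
        local_mean = np.where(cnt > 0, s1 / cnt, 0.0)
        local_var = np.where(cnt > 0, np.maximum(s2 / cnt - local_mean**2, 0.0), 0.0)

    need_hist = "local_entropy" in feature_names or "local_uniformity" in feature_names
    if need_hist:
        inmask = image.voxels[mask.voxels > 0]
        lo, hi = inmask.min(), inmask.max()
        width = (hi - lo) / _LOCAL_HIST_LEVELS if hi > lo else 1.0
        levels = np.zeros(image.shape, dtype=np.int32)
        levels[mask.voxels > 0] = np.minimum(
            ((image.voxels[mask.voxels > 0] - lo) / width).astype(np.int32),
            _LOCAL_HIST_LEVELS - 1,
        )
        ent = np.zeros(image.shape)
        unif = np.zeros(image.shape)
        for lev in range(_LOCAL_HIST_LEVELS):
            ind = ((levels == lev) & (mask.voxels > 0)).astype(np.float64)
            if not ind.any():
                continue
            c = _masked_box_sums(ind, kernel)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(cnt > 0, c / cnt, 0.0)
            nz = p > 1e-12
            ent[nz] -= p[nz] * np.log2(p[nz])
            unif += p * p

    maps = {
        "intensity": image.voxels,
        "local_mean": local_mean,
        "local_variance": local_var,
        # log compression keeps texture-scale contrast visible after
        # z-scoring when boundary windows produce variance outliers
        "local_log_variance": np.log1p(local_var),
        "local_energy": s2,
    }
    if need_hist:
        maps["local_entropy"] = ent
        maps["local_uniformity"] = unif

    sel = mask.voxels > 0
    coords = np.argwhere(sel)
    # isolated voxels (neighbourhood < 2): fall back to the voxel's intensity
    lonely = cnt[sel] < 2
    cols = []
    for name in feature_names:
        if name not in maps:
            raise ValueError(f"unknown voxel feature {name!r}")
        col = maps[name][sel].astype(np.float64)
        if lonely.any() and name != "intensity":
            col = col.copy()
            col[lonely] = image.voxels[sel][lonely]
        cols.append(col)
    raw = np.column_stack(cols)

    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    # guard against float noise on effectively constant maps
    degenerate = sd <= 1e-9 * np.maximum(np.abs(mean), 1.0)
    safe_sd = np.where(degenerate, 1.0, sd)
    values = (raw - mean) / safe_sd
    values[:, degenerate] = 0.0
    return VoxelFeatureMatrix(coords, values, raw, tuple(feature_names), mean, sd)


def kmeans_cluster(
    matrix: VoxelFeatureMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> tuple[np.ndarray, float]:
    """K-means++ with a fixed restart count; returns (labels in 0..k-1, WSS)."""
    X = matrix.values if isinstance(matrix, VoxelFeatureMatrix) else np.asarray(matrix)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of voxels {n}")
    if k == 1:
        centroid = X.mean(axis=0)
        return np.zeros(n, dtype=int), float(((X - centroid) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed)
    labels = km.fit_predict(X)
    return labels, float(km.inertia_)


def calinski_harabasz(
    matrix: VoxelFeatureMatrix | np.ndarray, labels: np.ndarray
) -> float:
    """Calinski-Harabasz score: [B/(K-1)] / [W/(n-K)].

    ``B`` is the between-cluster dispersion about the global centroid and
    ``W`` the pooled within-cluster dispersion.  Perfectly tight clusters
    (W = 0) return ``inf``.
    """
    X = matrix.values if isinstance(matrix, VoxelFeatureMatrix) else np.asarray(matrix)
    labels = np.asarray(labels)
    n = X.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if not 2 <= k <= n - 1:
        raise ValueError(f"need 2 <= K <= n-1, got K={k}, n={n}")
    overall = X.mean(axis=0)
    b = 0.0
    w = 0.0
    for u in uniq:
        grp = X[labels == u]
        c = grp.mean(axis=0)
        b += len(grp) * float(((c - overall) ** 2).sum())
        w += float(((grp - c) ** 2).sum())
    if w == 0.0:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def _elbow_from_curve(ks: np.ndarray, scores: np.ndarray, rule: str) -> int | None:
    """Pick K from a CH curve; None signals a featureless curve."""
    finite = np.isfinite(scores)
    if not finite.any():
        return None
    if rule == "ch_max":
        # interior or boundary maximum of the CH score
        best = np.nanargmax(np.where(finite, scores, -np.inf))
        return int(ks[best])
    if rule == "knee":
        # Turning point of the CH curve extended by CH(1) = 0 (one cluster
        # has zero between-cluster dispersion): the K whose incremental CH
        # gain collapses right after it, i.e. the maximum of
        # (CH(k) - CH(k-1)) - (CH(k+1) - CH(k)), the negated second
        # difference.  Ties break toward smaller K (argmax takes the first).
        ext = np.concatenate([[0.0], scores])
        gain = np.diff(ext)  # gain[i] = CH(ks[i]) - CH(ks[i] - 1)
        knee = gain[:-1] - gain[1:]  # defined for ks[0] .. ks[-2]
        if not np.isfinite(knee).any():
            return None
        best = int(np.nanargmax(np.where(np.isfinite(knee), knee, -np.inf)))
        return int(ks[best])
    raise ValueError(f"unknown elbow rule {rule!r}")


def select_optimal_k(
    matrix: VoxelFeatureMatrix | np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    rule: str = "knee",
    n_init: int = 10,
) -> tuple[int, dict[int, float]]:
    """Run K-means + CH for each K in [k_min, k_max] and pick the optimum.

    The default rule takes the K at which the CH score peaks (the turning
    point of the CH curve); ``rule='second_diff'`` instead maximizes the
    discrete second difference (the classical elbow on a decreasing curve).
    A featureless/degenerate curve falls back to ``k_min`` with a warning.
    Ties break toward smaller K.
    """
    X = matrix.values if isinstance(matrix, VoxelFeatureMatrix) else np.asarray(matrix)
    n = X.shape[0]
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    k_max = min(k_max, n - 1)
    if k_max < k_min:
        raise ValueError(f"k_max={k_max} below k_min={k_min} for n={n}")

    curve: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        labels, _ = kmeans_cluster(X, k, seed=seed, n_init=n_init)
        if len(np.unique(labels)) < 2:
            curve[k] = float("nan")
            continue
        curve[k] = calinski_harabasz(X, labels)

    ks = np.array(sorted(curve))
    scores = np.array([curve[k] for k in ks], dtype=float)
    # an inf score means a perfectly separated solution: prefer smallest such K
    if np.isposinf(scores).any():
        return int(ks[np.argmax(np.isposinf(scores))]), curve
    best = _elbow_from_curve(ks, scores, rule)
    if best is None:
        warnings.warn("degenerate CH curve; falling back to k_min", stacklevel=2)
        return k_min, curve
    return best, curve


def cluster_habitats(
    image: ImageVolume,
    mask: BinaryMask,
    k: int | None = None,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    kernel_radius: int = 1,
    rule: str = "knee",
) -> tuple[VoxelFeatureMatrix, HabitatLabeling]:
    """Voxel maps -> (optional) K selection -> K-means -> ordered labels 1..K."""
    matrix = voxel_feature_maps(image, mask, kernel_radius=kernel_radius)
    curve: dict[int, float] = {}
    if k is None:
        k, curve = select_optimal_k(matrix, k_min, k_max, seed=seed, rule=rule)
    raw_labels, _ = kmeans_cluster(matrix, k, seed=seed)
    ordered = _order_labels_by_intensity(image, matrix, raw_labels, k)
    return matrix, HabitatLabeling(k=k, labels=ordered, ch_curve=curve, seed=seed)


def _order_labels_by_intensity(
    image: ImageVolume, matrix: VoxelFeatureMatrix, labels: np.ndarray, k: int
) -> np.ndarray:
    """Map arbitrary cluster ids to 1..K by descending mean original intensity."""
    intens = image.voxels[tuple(matrix.coords.T)]
    uniq = np.unique(labels)
    means = np.array([intens[labels == u].mean() for u in uniq])
    # descending intensity; ties broken by cluster size then id for determinism
    sizes = np.array([(labels == u).sum() for u in uniq])
    order = np.lexsort((uniq, -sizes, -means))
    mapping = {int(uniq[idx]): rank + 1 for rank, idx in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels], dtype=int)


def build_habitat_masks(
    mask: BinaryMask,
    matrix: VoxelFeatureMatrix,
    labeling: HabitatLabeling,
) -> list[BinaryMask]:
    """Split the ROI into K disjoint habitat masks h1..hK (union = ROI)."""
    if labeling.labels.shape[0] != matrix.n_voxels:
        raise ValueError("labels do not align with the voxel feature matrix")
    out = []
    for h in range(1, labeling.k + 1):
        vox = np.zeros(mask.shape, dtype=np.uint8)
        sel = matrix.coords[labeling.labels == h]
        if len(sel):
            vox[tuple(sel.T)] = 1
        out.append(BinaryMask(vox, mask.spacing, mask.origin, mask.direction))
    return out


def labeling_to_map(
    mask: BinaryMask, matrix: VoxelFeatureMatrix, labeling: HabitatLabeling
) -> np.ndarray:
    """Dense integer habitat map (0 outside ROI)."""
    out = np.zeros(mask.shape, dtype=np.int16)
    out[tuple(matrix.coords.T)] = labeling.labels
    return out


def extract_habitat_features(
    image: ImageVolume,
    habitat_masks: list[BinaryMask],
    min_voxels: int = 10,
    bin_width: float = 25.0,
) -> dict[str, float]:
    """Non-shape radiomics per habitat; names suffixed ``_h{k}``.

    Habitats below ``min_voxels`` produce NaN placeholders for all their
    features (imputed later at the cohort-table level), so the feature-name
    inventory is identical for every sample.
    """
    from .radiomics import apply_filter_bank, extract_features, feature_name_inventory

    bank = apply_filter_bank(image)  # mask-independent: share across habitats
    record: dict[str, float] = {}
    for i, hmask in enumerate(habitat_masks, start=1):
        if hmask.n_foreground >= min_voxels:
            feats = extract_features(image, hmask, include_shape=False,
                                     bin_width=bin_width, filter_bank=bank)
            items = feats.items()
        else:
            logger.warning("habitat %d below %d voxels; features set missing",
                           i, min_voxels)
            items = ((name, float("nan"))
                     for name in feature_name_inventory(include_shape=False))
        for name, value in items:
            record[f"{name}_h{i}"] = value
    return record
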