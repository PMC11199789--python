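"""Grey-level texture matrices and their descriptor sets.

Five matrix families over a discretized, masked volume:

* GLCM  — co-occurrence over the 13 unique 3D directions at distance 1,
          symmetrized; 22 descriptors (the standard 24 minus the two
          redundant ones: Sum Average duplicates 2*Joint Average on a
          symmetric matrix, Dissimilarity duplicates Difference Average);
          feature values averaged across directions.
* GLRLM — run lengths along the same 13 directions; 16 descriptors,
          averaged across directions.
* GLSZM — zone sizes via 26-connected components per grey level; 16.
* NGTDM — neighbourhood grey-tone difference over the 26-neighbourhood; 5.
* GLDM  — dependence counts (alpha = 0) over the 26-neighbourhood; 14.

Matrix builders are exposed separately from the feature functions so that
an independent brute-force enumeration can be checked against them on tiny
grids.  Degenerate regions (single grey level, single voxel) follow fixed
conventions — no feature is ever NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedVolume

__all__ = [
    "DIRECTIONS_13",
    "OFFSETS_26",
    "glcm_matrices",
    "glcm_features",
    "glrlm_matrices",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_table",
    "ngtdm_features",
    "gldm_matrix",
    "gldm_features",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "GLDM_NAMES",
]

_EPS = np.finfo(float).eps


def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if d > tuple(-c for c in d):
                    continue  # keep one of each antipodal pair
                dirs.append(d)
    return tuple(dirs)


DIRECTIONS_13 = _unique_directions()
OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


def _shifted_views(shape, d):
    """Slices (src, dst) such that arr[src] + d == arr[dst] positions."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(0, n))
            dst.append(slice(0, n))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------- GLCM


def glcm_matrices(disc: DiscretizedVolume) -> list[np.ndarray]:
    """Symmetrized co-occurrence count matrices, one per direction."""
    lev, mask, ng = disc.levels, disc.mask, disc.ng
    out = []
    for d in DIRECTIONS_13:
        src, dst = _shifted_views(lev.shape, d)
        valid = mask[src] & mask[dst]
        i = lev[src][valid] - 1
        j = lev[dst][valid] - 1
        c = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
        out.append(c + c.T)
    return out


def _glcm_single(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((p * ii).sum())
    sigma2 = float((p * (ii - mu) ** 2).sum())
    sigma = np.sqrt(sigma2)

    diff = np.abs(ii - jj)
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.array([p[diff == k].sum() for k in k_diff])
    ssum = ii + jj
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([p[ssum == k].sum() for k in k_sum])

    nz = p > 0
    joint_entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    pxnz = px[px > 0]
    hx = float(-(pxnz * np.log2(pxnz)).sum())
    pxy1 = np.outer(px, px)
    nz1 = nz & (pxy1 > 0)
    hxy1 = float(-(p[nz1] * np.log2(pxy1[nz1])).sum())
    nz2 = pxy1 > 0
    hxy2 = float(-(pxy1[nz2] * np.log2(pxy1[nz2])).sum())

    if hx > 0:
        imc1 = (joint_entropy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)), 0.0)))

    if sigma2 > 0:
        correlation = float(((p * ii * jj).sum() - mu * mu) / sigma2)
    else:
        correlation = 1.0  # single grey level: perfectly correlated by convention

    # MCC: sqrt of the second largest eigenvalue of
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) px(k))
    if ng > 1:
        safe_px = np.maximum(px, _EPS)
        q = (p / safe_px[:, None]) @ (p / safe_px[None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(ev[-2], 0.0))) if len(ev) > 1 else 1.0
    else:
        mcc = 1.0

    da = float((p_diff * k_diff).sum())
    nd = p_diff > 0
    ns = p_sum > 0
    inv_var = float((p[diff > 0] / (ii - jj)[diff > 0] ** 2).sum()) if ng > 1 else 0.0
    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "JointAverage": mu,
        "ClusterProminence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff[nd] * np.log2(p_diff[nd])).sum()),
        "DifferenceVariance": float((p_diff * (k_diff - da) ** 2).sum()),
        "Id": float((p / (1.0 + diff)).sum()),
        "Idm": float((p / (1.0 + diff**2)).sum()),
        "Idmn": float((p / (1.0 + (diff / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + diff / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointEnergy": float((p * p).sum()),
        "JointEntropy": joint_entropy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-(p_sum[ns] * np.log2(p_sum[ns])).sum()),
    }


GLCM_NAMES: tuple[str, ...] = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumEntropy",
)


def glcm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """22 GLCM descriptors averaged over the 13 directions."""
    mats = glcm_matrices(disc)
    per_dir = []
    for c in mats:
        total = c.sum()
        if total == 0:  # no valid pair along this direction (e.g. single voxel)
            continue
        per_dir.append(_glcm_single(c / total, disc.ng))
    if not per_dir:
        # single-voxel region: fixed degenerate convention
        base = _glcm_single(np.ones((1, 1)), 1)
        return {k: base[k] for k in GLCM_NAMES}
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------- GLRLM


def glrlm_matrices(disc: DiscretizedVolume) -> list[np.ndarray]:
    """Run-length count matrices P[i-1, l-1], one per direction."""
    lev, mask, ng = disc.levels, disc.mask, disc.ng
    shape = np.asarray(lev.shape)
    max_len = int(shape.max())
    coords_all = np.argwhere(mask)
    out = []
    for d in DIRECTIONS_13:
        dv = np.asarray(d)
        prev = coords_all - dv
        ok = np.all((prev >= 0) & (prev < shape), axis=1)
        prev_in = np.zeros(len(coords_all), dtype=bool)
        prev_in[ok] = mask[tuple(prev[ok].T)]
        starts = coords_all[~prev_in]  # line entry points

        mat = np.zeros((ng, max_len), dtype=float)
        pos = starts
        cur = lev[tuple(pos.T)]
        rl = np.ones(len(pos), dtype=int)
        while len(pos):
            nxt = pos + dv
            ok = np.all((nxt >= 0) & (nxt < shape), axis=1)
            in_mask = np.zeros(len(pos), dtype=bool)
            in_mask[ok] = mask[tuple(nxt[ok].T)]
            nxt_lev = np.zeros(len(pos), dtype=lev.dtype)
            nxt_lev[in_mask] = lev[tuple(nxt[in_mask].T)]
            cont = in_mask & (nxt_lev == cur)
            ended = ~cont
            if ended.any():
                np.add.at(mat, (cur[ended] - 1, rl[ended] - 1), 1.0)
            # keep walking: either continuing the run or starting a new one
            keep = in_mask
            pos = nxt[keep]
            new_run = ~cont[keep]
            cur = np.where(new_run, nxt_lev[keep], cur[keep])
            rl = np.where(new_run, 1, rl[keep] + 1)
        out.append(mat)
    return out


def _rl_style_features(mat: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared feature algebra for run-length / size-zone / dependence matrices.

    ``mat[i-1, s-1]`` counts entities (runs/zones/voxels) of grey level i and
    size s.  ``kind`` selects the naming convention.
    """
    ng, smax = mat.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    s = np.arange(1, smax + 1, dtype=float)[None, :]
    nr = mat.sum()
    if nr == 0:
        raise ValueError("empty matrix")
    p = mat / nr
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = float((pg * i[:, 0]).sum())
    mu_s = float((ps * s[0, :]).sum())
    nzp = p[p > 0]

    vals = {
        "SmallEmphasis": float((mat / s**2).sum() / nr),
        "LargeEmphasis": float((mat * s**2).sum() / nr),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((mat.sum(axis=1) ** 2).sum() / nr**2),
        "SizeNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nr),
        "SizeNonUniformityNormalized": float((mat.sum(axis=0) ** 2).sum() / nr**2),
        "Percentage": float(nr / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_g) ** 2).sum()),
        "SizeVariance": float((p * (s - mu_s) ** 2).sum()),
        "Entropy": float(-(nzp * np.log2(nzp)).sum()),
        "LowGrayLevelEmphasis": float((mat / i**2).sum() / nr),
        "HighGrayLevelEmphasis": float((mat * i**2).sum() / nr),
        "SmallLowGrayLevelEmphasis": float((mat / (i**2 * s**2)).sum() / nr),
        "SmallHighGrayLevelEmphasis": float((mat * i**2 / s**2).sum() / nr),
        "LargeLowGrayLevelEmphasis": float((mat * s**2 / i**2).sum() / nr),
        "LargeHighGrayLevelEmphasis": float((mat * i**2 * s**2).sum() / nr),
    }
    if kind == "glrlm":
        rename = {
            "SmallEmphasis": "ShortRunEmphasis",
            "LargeEmphasis": "LongRunEmphasis",
            "SizeNonUniformity": "RunLengthNonUniformity",
            "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
            "Percentage": "RunPercentage",
            "SizeVariance": "RunVariance",
            "Entropy": "RunEntropy",
            "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
            "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
            "SmallLowGrayLevelEmphasis": "ShortRunLowGrayLevelEmphasis",
            "SmallHighGrayLevelEmphasis": "ShortRunHighGrayLevelEmphasis",
            "LargeLowGrayLevelEmphasis": "LongRunLowGrayLevelEmphasis",
            "LargeHighGrayLevelEmphasis": "LongRunHighGrayLevelEmphasis",
        }
    else:  # glszm
        rename = {
            "SmallEmphasis": "SmallAreaEmphasis",
            "LargeEmphasis": "LargeAreaEmphasis",
            "SizeNonUniformity": "SizeZoneNonUniformity",
            "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
            "Percentage": "ZonePercentage",
            "SizeVariance": "ZoneVariance",
            "Entropy": "ZoneEntropy",
            "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
            "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
            "SmallLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
            "SmallHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
            "LargeLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
            "LargeHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
        }
    return {rename.get(k, k): v for k, v in vals.items()}


GLRLM_NAMES: tuple[str, ...] = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_NAMES: tuple[str, ...] = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)


def glrlm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """16 run-length descriptors averaged over the 13 directions."""
    n_vox = int(disc.mask.sum())
    per_dir = [
        _rl_style_features(m, n_vox, "glrlm") for m in glrlm_matrices(disc)
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------- GLSZM


def glszm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """Zone-size count matrix P[i-1, s-1] via 26-connected components."""
    lev, mask, ng = disc.levels, disc.mask, disc.ng
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for g in range(1, ng + 1):
        sel = (lev == g) & mask
        if not sel.any():
            continue
        lab, n_zones = ndimage.label(sel, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            zones.append((g, int(sz)))
            max_size = max(max_size, int(sz))
    mat = np.zeros((ng, max_size), dtype=float)
    for g, sz in zones:
        mat[g - 1, sz - 1] += 1.0
    return mat


def glszm_features(disc: DiscretizedVolume) -> dict[str, float]:
    mat = glszm_matrix(disc)
    feats = _rl_style_features(mat, int(disc.mask.sum()), "glszm")
    return {k: feats[k] for k in GLSZM_NAMES}


# ---------------------------------------------------------------- NGTDM


NGTDM_NAMES: tuple[str, ...] = (
    "Coarseness", "Contrast", "Busyness", "Complexity", "Strength",
)

_COARSENESS_CAP = 1e6


def ngtdm_table(disc: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) over grey levels i = 1..Ng.

    ``n_i`` counts in-mask voxels of level i that have at least one in-mask
    26-neighbour; ``s_i`` sums |i - A| over those voxels, where A is the
    mean level of the voxel's in-mask neighbours.
    """
    lev, mask, ng = disc.levels, disc.mask, disc.ng
    lv = lev.astype(np.float64) * mask
    nbr_sum = np.zeros_like(lv)
    nbr_cnt = np.zeros_like(lv)
    for d in OFFSETS_26:
        src, dst = _shifted_views(lv.shape, d)
        nbr_sum[dst] += lv[src]
        nbr_cnt[dst] += mask[src]
    valid = mask & (nbr_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(valid, nbr_sum / np.maximum(nbr_cnt, 1), 0.0)
    diff = np.abs(lev.astype(np.float64) - a) * valid
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for g in range(1, ng + 1):
        sel = valid & (lev == g)
        n_i[g - 1] = sel.sum()
        s_i[g - 1] = diff[sel].sum()
    return n_i, s_i


def ngtdm_features(disc: DiscretizedVolume) -> dict[str, float]:
    n_i, s_i = ngtdm_table(disc)
    nv = n_i.sum()
    if nv == 0:  # fully isolated voxels: flat by convention
        return {"Coarseness": _COARSENESS_CAP, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    p = n_i / nv
    i = np.arange(1, disc.ng + 1, dtype=float)
    act = p > 0
    ngp = int(act.sum())

    denom_coarse = float((p * s_i).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else _COARSENESS_CAP
    coarseness = min(coarseness, _COARSENESS_CAP)

    if ngp > 1:
        pi = p[act][:, None]
        pj = p[act][None, :]
        ii = i[act][:, None]
        jj = i[act][None, :]
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / nv)
        )
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = float((p * s_i).sum() / busy_den) if busy_den > 0 else 0.0
        si = s_i[act][:, None]
        sj = s_i[act][None, :]
        complexity = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / nv
        )
        s_sum = float(s_i.sum())
        strength = float(((pi + pj) * (ii - jj) ** 2).sum() / s_sum) if s_sum > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------- GLDM


GLDM_NAMES: tuple[str, ...] = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)


def gldm_matrix(disc: DiscretizedVolume, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix P[i-1, j-1].

    A 26-neighbour is dependent when |level difference| <= alpha; the
    dependence size j of a voxel is 1 + its dependent-neighbour count (the
    voxel itself is always dependent on itself).
    """
    lev, mask, ng = disc.levels, disc.mask, disc.ng
    dep = np.zeros(lev.shape, dtype=np.int32)
    for d in OFFSETS_26:
        src, dst = _shifted_views(lev.shape, d)
        ok = mask[src] & mask[dst] & (np.abs(lev[src].astype(int) - lev[dst].astype(int)) <= alpha)
        dep[dst] += ok
    j = dep[mask] + 1
    i = disc.levels[mask]
    max_j = int(j.max())
    mat = np.zeros((ng, max_j), dtype=float)
    np.add.at(mat, (i - 1, j - 1), 1.0)
    return mat


def gldm_features(disc: DiscretizedVolume, alpha: int = 0) -> dict[str, float]:
    mat = gldm_matrix(disc, alpha=alpha)
    base = _rl_style_features(mat, int(disc.mask.sum()), "glszm")
    rename = {
        "SmallAreaEmphasis": "SmallDependenceEmphasis",
        "LargeAreaEmphasis": "LargeDependenceEmphasis",
        "SizeZoneNonUniformity": "DependenceNonUniformity",
        "SizeZoneNonUniformityNormalized": "DependenceNonUniformityNormalized",
        "ZoneVariance": "DependenceVariance",
        "ZoneEntropy": "DependenceEntropy",
        "LowGrayLevelZoneEmphasis": "LowGrayLevelEmphasis",
        "HighGrayLevelZoneEmphasis": "HighGrayLevelEmphasis",
        "SmallAreaLowGrayLevelEmphasis": "SmallDependenceLowGrayLevelEmphasis",
        "SmallAreaHighGrayLevelEmphasis": "SmallDependenceHighGrayLevelEmphasis",
        "LargeAreaLowGrayLevelEmphasis": "LargeDependenceLowGrayLevelEmphasis",
        "LargeAreaHighGrayLevelEmphasis": "LargeDependenceHighGrayLevelEmphasis",
    }
    feats = {rename.get(k, k): v for k, v in base.items()}
    return {k: feats[k] for k in GLDM_NAMES}
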