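"""Independent brute-force oracles for the texture matrices.

Everything here is written as plain triple-loop enumeration over voxels,
deliberately sharing no code with the production implementation, so that
exact agreement on small grids is meaningful evidence of correctness.
"""

from __future__ import annotations

import numpy as np

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
HALF_13 = [d for d in ALL_26 if d > tuple(-c for c in d)]


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def brute_glcm(levels: np.ndarray, mask: np.ndarray, ng: int,
               direction: tuple[int, int, int]) -> np.ndarray:
    """Symmetrized co-occurrence counts for one direction (distance 1)."""
    mat = np.zeros((ng, ng))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                q = (x + direction[0], y + direction[1], z + direction[2])
                if _inside(shape, q) and mask[q]:
                    i = levels[x, y, z] - 1
                    j = levels[q] - 1
                    mat[i, j] += 1
                    mat[j, i] += 1
    return mat


def brute_glrlm(levels: np.ndarray, mask: np.ndarray, ng: int,
                direction: tuple[int, int, int], max_len: int) -> np.ndarray:
    """Run-length counts for one direction by explicit line walking."""
    mat = np.zeros((ng, max_len))
    shape = levels.shape
    d = direction
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                prev = (x - d[0], y - d[1], z - d[2])
                if _inside(shape, prev) and mask[prev]:
                    continue  # not a line entry point
                # walk the whole line, splitting runs on level changes
                p = (x, y, z)
                run_level = levels[p]
                run_len = 0
                while _inside(shape, p) and mask[p]:
                    if levels[p] == run_level:
                        run_len += 1
                    else:
                        mat[run_level - 1, run_len - 1] += 1
                        run_level = levels[p]
                        run_len = 1
                    p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                mat[run_level - 1, run_len - 1] += 1
    return mat


def brute_glszm(levels: np.ndarray, mask: np.ndarray, ng: int,
                max_size: int) -> np.ndarray:
    """Zone sizes by flood fill over the 26-neighbourhood, per grey level."""
    mat = np.zeros((ng, max_size))
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                g = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in ALL_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if (_inside(shape, q) and mask[q] and not seen[q]
                                and levels[q] == g):
                            seen[q] = True
                            stack.append(q)
                mat[g - 1, size - 1] += 1
    return mat


def brute_ngtdm(levels: np.ndarray, mask: np.ndarray, ng: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i): voxel counts and summed |i - neighbourhood mean|."""
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                nbrs = []
                for d in ALL_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and mask[q]:
                        nbrs.append(levels[q])
                if not nbrs:
                    continue
                g = levels[x, y, z]
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - np.mean(nbrs))
    return n_i, s_i


def brute_gldm(levels: np.ndarray, mask: np.ndarray, ng: int,
               alpha: int = 0) -> np.ndarray:
    """Dependence counts: j = 1 + #neighbours with |level diff| <= alpha."""
    shape = levels.shape
    rows = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                dep = 0
                for d in ALL_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if (_inside(shape, q) and mask[q]
                            and abs(int(levels[q]) - int(levels[x, y, z])) <= alpha):
                        dep += 1
                rows.append((levels[x, y, z], dep + 1))
    max_j = max(j for _, j in rows)
    mat = np.zeros((ng, max_j))
    for g, j in rows:
        mat[g - 1, j - 1] += 1
    return mat


def brute_calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """CH score straight from its definition, loop per cluster."""
    X = np.asarray(X, float)
    n = len(X)
    uniq = sorted(set(labels.tolist()))
    k = len(uniq)
    centre = X.mean(axis=0)
    b = 0.0
    w = 0.0
    for u in uniq:
        grp = X[np.asarray(labels) == u]
        mu = grp.mean(axis=0)
        b += len(grp) * np.sum((mu - centre) ** 2)
        w += np.sum((grp - mu) ** 2)
    if w == 0:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def brute_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC by exhaustive pair counting with half credit for ties."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
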