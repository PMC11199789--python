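"""Voxel feature maps, clustering, CH-based K selection, habitat masks."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from habitatrad.habitat import (
    build_habitat_masks,
    calinski_harabasz,
    cluster_habitats,
    extract_habitat_features,
    kmeans_cluster,
    labeling_to_map,
    select_optimal_k,
    voxel_feature_maps,
)
from habitatrad.phantom import PhantomSpec, generate_lesion

from . import oracles
from .conftest import make_mask, make_volume


def test_constant_image_gives_all_zero_zscored_matrix():
    img = make_volume(np.full((8, 8, 8), 12.0))
    msk = make_mask(np.ones((8, 8, 8)))
    m = voxel_feature_maps(img, msk)
    assert m.n_voxels == 512
    np.testing.assert_array_equal(m.values, 0.0)


def test_local_mean_of_linear_ramp_is_the_ramp_interior():
    ramp = np.tile(np.arange(10.0)[:, None, None], (1, 10, 10))
    img = make_volume(ramp)
    msk = make_mask(np.ones((10, 10, 10)))
    m = voxel_feature_maps(img, msk, feature_names=("intensity", "local_mean"))
    lm = np.zeros((10, 10, 10))
    lm[tuple(m.coords.T)] = m.raw[:, 1]
    interior = lm[1:-1, 1:-1, 1:-1]
    np.testing.assert_allclose(interior, ramp[1:-1, 1:-1, 1:-1], atol=1e-9)


def test_row_count_equals_mask_foreground(small_lesion):
    img, msk, _ = small_lesion
    m = voxel_feature_maps(img, msk)
    assert m.n_voxels == msk.n_foreground


def test_kmeans_basics():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 2))
    labels, wss = kmeans_cluster(X, 1)
    assert set(labels) == {0}
    assert wss == pytest.approx(((X - X.mean(0)) ** 2).sum())

    blobs = np.vstack([rng.normal(0, 0.1, (40, 2)), rng.normal(8, 0.1, (40, 2))])
    lab, _ = kmeans_cluster(blobs, 2, seed=1)
    truth = np.array([0] * 40 + [1] * 40)
    assert adjusted_rand_score(truth, lab) == 1.0

    with pytest.raises(ValueError):
        kmeans_cluster(X, 51)


def test_wss_non_increasing_in_k():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(120, 3))
    wss = [kmeans_cluster(X, k, seed=0)[1] for k in range(1, 7)]
    assert all(a >= b - 1e-9 for a, b in zip(wss, wss[1:]))


def test_calinski_harabasz_formula_and_sentinel():
    # perfectly tight clusters -> +inf sentinel
    X = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0]).reshape(-1, 1)
    labels = np.array([0, 0, 0, 1, 1, 1])
    assert calinski_harabasz(X, labels) == float("inf")

    # jittered version agrees with brute force and sklearn
    Xj = np.array([0.0, 0.1, -0.1, 10.0, 10.1, 9.9]).reshape(-1, 1)
    ours = calinski_harabasz(Xj, labels)
    assert ours == pytest.approx(oracles.brute_calinski_harabasz(Xj, labels))
    assert ours == pytest.approx(calinski_harabasz_score(Xj, labels))

    # label permutation symmetry
    assert calinski_harabasz(Xj, 1 - labels) == pytest.approx(ours)

    with pytest.raises(ValueError):
        calinski_harabasz(Xj, np.zeros(6, dtype=int))


def test_random_labels_on_noise_score_near_one():
    rng = np.random.default_rng(5)
    scores = []
    for _ in range(20):
        X = rng.normal(size=(60, 3))
        labels = rng.integers(0, 3, size=60)
        if len(np.unique(labels)) < 2:
            continue
        scores.append(calinski_harabasz(X, labels))
    assert 0.5 < np.mean(scores) < 2.0


def _phantom_matrix(k_true, seed, means=None):
    means = means or tuple(np.linspace(-150, 150, k_true))
    spec = PhantomSpec(grid_shape=(32, 32, 32), lesion_radii=(10.0, 9.0, 8.0),
                       k_true=k_true, habitat_means=means,
                       habitat_texture_scales=(1.5,) * k_true,
                       texture_sd=10.0, noise_sd=10.0, seed=seed)
    img, msk, hab = generate_lesion(spec)
    return img, msk, hab, voxel_feature_maps(img, msk)


@pytest.mark.parametrize("k_true", [2, 4])
def test_select_optimal_k_recovers_planted_k(k_true):
    _, _, _, matrix = _phantom_matrix(k_true, seed=17)
    k, curve = select_optimal_k(matrix, seed=0)
    assert k == k_true
    assert set(curve) == set(range(2, 11))


def test_pure_noise_matrix_selects_k_min():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(400, 3))
    k, _ = select_optimal_k(X, seed=0)
    assert k == 2


def test_noiseless_distinct_means_cluster_perfectly():
    """Intensity alone separates habitats exactly when noise is zero."""
    spec = PhantomSpec(grid_shape=(28, 28, 28), lesion_radii=(9.0, 8.0, 8.0),
                       k_true=3, habitat_means=(-100.0, 0.0, 100.0),
                       habitat_texture_scales=(1.0,) * 3,
                       texture_sd=0.0, noise_sd=0.0, seed=1)
    img, msk, hab = generate_lesion(spec)
    m = voxel_feature_maps(img, msk, feature_names=("intensity",))
    labels, _ = kmeans_cluster(m, 3, seed=0)
    assert adjusted_rand_score(hab[msk.voxels > 0], labels) == 1.0


def test_habitat_masks_partition_roi(small_lesion):
    img, msk, _ = small_lesion
    matrix, labeling = cluster_habitats(img, msk, k=4, seed=0)
    masks = build_habitat_masks(msk, matrix, labeling)
    assert len(masks) == 4
    union = sum(m.voxels.astype(int) for m in masks)
    np.testing.assert_array_equal(union, msk.voxels)
    # h1 has the highest mean intensity (ordering rule)
    means = [img.voxels[m.voxels > 0].mean() for m in masks if m.n_foreground]
    assert all(a >= b for a, b in zip(means, means[1:]))


def test_habitat_ordering_invariant_to_cluster_relabeling(small_lesion):
    """Different k-means seeds yielding the same partition produce identical
    habitat maps thanks to the intensity-ordering rule."""
    img, msk, _ = small_lesion
    maps = []
    for seed in (0, 1, 2):
        matrix, labeling = cluster_habitats(img, msk, k=4, seed=seed)
        maps.append(labeling_to_map(msk, matrix, labeling))
    np.testing.assert_array_equal(maps[0], maps[1])
    np.testing.assert_array_equal(maps[0], maps[2])


def test_k1_yields_single_mask_equal_to_roi(small_lesion):
    img, msk, _ = small_lesion
    matrix, labeling = cluster_habitats(img, msk, k=1, seed=0)
    masks = build_habitat_masks(msk, matrix, labeling)
    assert len(masks) == 1
    np.testing.assert_array_equal(masks[0].voxels, msk.voxels)


def test_habitat_feature_names_and_missing_policy(small_lesion):
    img, msk, _ = small_lesion
    matrix, labeling = cluster_habitats(img, msk, k=4, seed=0)
    masks = build_habitat_masks(msk, matrix, labeling)
    rec = extract_habitat_features(img, masks)
    assert len(rec) == 7280
    for h in range(1, 5):
        assert sum(name.endswith(f"_h{h}") for name in rec) == 1820

    # a too-small habitat produces NaN placeholders, names unchanged
    tiny = [masks[0], make_mask(np.zeros(msk.shape))]
    tiny[1].voxels[0, 0, 0] = 1
    tiny[1] = make_mask(tiny[1].voxels)
    rec2 = extract_habitat_features(img, tiny, min_voxels=10)
    assert len(rec2) == 2 * 1820
    h2_vals = [v for k, v in rec2.items() if k.endswith("_h2")]
    assert all(np.isnan(v) for v in h2_vals)
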