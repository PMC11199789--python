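"""Shared fixtures: small phantoms and tiny discretized grids."""

from __future__ import annotations

import numpy as np
import pytest

from habitatrad.imaging import BinaryMask, ImageVolume
from habitatrad.phantom import PhantomSpec, generate_lesion
from habitatrad.radiomics.discretize import DiscretizedVolume


@pytest.fixture(scope="session")
def small_lesion():
    """A 4-habitat lesion small enough for fast whole-record extraction."""
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        lesion_radii=(10.0, 9.0, 8.0),
        k_true=4,
        habitat_means=(-150.0, -50.0, 50.0, 150.0),
        habitat_texture_scales=(1.0, 2.0, 3.0, 4.0),
        texture_sd=10.0,
        noise_sd=10.0,
        seed=42,
    )
    return generate_lesion(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240612)


def random_disc(rng: np.random.Generator, shape=(4, 4, 4), ng=4,
                mask_fraction=0.8) -> DiscretizedVolume:
    """A random small discretized volume with a random mask."""
    mask = rng.random(shape) < mask_fraction
    if not mask.any():
        mask.flat[0] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    ng_eff = int(levels.max())
    return DiscretizedVolume(levels=levels, mask=mask, ng=ng_eff, bin_width=1.0)


def make_volume(arr, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    return ImageVolume(np.asarray(arr, dtype=float), spacing)


def make_mask(arr, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    return BinaryMask(np.asarray(arr), spacing)
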