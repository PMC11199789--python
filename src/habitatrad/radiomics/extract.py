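"""Whole-record feature extraction: filter bank x feature classes.

Shape descriptors (14) are computed once on the original mask.  First-order
(18) and the five texture classes (22 + 16 + 16 + 5 + 14 = 73) are computed
on each of the 20 filter-bank volumes, for 20 x 91 = 1820 non-shape
features; 1834 in total with shape.  Feature names follow
``<imagetype>_<class>_<feature>``.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from ..imaging import BinaryMask, ImageVolume, check_geometry
from .discretize import DEFAULT_BIN_WIDTH_HU, bin_width_for, discretize
from .filters import FILTER_NAMES, apply_filter_bank
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "extract_features",
    "feature_name_inventory",
    "feature_class_counts",
    "N_FEATURES_WITH_SHAPE",
    "N_FEATURES_NO_SHAPE",
]

_CLASS_NAMES = {
    "firstorder": FIRST_ORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}

N_FEATURES_NO_SHAPE = len(FILTER_NAMES) * sum(len(v) for v in _CLASS_NAMES.values())
N_FEATURES_WITH_SHAPE = N_FEATURES_NO_SHAPE + len(SHAPE_NAMES)


def feature_name_inventory(include_shape: bool = True) -> list[str]:
    """The full ordered feature-name list the extractor produces."""
    names = []
    if include_shape:
        names += [f"original_shape_{n}" for n in SHAPE_NAMES]
    for img_type in FILTER_NAMES:
        for cls, feats in _CLASS_NAMES.items():
            names += [f"{img_type}_{cls}_{n}" for n in feats]
    return names


def feature_class_counts(record: dict[str, float]) -> dict[str, int]:
    """Tally features per class across all image types."""
    counts: dict[str, int] = {}
    for name in record:
        cls = name.split("_")[1]
        counts[cls] = counts.get(cls, 0) + 1
    return counts


def extract_features(
    image: ImageVolume,
    mask: BinaryMask,
    include_shape: bool = True,
    bin_width: float = DEFAULT_BIN_WIDTH_HU,
    filter_bank: dict[str, np.ndarray] | None = None,
) -> "OrderedDict[str, float]":
    """Extract the full radiomics record for one image/mask pair.

    Returns 1834 named features with shape, 1820 without.  All values are
    finite by construction of the per-class degenerate conventions.
    ``filter_bank`` lets callers reuse the (mask-independent) derived
    volumes when extracting several sub-masks of the same image.
    """
    check_geometry(image, mask)
    mask.require_nonempty()
    m = mask.voxels.astype(bool)
    record: "OrderedDict[str, float]" = OrderedDict()

    if include_shape:
        for name, val in shape_features(m, image.spacing).items():
            record[f"original_shape_{name}"] = val

    bank = filter_bank if filter_bank is not None else apply_filter_bank(image)
    for img_type, arr in bank.items():
        bw = bin_width_for(img_type, arr, m, bin_width)
        disc = discretize(arr, m, bw)
        fo = first_order_features(arr, m, bw, voxel_volume=image.voxel_volume)
        for name, val in fo.items():
            record[f"{img_type}_firstorder_{name}"] = val
        for cls, fn in (
            ("glcm", glcm_features),
            ("glrlm", glrlm_features),
            ("glszm", glszm_features),
            ("ngtdm", ngtdm_features),
            ("gldm", gldm_features),
        ):
            for name, val in fn(disc).items():
                record[f"{img_type}_{cls}_{name}"] = val

    expected = N_FEATURES_WITH_SHAPE if include_shape else N_FEATURES_NO_SHAPE
    assert len(record) == expected, (len(record), expected)
    return record
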