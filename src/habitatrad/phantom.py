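"""Synthetic CT lesion phantoms with planted habitat structure.

Real multicenter chest-CT cohorts for neoadjuvant immunochemotherapy are not
publicly depositable, so every downstream stage of the pipeline is exercised
on phantoms: ellipsoidal lesions embedded in a soft-tissue-like background,
partitioned into ``k_true`` habitats that differ in mean attenuation and in
texture correlation length.  Habitats are laid out as concentric shells by
default (mimicking perfusion-driven core/rim heterogeneity) or as angular
wedges.  The two-class cohort generator plants the outcome signal in habitat
*composition*: positive-class lesions tilt their habitat volume fractions
toward the innermost habitats.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import BinaryMask, ImageVolume, write_labelmap, write_mask, write_volume

__all__ = ["PhantomSpec", "CohortSpec", "generate_lesion", "generate_cohort",
           "perturb_mask", "write_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic lesion.

    ``habitat_fractions`` are target volume fractions of the planted
    habitats (innermost first for the shell layout); ``None`` means equal
    fractions.  ``texture_sd`` is the standard deviation (HU) of the
    spatially correlated texture component added inside each habitat.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_radii: tuple[float, float, float] = (15.0, 13.0, 12.0)  # mm semi-axes
    k_true: int = 4
    habitat_means: tuple[float, ...] = (-100.0, 0.0, 60.0, 120.0)  # HU
    habitat_texture_scales: tuple[float, ...] = (0.8, 1.5, 2.5, 4.0)  # mm
    habitat_fractions: tuple[float, ...] | None = None
    texture_sd: float = 15.0
    noise_sd: float = 10.0
    background_mean: float = -780.0  # aerated-lung-like HU
    layout: str = "shells"  # or "wedges"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if len(self.habitat_means) != self.k_true:
            raise ValueError("habitat_means must have k_true entries")
        if len(self.habitat_texture_scales) != self.k_true:
            raise ValueError("habitat_texture_scales must have k_true entries")
        if self.habitat_fractions is not None:
            f = np.asarray(self.habitat_fractions, float)
            if len(f) != self.k_true or np.any(f <= 0):
                raise ValueError("habitat_fractions must be k_true positive values")
        if self.noise_sd < 0 or self.texture_sd < 0:
            raise ValueError("noise_sd and texture_sd must be >= 0")
        if self.layout not in ("shells", "wedges"):
            raise ValueError(f"unknown layout {self.layout!r}")
        half_extent = np.asarray(self.grid_shape) * np.asarray(self.spacing) / 2.0
        if np.any(np.asarray(self.lesion_radii) >= half_extent):
            raise ValueError(
                f"lesion radii {self.lesion_radii} mm do not fit inside the grid "
                f"(half extents {tuple(half_extent)} mm)"
            )

    def fractions(self) -> np.ndarray:
        if self.habitat_fractions is None:
            return np.full(self.k_true, 1.0 / self.k_true)
        f = np.asarray(self.habitat_fractions, float)
        return f / f.sum()


@dataclass(frozen=True)
class CohortSpec:
    """A two-class phantom cohort.

    ``pcr_fraction`` defaults to the pathologic-complete-response prevalence
    of the motivating multicenter cohort (36%).  ``effect`` >= 0 tilts the
    habitat volume fractions of positive-class lesions toward the inner
    habitats; ``effect = 0`` yields exchangeable classes (a null cohort).
    """

    n: int = 50
    pcr_fraction: float = 0.36
    effect: float = 1.0
    base: PhantomSpec = field(default_factory=PhantomSpec)
    radius_jitter: float = 0.15  # relative sd of per-subject semi-axis scaling
    composition_jitter: float = 0.3  # sd of per-subject log habitat weights
    mean_jitter: float = 5.0  # HU sd of per-subject habitat mean offsets
    composition_tilt: float = 0.3  # log-weight tilt magnitude per unit effect
    tilt_vector: tuple[float, ...] | None = None  # direction of the tilt;
    # None -> linspace(1, -1, K), i.e. mass moves toward the innermost habitat
    focal_shift_hu: float = 10.0  # attenuation shift of habitat 2 per unit effect
    scale_jitter: float = 0.25  # log-sd of per-subject texture-scale variation
    texture_scale_shift: float = 0.0  # log texture-scale shift of habitat 2
    # per unit effect: changes that habitat's micro-structure without
    # touching the intensity histogram
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pcr_fraction <= 1.0:
            raise ValueError("pcr_fraction must be in [0, 1]")
        if self.n < 2:
            raise ValueError("cohort needs n >= 2")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        n_pos = int(round(self.n * self.pcr_fraction))
        if 0.0 < self.pcr_fraction < 1.0 and not 0 < n_pos < self.n:
            raise ValueError("cohort must contain at least one sample per class")


def _normalized_radius(spec: PhantomSpec) -> np.ndarray:
    """Ellipsoidal coordinate rho: rho<=1 inside the lesion."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.grid_shape, spec.spacing)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    a, b, c = spec.lesion_radii
    return np.sqrt((xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2)


def _habitat_map(spec: PhantomSpec, rho: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Integer habitat labels 1..K inside the mask, 0 outside."""
    fr = spec.fractions()
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    if spec.layout == "shells":
        # equal-volume shells: radius thresholds at cumulative fraction^(1/3)
        cum = np.cumsum(fr)
        thresholds = cum ** (1.0 / 3.0)
        lab = np.searchsorted(thresholds, rho, side="left") + 1
        labels[mask] = np.clip(lab[mask], 1, spec.k_true)
    else:  # wedges: azimuthal sectors proportional to fractions
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(spec.grid_shape, spec.spacing)
        ]
        xx, yy, _ = np.meshgrid(*axes, indexing="ij")
        theta = np.mod(np.arctan2(yy, xx), 2 * np.pi)
        edges = 2 * np.pi * np.cumsum(fr)
        lab = np.searchsorted(edges, theta, side="left") + 1
        labels[mask] = np.clip(lab[mask], 1, spec.k_true)
    return labels


def _correlated_noise(rng: np.random.Generator, shape, sigma_voxels) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length ``sigma``."""
    w = rng.standard_normal(shape)
    if np.all(np.asarray(sigma_voxels) < 1e-6):
        return w
    f = ndimage.gaussian_filter(w, sigma=sigma_voxels, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_lesion(
    spec: PhantomSpec,
) -> tuple[ImageVolume, BinaryMask, np.ndarray]:
    """Build one lesion: image, ROI mask and ground-truth habitat map.

    The image is ``habitat mean + correlated texture + white noise`` inside
    the lesion and ``background_mean`` (plus noise) outside.  Deterministic
    for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rho = _normalized_radius(spec)
    mask = rho <= 1.0
    n_fg = int(mask.sum())
    if n_fg == 0:
        raise ValueError("lesion contains no voxels at this grid/spacing")
    if spec.k_true > n_fg:
        raise ValueError(
            f"k_true={spec.k_true} exceeds the lesion voxel count {n_fg}"
        )
    habitats = _habitat_map(spec, rho, mask)

    img = np.full(spec.grid_shape, spec.background_mean, dtype=np.float64)
    for k in range(1, spec.k_true + 1):
        sel = habitats == k
        if not sel.any():
            continue
        img[sel] = spec.habitat_means[k - 1]
        if spec.texture_sd > 0:
            sigma_vox = tuple(
                spec.habitat_texture_scales[k - 1] / s for s in spec.spacing
            )
            tex = _correlated_noise(rng, spec.grid_shape, sigma_vox)
            img[sel] += spec.texture_sd * tex[sel]
    if spec.noise_sd > 0:
        img += spec.noise_sd * rng.standard_normal(spec.grid_shape)

    volume = ImageVolume(img, spec.spacing)
    roi = BinaryMask(mask.astype(np.uint8), spec.spacing)
    return volume, roi, habitats


def _class_fractions(base: PhantomSpec, log_tilt: float,
                     tilt_vector=None) -> np.ndarray:
    """Positive-class habitat fractions: an exponential log-weight tilt."""
    f = base.fractions()
    if base.k_true == 1:
        return f
    tilt = (np.asarray(tilt_vector, float) if tilt_vector is not None
            else np.linspace(1.0, -1.0, base.k_true))
    g = f * np.exp(log_tilt * tilt)
    return g / g.sum()


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[tuple[ImageVolume, BinaryMask, np.ndarray]], np.ndarray]:
    """Generate ``spec.n`` lesions and binary labels.

    Exactly ``round(n * pcr_fraction)`` samples are positive.  The class
    effect has two components, both scaled by ``spec.effect``: a volume-
    fraction tilt toward the innermost habitat (``composition_tilt``) and a
    focal attenuation shift of the second habitat (``focal_shift_hu``) —
    the kind of localized change a whole-ROI histogram dilutes but a
    habitat-resolved model isolates.  Subject-level variability (semi-axis
    scaling, log-normal composition jitter, habitat-mean jitter, independent
    texture seeds) makes the classes overlap, so discrimination is a
    statistical problem rather than a lookup.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n * spec.pcr_fraction))
    labels = np.zeros(spec.n, dtype=int)
    labels[:n_pos] = 1
    labels = labels[rng.permutation(spec.n)]

    child_seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n) % (2**31)
    pos_fractions = _class_fractions(spec.base, spec.effect * spec.composition_tilt,
                                     spec.tilt_vector)
    neg_fractions = spec.base.fractions()
    base_means = np.asarray(spec.base.habitat_means, float)
    k = spec.base.k_true
    lesions = []
    for i in range(spec.n):
        scale = float(
            np.clip(1.0 + spec.radius_jitter * rng.standard_normal(), 0.6, 1.6)
        )
        radii = tuple(r * scale for r in spec.base.lesion_radii)
        class_f = pos_fractions if labels[i] == 1 else neg_fractions
        w = class_f * np.exp(spec.composition_jitter * rng.standard_normal(k))
        means = base_means + spec.mean_jitter * rng.standard_normal(k)
        scales = np.asarray(spec.base.habitat_texture_scales, float) * np.exp(
            spec.scale_jitter * rng.standard_normal(k)
        )
        if labels[i] == 1 and k >= 2:
            means[1] += spec.effect * spec.focal_shift_hu
            scales[1] *= np.exp(spec.effect * spec.texture_scale_shift)
        sub = replace(
            spec.base,
            lesion_radii=radii,
            habitat_fractions=tuple(w / w.sum()),
            habitat_means=tuple(means),
            habitat_texture_scales=tuple(scales),
            seed=int(child_seeds[i]),
        )
        lesions.append(generate_lesion(sub))
    return lesions, labels


def perturb_mask(mask: BinaryMask, boundary_jitter: float, seed: int = 0) -> BinaryMask:
    """Simulate a second rater's segmentation by jittering the ROI boundary.

    A smooth random field (correlation length ~3 voxels), scaled to
    ``boundary_jitter`` mm, displaces the zero level of the signed distance
    to the original boundary, producing local dilations and erosions of up
    to the jitter amplitude.
    """
    if boundary_jitter < 0:
        raise ValueError("boundary_jitter must be >= 0")
    mask.require_nonempty()
    if boundary_jitter == 0:
        return BinaryMask(mask.voxels.copy(), mask.spacing, mask.origin, mask.direction)

    rng = np.random.default_rng(seed)
    inside = mask.voxels > 0
    # signed distance (mm) to the boundary surface, which lies half a voxel
    # beyond the outermost inside voxel centers: negative inside, positive out
    half = float(np.mean(mask.spacing)) / 2.0
    d_out = ndimage.distance_transform_edt(~inside, sampling=mask.spacing)
    d_in = ndimage.distance_transform_edt(inside, sampling=mask.spacing)
    signed = np.where(inside, -(d_in - half), d_out - half)
    fld = _correlated_noise(rng, mask.shape, sigma_voxels=(3.0, 3.0, 3.0))
    # displacement sd = jitter/2 with a hard bound at +-jitter
    fld = np.clip(fld * (boundary_jitter / 2.0), -boundary_jitter, boundary_jitter)
    new = signed <= fld
    overlap = int(np.logical_and(new, inside).sum())
    if overlap == 0 or not new.any():
        raise ValueError(
            f"boundary_jitter={boundary_jitter} mm destroys the mask "
            f"(lesion too small for this perturbation)"
        )
    return BinaryMask(new.astype(np.uint8), mask.spacing, mask.origin, mask.direction)


def write_cohort(
    lesions: list[tuple[ImageVolume, BinaryMask, np.ndarray]],
    labels: np.ndarray,
    out_dir: str | Path,
) -> list[str]:
    """Persist a cohort: per-subject NIfTI image/mask/habitat map + labels CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = []
    for i, (img, msk, hab) in enumerate(lesions):
        pid = f"P{i:04d}"
        write_volume(img, out_dir / f"{pid}_image.nii.gz")
        write_mask(msk, out_dir / f"{pid}_mask.nii.gz")
        write_labelmap(hab, img, out_dir / f"{pid}_habitats_true.nii.gz")
        ids.append(pid)
    with open(out_dir / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "label"])
        for pid, lab in zip(ids, labels):
            w.writerow([pid, int(lab)])
    return ids
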