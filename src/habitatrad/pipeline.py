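"""End-to-end orchestration of the two experiment arms.

The *radiomics arm* extracts one whole-ROI feature record per patient
(shape included); the *habitat arm* clusters each tumor into habitats and
concatenates per-habitat non-shape records.  Both arms then share the same
selection-cascade and logistic-regression code path, so any performance
difference is attributable to the feature representation.

Cohort splits are explicit inputs (a train/validation tag per sample),
never randomized internally.  All stochastic stages derive their seeds from
one root seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .evaluation import EvalReport, FittedModel, choose_threshold, evaluate, fit_lr, predict_proba
from .habitat import (
    DEFAULT_VOXEL_FEATURES,
    build_habitat_masks,
    cluster_habitats,
    extract_habitat_features,
    select_optimal_k,
    voxel_feature_maps,
)
from .imaging import BinaryMask, ImageVolume, crop_to_roi, resample_pair
from .phantom import perturb_mask
from .radiomics import extract_features
from .selection import (
    SelectionReport,
    icc_filter,
    impute_missing,
    run_selection_cascade,
    zscore_apply,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ArmResult",
    "RunManifest",
    "Sample",
    "prepare_sample",
    "extract_cohort_table",
    "extract_habitat_table",
    "calibrate_k",
    "run_radiomics_arm",
    "run_habitat_arm",
    "run_icc_study",
]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one place."""

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    crop_margin_voxels: int = 2
    bin_width: float = 25.0
    kernel_radius: int = 1
    voxel_features: tuple[str, ...] = DEFAULT_VOXEL_FEATURES
    k: int | None = None  # fixed habitat count; None selects via CH
    k_min: int = 2
    k_max: int = 10
    elbow_rule: str = "knee"
    icc_threshold: float = 0.75
    alpha: float = 0.05
    r_threshold: float = 0.9
    folds: int = 10
    min_habitat_voxels: int = 10
    resample: bool = False  # phantoms are already isotropic
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold must be in (0, 1]")
        if not 0 <= self.icc_threshold <= 1:
            raise ValueError("icc_threshold must be in [0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Sample:
    sample_id: str
    image: ImageVolume
    mask: BinaryMask


@dataclass
class ArmResult:
    arm: str
    model: FittedModel
    selection: SelectionReport
    train_report: EvalReport
    validation_report: EvalReport | None
    feature_table: pd.DataFrame
    k_used: int | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)

    def add_file(self, path) -> None:
        h = hashlib.sha256(open(path, "rb").read()).hexdigest()[:16]
        self.checksums[str(path)] = h

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def prepare_sample(sample: Sample, config: PipelineConfig) -> Sample:
    """Shared preprocessing: optional isotropic resampling, then ROI crop."""
    image, mask = sample.image, sample.mask
    if config.resample:
        image, mask = resample_pair(image, mask, config.target_spacing)
    image, mask = crop_to_roi(image, mask, margin_voxels=config.crop_margin_voxels)
    return Sample(sample.sample_id, image, mask)


def extract_cohort_table(
    samples: list[Sample], config: PipelineConfig, include_shape: bool = True
) -> pd.DataFrame:
    """Whole-ROI feature table: one row per sample."""
    rows = {}
    for s in samples:
        p = prepare_sample(s, config)
        rows[s.sample_id] = extract_features(
            p.image, p.mask, include_shape=include_shape, bin_width=config.bin_width
        )
    return pd.DataFrame.from_dict(rows, orient="index")


def calibrate_k(
    samples: list[Sample], config: PipelineConfig, max_cases: int = 20
) -> tuple[int, list[int]]:
    """Cohort-wide habitat count: per-lesion CH selection, then the mode.

    Ties in the vote break toward smaller K for parsimony.
    """
    votes = []
    for s in samples[:max_cases]:
        p = prepare_sample(s, config)
        matrix = voxel_feature_maps(
            p.image, p.mask, kernel_radius=config.kernel_radius,
            feature_names=config.voxel_features,
        )
        k, _ = select_optimal_k(
            matrix, config.k_min, config.k_max, seed=config.seed,
            rule=config.elbow_rule,
        )
        votes.append(k)
    counts = Counter(votes)
    top = max(counts.values())
    k_star = min(k for k, c in counts.items() if c == top)
    return k_star, votes


def extract_habitat_table(
    samples: list[Sample], config: PipelineConfig, k: int
) -> pd.DataFrame:
    """Per-habitat feature table (K x 1820 columns), habitats ordered h1..hK."""
    rows = {}
    for s in samples:
        p = prepare_sample(s, config)
        matrix, labeling = cluster_habitats(
            p.image, p.mask, k=k, seed=config.seed,
            kernel_radius=config.kernel_radius, rule=config.elbow_rule,
        )
        masks = build_habitat_masks(p.mask, matrix, labeling)
        rows[s.sample_id] = extract_habitat_features(
            p.image, masks, min_voxels=config.min_habitat_voxels,
            bin_width=config.bin_width,
        )
    return pd.DataFrame.from_dict(rows, orient="index")


def _fit_and_eval(
    arm: str,
    table: pd.DataFrame,
    labels: np.ndarray,
    split: np.ndarray,
    config: PipelineConfig,
    k_used: int | None = None,
) -> ArmResult:
    """The selection + modeling + evaluation path shared by both arms.

    Everything is fitted on the training rows; validation rows are
    transformed with frozen parameters and scored at the frozen threshold.
    """
    labels = np.asarray(labels).astype(int)
    split = np.asarray(split)
    is_train = split == "train"
    if is_train.sum() < 4:
        raise ValueError("training split too small")
    train_tbl = table.loc[is_train]
    y_train = labels[is_train]

    report = run_selection_cascade(
        train_tbl, y_train, alpha=config.alpha, r_threshold=config.r_threshold,
        folds=config.folds, seed=config.seed,
    )
    selected = report.after_lasso

    def _transform(tbl: pd.DataFrame) -> np.ndarray:
        filled, _ = impute_missing(tbl, report.medians)
        z = zscore_apply(filled, report.zscore)
        return z[selected].to_numpy(dtype=float)

    X_train = _transform(train_tbl)
    model = fit_lr(X_train, y_train, provenance={
        "arm": arm, "seed": config.seed, "lambda_star": report.lasso.lambda_star,
        "config_hash": config.hash(),
    })
    model.feature_names = list(selected)
    p_train = predict_proba(model, X_train)
    model.threshold = choose_threshold(p_train, y_train)

    train_report = evaluate(p_train, y_train, model.threshold)
    val_report = None
    if (~is_train).any():
        val_tbl = table.loc[~is_train]
        X_val = _transform(val_tbl)
        p_val = predict_proba(model, X_val)
        val_report = evaluate(p_val, labels[~is_train], model.threshold)

    return ArmResult(
        arm=arm, model=model, selection=report, train_report=train_report,
        validation_report=val_report, feature_table=table, k_used=k_used,
    )


def run_radiomics_arm(
    samples: list[Sample],
    labels: np.ndarray,
    split: np.ndarray,
    config: PipelineConfig,
    icc_retained: list[str] | None = None,
    table: pd.DataFrame | None = None,
) -> ArmResult:
    """Conventional whole-ROI radiomics model (1834 features, shape included)."""
    if table is None:
        table = extract_cohort_table(samples, config, include_shape=True)
    if icc_retained is not None:
        table = table[[c for c in table.columns if c in set(icc_retained)]]
    return _fit_and_eval("radiomics", table, labels, split, config)


def run_habitat_arm(
    samples: list[Sample],
    labels: np.ndarray,
    split: np.ndarray,
    config: PipelineConfig,
    icc_retained: list[str] | None = None,
    table: pd.DataFrame | None = None,
) -> ArmResult:
    """Habitat model: per-habitat feature fusion over a cohort-wide K."""
    k = config.k
    if table is None:
        if k is None:
            train_samples = [s for s, sp in zip(samples, split) if sp == "train"]
            k, votes = calibrate_k(train_samples, config)
            logger.info("calibrated habitat count K=%d (votes %s)", k, votes)
        table = extract_habitat_table(samples, config, k)
    return _fit_and_eval("habitat", table, labels, split, config, k_used=k)


def run_icc_study(
    samples: list[Sample],
    config: PipelineConfig,
    n_cases: int = 50,
    boundary_jitter: float = 1.0,
    include_shape: bool = True,
) -> tuple[list[str], pd.Series]:
    """Segmentation-robustness filter: features stable under mask perturbation.

    Re-extracts features from ``n_cases`` samples with a jittered mask
    emulating a second rater and retains features with ICC(2,1) >= the
    configured threshold.
    """
    if n_cases > len(samples):
        raise ValueError(f"n_cases={n_cases} exceeds cohort size {len(samples)}")
    rows1, rows2 = {}, {}
    for i, s in enumerate(samples[:n_cases]):
        p = prepare_sample(s, config)
        mask2 = perturb_mask(p.mask, boundary_jitter, seed=config.seed + 7919 * i)
        rows1[s.sample_id] = extract_features(
            p.image, p.mask, include_shape=include_shape, bin_width=config.bin_width)
        rows2[s.sample_id] = extract_features(
            p.image, mask2, include_shape=include_shape, bin_width=config.bin_width)
    t1 = pd.DataFrame.from_dict(rows1, orient="index")
    t2 = pd.DataFrame.from_dict(rows2, orient="index")
    return icc_filter(t1, t2, threshold=config.icc_threshold)
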