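"""Feature-selection cascade: ICC filter, z-scoring, t-test screen,
Pearson redundancy pruning, cross-validated LASSO, and the composite score.

All fitting statistics (means, SDs, medians, test statistics, penalty path)
are computed on the training cohort only; validation data are transformed
with frozen parameters.  Retained feature sets are strictly nested across
the stages.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "icc_filter",
    "icc_2_1",
    "ZScoreParams",
    "zscore_fit",
    "zscore_apply",
    "ttest_filter",
    "pearson_prune",
    "LassoResult",
    "lasso_cv_select",
    "composite_score",
    "SelectionReport",
    "run_selection_cascade",
    "impute_missing",
]


# ------------------------------------------------------------------ ICC


def icc_2_1(r1: np.ndarray, r2: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA decomposition of the n x 2 table of
    measurements (subjects x raters).  Undefined (NaN) when both raters are
    constant across subjects.
    """
    x = np.column_stack([np.asarray(r1, float), np.asarray(r2, float)])
    n, k = x.shape
    if n < 2:
        raise ValueError("ICC needs at least two subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.isclose(denom, 0.0):
        return float("nan")
    return float((msr - mse) / denom)


def icc_filter(
    table_rater1: pd.DataFrame,
    table_rater2: pd.DataFrame,
    threshold: float = 0.75,
) -> tuple[list[str], pd.Series]:
    """Retain features whose ICC(2,1) across the two raters is >= threshold.

    Zero-variance features (ICC undefined) are dropped with a warning.
    """
    if list(table_rater1.columns) != list(table_rater2.columns):
        raise ValueError("rater tables must share identical feature columns")
    if len(table_rater1) != len(table_rater2):
        raise ValueError("rater tables must cover the same samples")
    iccs = {}
    for col in table_rater1.columns:
        iccs[col] = icc_2_1(table_rater1[col].to_numpy(), table_rater2[col].to_numpy())
    icc_series = pd.Series(iccs, name="icc")
    undefined = icc_series[icc_series.isna()].index
    if len(undefined):
        logger.warning("%d features have undefined ICC (zero variance); dropped",
                       len(undefined))
    retained = [c for c in table_rater1.columns
                if np.isfinite(icc_series[c]) and icc_series[c] >= threshold]
    return retained, icc_series


# ------------------------------------------------------------- z-score


@dataclass
class ZScoreParams:
    columns: list[str]
    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)


def zscore_fit(train: pd.DataFrame) -> ZScoreParams:
    """Fit per-feature standardization on the training cohort.

    Zero-variance columns are dropped (logged); remaining columns transform
    to mean 0, SD 1 on the training data.
    """
    mean = train.mean()
    sd = train.std(ddof=0)
    dropped = sd[sd == 0].index.tolist()
    if dropped:
        logger.warning("dropping %d zero-variance features", len(dropped))
    cols = [c for c in train.columns if c not in set(dropped)]
    return ZScoreParams(columns=cols, mean=mean[cols], sd=sd[cols], dropped=dropped)


def zscore_apply(table: pd.DataFrame, params: ZScoreParams) -> pd.DataFrame:
    """Apply frozen standardization parameters (no refitting on new data)."""
    return (table[params.columns] - params.mean) / params.sd


# --------------------------------------------------------------- t-test


def ttest_filter(
    table: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Two-sided Welch t-test per feature; retain p < alpha."""
    y = np.asarray(labels).astype(int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each class needs at least two samples for the t-test")
    a = table[y == 1].to_numpy()
    b = table[y == 0].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    report = pd.DataFrame({"t": t, "p": p}, index=table.columns)
    retained = report.index[report["p"] < alpha].tolist()
    return retained, report


# ------------------------------------------------------ Pearson pruning


def pearson_prune(
    table: pd.DataFrame,
    threshold: float = 0.9,
    importance: pd.Series | None = None,
) -> list[str]:
    """Greedy redundancy pruning: no retained pair has |r| > threshold.

    Features are visited in order of decreasing importance (|t| statistic;
    ties broken lexicographically) and kept only if not too correlated with
    any already-kept feature, so the more informative member of each
    correlated pair survives.
    """
    cols = list(table.columns)
    if importance is None:
        importance = pd.Series(0.0, index=cols)
    order = sorted(cols, key=lambda c: (-abs(float(importance.get(c, 0.0))), c))
    corr = table[order].corr().abs().to_numpy()
    idx = {c: k for k, c in enumerate(order)}
    kept: list[str] = []
    for c in order:
        if all(corr[idx[c], idx[k]] <= threshold or np.isnan(corr[idx[c], idx[k]])
               for k in kept):
            kept.append(c)
    return [c for c in cols if c in set(kept)]


# ----------------------------------------------------------------- LASSO


@dataclass
class LassoResult:
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray  # mean held-out deviance per lambda
    lambda_star: float
    coefficients: pd.Series  # at lambda_star, fitted on the full training set
    intercept: float
    selected: list[str]


def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # sklearn minimizes ||w||_1 + C * sum(logloss); lam = 1 / (C * n)
    c = 1.0 / max(lam * len(y), 1e-12)
    # fixed random_state: liblinear's internal shuffling must not break
    # bit-reproducibility of the selection
    return LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                              max_iter=2000, random_state=0).fit(X, y)


def lasso_cv_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 40,
) -> LassoResult:
    """L1-penalized logistic regression over a log-spaced lambda grid.

    lambda* minimizes the mean cross-validated deviance; the model is then
    refitted on the full training table at lambda* and features with
    nonzero coefficients are selected.  An empty selection is reported with
    a warning (callers fall back to the top-|t| feature).
    """
    y = np.asarray(labels).astype(int)
    X = table.to_numpy(dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError(f"need n >= folds, got n={n}, folds={folds}")
    # largest lambda that zeroes all coefficients (gradient bound at w=0)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-6)
    grid = np.geomspace(lam_max * 1.1, lam_max * 1e-3, n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, n_lambdas))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        for j, lam in enumerate(grid):
            model = _l1_logistic(X[tr], y[tr], lam)
            prob = model.predict_proba(X[te])[:, 1]
            dev[f, j] = 2.0 * log_loss(y[te], prob, labels=[0, 1], normalize=False)
    mean_dev = dev.mean(axis=0)
    j_star = int(np.argmin(mean_dev))
    lam_star = float(grid[j_star])

    final = _l1_logistic(X, y, lam_star)
    coefs = pd.Series(final.coef_[0], index=table.columns)
    selected = coefs.index[coefs != 0].tolist()
    if not selected:
        warnings.warn("LASSO selected no features at lambda*", stacklevel=2)
    return LassoResult(
        lambda_grid=grid,
        cv_deviance=mean_dev,
        lambda_star=lam_star,
        coefficients=coefs,
        intercept=float(final.intercept_[0]),
        selected=selected,
    )


# ------------------------------------------------------- composite score


def composite_score(
    record: dict[str, float] | pd.Series,
    coefficients: pd.Series,
    intercept: float = 0.0,
) -> float:
    """Rad/habitat score: intercept + sum(coefficient * standardized value)."""
    total = float(intercept)
    for name, coef in coefficients.items():
        if coef == 0:
            continue
        if name not in record:
            raise KeyError(f"record is missing selected feature {name!r}")
        total += float(coef) * float(record[name])
    return total


# ------------------------------------------------------------- cascade


def impute_missing(table: pd.DataFrame, medians: pd.Series | None = None
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Median-impute missing values (e.g. empty-habitat features).

    Medians come from the training cohort; columns that are entirely
    missing in training impute to 0.
    """
    if medians is None:
        medians = table.median()
    filled = table.fillna(medians.fillna(0.0))
    return filled.fillna(0.0), medians


@dataclass
class SelectionReport:
    """Per-stage record of the cascade, with strictly nested retained sets."""

    initial: list[str]
    after_ttest: list[str]
    after_pearson: list[str]
    after_lasso: list[str]
    ttest_stats: pd.DataFrame
    lasso: LassoResult
    zscore: ZScoreParams
    medians: pd.Series
    fallback_used: bool = False

    def stage_counts(self) -> dict[str, int]:
        return {
            "initial": len(self.initial),
            "ttest": len(self.after_ttest),
            "pearson": len(self.after_pearson),
            "lasso": len(self.after_lasso),
        }

    def to_json(self, path) -> None:
        payload = {
            "stage_counts": self.stage_counts(),
            "after_ttest": self.after_ttest,
            "after_pearson": self.after_pearson,
            "after_lasso": self.after_lasso,
            "lambda_star": self.lasso.lambda_star,
            "coefficients": {
                k: v for k, v in self.lasso.coefficients.items() if v != 0
            },
            "fallback_used": self.fallback_used,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def run_selection_cascade(
    train: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
    r_threshold: float = 0.9,
    folds: int = 10,
    seed: int = 0,
) -> SelectionReport:
    """Impute -> z-score -> t-test -> Pearson prune -> LASSO-CV.

    Returns the fitted transformation parameters alongside the per-stage
    retained feature lists so the identical transform can be applied to a
    validation cohort.
    """
    filled, medians = impute_missing(train)
    zs = zscore_fit(filled)
    z = zscore_apply(filled, zs)

    t_kept, t_stats = ttest_filter(z, labels, alpha=alpha)
    if not t_kept:
        # degenerate screen: keep the single most discriminative feature
        t_kept = [t_stats["t"].abs().idxmax()]
        logger.warning("t-test retained nothing at alpha=%.3g; keeping top-|t|", alpha)

    p_kept = pearson_prune(z[t_kept], threshold=r_threshold,
                           importance=t_stats["t"].abs())

    folds_eff = min(folds, len(labels))
    lasso = lasso_cv_select(z[p_kept], labels, folds=folds_eff, seed=seed)
    fallback = False
    selected = lasso.selected
    if not selected:
        selected = [t_stats.loc[p_kept, "t"].abs().idxmax()]
        fallback = True

    return SelectionReport(
        initial=list(train.columns),
        after_ttest=t_kept,
        after_pearson=p_kept,
        after_lasso=selected,
        ttest_stats=t_stats,
        lasso=lasso,
        zscore=zs,
        medians=medians,
        fallback_used=fallback,
    )
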