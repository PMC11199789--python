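"""Logistic model fitting and discrimination / calibration / utility metrics.

AUC uses the Mann-Whitney construction with half credit for ties and a
DeLong 95% CI.  The operating point is Youden's J on the training ROC,
frozen before any validation data are seen.  Decision-curve analysis and
the Hosmer-Lemeshow decile test complete the evaluation report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "FittedModel",
    "EvalReport",
    "fit_lr",
    "predict_proba",
    "roc_auc_ci",
    "auc_mann_whitney",
    "choose_threshold",
    "confusion_metrics",
    "decision_curve",
    "calibration_and_hl",
    "evaluate",
]


@dataclass
class FittedModel:
    """A logistic-regression classifier over selected, standardized features."""

    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    threshold: float = 0.5
    ridge_fallback: bool = False
    provenance: dict = field(default_factory=dict)

    def linear_score(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.weights


def fit_lr(X: np.ndarray, y: np.ndarray, provenance: dict | None = None) -> FittedModel:
    """Maximum-likelihood logistic regression (unpenalized).

    Quasi-separated problems (diverging weights) fall back to a small ridge
    stabilizer, which is logged and flagged on the model.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the model")
    model = LogisticRegression(C=np.inf, max_iter=5000).fit(X, y)
    weights = model.coef_[0]
    intercept = float(model.intercept_[0])
    ridge = False
    if not np.all(np.isfinite(weights)) or np.abs(weights).max() > 1e3:
        logger.warning("possible separation; refitting with ridge stabilizer")
        model = LogisticRegression(C=1e2, max_iter=5000).fit(X, y)
        weights = model.coef_[0]
        intercept = float(model.intercept_[0])
        ridge = True
    return FittedModel(
        feature_names=[f"x{i}" for i in range(X.shape[1])],
        weights=weights,
        intercept=intercept,
        ridge_fallback=ridge,
        provenance=provenance or {},
    )


def predict_proba(model: FittedModel, X: np.ndarray) -> np.ndarray:
    z = model.linear_score(X)
    return 1.0 / (1.0 + np.exp(-z))


# ----------------------------------------------------------------- AUC


def auc_mann_whitney(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability, ties receiving half credit."""
    scores = np.asarray(scores, float)
    y = np.asarray(y).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc_ci(scores: np.ndarray, y: np.ndarray, level: float = 0.95
               ) -> tuple[float, float, float]:
    """AUC with a DeLong variance-based confidence interval, clipped to [0,1]."""
    scores = np.asarray(scores, float)
    y = np.asarray(y).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC needs both classes present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    zq = stats.norm.ppf(0.5 + level / 2.0)
    half = zq * np.sqrt(max(var, 0.0))
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


# ----------------------------------------------- threshold & confusion


def choose_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Operating point maximizing Youden's J = sens + spec - 1 on training data.

    The threshold is placed midway between adjacent unique scores; ties in J
    break toward the lower threshold (higher sensitivity).
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y).astype(int)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0])
    cuts = (uniq[1:] + uniq[:-1]) / 2.0
    best_cut, best_j = cuts[0], -np.inf
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    for c in cuts:
        pred = scores >= c
        tp = int(np.sum(pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j:
            best_j, best_cut = j, c
    return float(best_cut)


def confusion_metrics(scores: np.ndarray, y: np.ndarray, threshold: float
                      ) -> dict[str, float]:
    """Accuracy / sensitivity / specificity / PPV / NPV at a fixed threshold.

    Ratios with zero denominators are reported as NaN (missing).
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = tp + tn + fp + fn

    def _ratio(a: int, b: int) -> float:
        return a / b if b > 0 else float("nan")

    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn, "n": n,
        "accuracy": _ratio(tp + tn, n),
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


# ----------------------------------------------------------------- DCA


def decision_curve(probabilities: np.ndarray, y: np.ndarray,
                   pt_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Net benefit NB(pt) = TP/n - FP/n * pt/(1-pt) with reference curves.

    ``treat_all`` classifies everyone positive; ``treat_none`` is
    identically zero.
    """
    if pt_grid is None:
        pt_grid = np.linspace(0.01, 0.99, 99)
    pt_grid = np.asarray(pt_grid, float)
    if np.any((pt_grid <= 0) | (pt_grid >= 1)):
        raise ValueError("threshold probabilities must lie in (0, 1)")
    p = np.asarray(probabilities, float)
    y = np.asarray(y).astype(int)
    n = len(y)
    prevalence = y.mean()
    rows = []
    for pt in pt_grid:
        pred = p >= pt
        tp = np.sum(pred & (y == 1))
        fp = np.sum(pred & (y == 0))
        odds = pt / (1.0 - pt)
        rows.append({
            "pt": pt,
            "net_benefit": tp / n - fp / n * odds,
            "treat_all": prevalence - (1.0 - prevalence) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


# -------------------------------------------- calibration & HL test


def calibration_and_hl(probabilities: np.ndarray, y: np.ndarray,
                       groups: int = 10) -> tuple[pd.DataFrame, float, int, float]:
    """Decile calibration bins and the Hosmer-Lemeshow chi-square test.

    Bins are deciles of predicted risk; empty/degenerate bins are merged
    with their neighbour (df adjusted, logged).  Returns
    (bins, chi2, df, p) where bins holds mean predicted vs observed rates.
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < groups:
        raise ValueError(f"need n >= groups, got n={n}, groups={groups}")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, groups + 1)))
    if len(edges) - 1 < groups:
        logger.warning("tied predicted risks: %d bins merged to %d",
                       groups, len(edges) - 1)
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)

    rows = []
    chi2 = 0.0
    for b in range(len(edges) - 1):
        sel = idx == b
        nb = int(sel.sum())
        if nb == 0:
            continue
        obs = int(y[sel].sum())
        exp = float(p[sel].sum())
        mean_pred = float(p[sel].mean())
        rows.append({
            "bin": b, "n": nb, "mean_predicted": mean_pred,
            "observed_rate": obs / nb, "observed": obs, "expected": exp,
        })
        denom = exp * (1.0 - exp / nb)
        if denom > 1e-12:
            chi2 += (obs - exp) ** 2 / denom
    bins = pd.DataFrame(rows)
    df = max(len(bins) - 2, 1)
    pval = float(stats.chi2.sf(chi2, df))
    return bins, float(chi2), df, pval


# ------------------------------------------------------------- report


@dataclass
class EvalReport:
    """Full discrimination/calibration/utility summary for one cohort."""

    auc: float
    auc_ci: tuple[float, float]
    metrics: dict[str, float]
    hl_chi2: float
    hl_df: int
    hl_p: float
    calibration_bins: pd.DataFrame
    dca: pd.DataFrame
    threshold: float

    def summary(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "accuracy": self.metrics["accuracy"],
            "sensitivity": self.metrics["sensitivity"],
            "specificity": self.metrics["specificity"],
            "ppv": self.metrics["ppv"],
            "npv": self.metrics["npv"],
            "hl_chi2": self.hl_chi2,
            "hl_p": self.hl_p,
            "threshold": self.threshold,
        }

    def to_json(self, path) -> None:
        payload = {
            "summary": self.summary(),
            "confusion": {k: self.metrics[k] for k in ("tp", "tn", "fp", "fn", "n")},
            "calibration_bins": self.calibration_bins.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def write_curves(self, directory, prefix: str) -> list:
        """Write the decision and calibration curves as CSV; returns paths."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        dca_path = directory / f"{prefix}_dca.csv"
        cal_path = directory / f"{prefix}_calibration.csv"
        self.dca.to_csv(dca_path, index=False)
        self.calibration_bins.to_csv(cal_path, index=False)
        return [dca_path, cal_path]


def evaluate(probabilities: np.ndarray, y: np.ndarray, threshold: float,
             hl_groups: int = 10) -> EvalReport:
    """Assemble the evaluation report at a frozen decision threshold."""
    auc, lo, hi = roc_auc_ci(probabilities, y)
    metrics = confusion_metrics(probabilities, y, threshold)
    groups = min(hl_groups, len(y))
    bins, chi2, df, pval = calibration_and_hl(probabilities, y, groups=groups)
    dca = decision_curve(probabilities, y)
    return EvalReport(
        auc=auc,
        auc_ci=(lo, hi),
        metrics=metrics,
        hl_chi2=chi2,
        hl_df=df,
        hl_p=pval,
        calibration_bins=bins,
        dca=dca,
        threshold=threshold,
    )
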