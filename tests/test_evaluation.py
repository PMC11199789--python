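"""Discrimination, calibration and decision-curve metrics."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from habitatrad.evaluation import (
    auc_mann_whitney,
    calibration_and_hl,
    choose_threshold,
    confusion_metrics,
    decision_curve,
    evaluate,
    fit_lr,
    predict_proba,
    roc_auc_ci,
)

from . import oracles


# ------------------------------------------------------------------ LR


def test_lr_separable_feature_gives_training_auc_one():
    y = np.array([0] * 20 + [1] * 20)
    X = y.reshape(-1, 1) * 2.0 - 1.0
    model = fit_lr(X, y)
    p = predict_proba(model, X)
    assert auc_mann_whitney(p, y) == 1.0


def test_lr_antisymmetric_data_has_near_zero_intercept():
    rng = np.random.default_rng(0)
    x = rng.normal(size=100)
    X = np.concatenate([x, -x]).reshape(-1, 1)
    y = np.array([1] * 100 + [0] * 100)
    model = fit_lr(X, y)
    assert abs(model.intercept) < 0.2


def test_lr_mean_probability_matches_prevalence():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(120, 3))
    y = (rng.random(120) < 0.3).astype(int)
    if y.sum() in (0, 120):
        pytest.skip("degenerate draw")
    model = fit_lr(X, y)
    p = predict_proba(model, X)
    assert p.mean() == pytest.approx(y.mean(), abs=1e-4)


def test_lr_one_class_errors():
    with pytest.raises(ValueError):
        fit_lr(np.zeros((10, 1)), np.zeros(10))


# ----------------------------------------------------------------- AUC


def test_auc_examples_and_bruteforce_equivalence():
    assert auc_mann_whitney(np.array([0, 0, 1, 1]), np.array([0, 0, 1, 1])) == 1.0
    assert auc_mann_whitney(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0
    scores = np.array([0.1, 0.4, 0.35, 0.8])
    y = np.array([0, 0, 1, 1])
    assert auc_mann_whitney(scores, y) == pytest.approx(0.75)
    assert oracles.brute_auc(scores, y) == pytest.approx(0.75)

    rng = np.random.default_rng(2)
    s = np.round(rng.random(60), 2)  # rounding forces ties
    t = (rng.random(60) < 0.4).astype(int)
    if 0 < t.sum() < 60:
        ours = auc_mann_whitney(s, t)
        assert ours == pytest.approx(oracles.brute_auc(s, t), abs=1e-12)
        # trapezoid-rule route (sklearn) agrees with the rank construction
        assert ours == pytest.approx(roc_auc_score(t, s), abs=1e-12)


def test_delong_ci_contains_auc_and_orders():
    rng = np.random.default_rng(3)
    s = np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 50)])
    y = np.array([1] * 50 + [0] * 50)
    auc, lo, hi = roc_auc_ci(s, y)
    assert 0.0 <= lo <= auc <= hi <= 1.0
    assert auc == pytest.approx(auc_mann_whitney(s, y), abs=1e-12)
    with pytest.raises(ValueError):
        roc_auc_ci(s, np.ones_like(y))


def test_delong_ci_coverage_on_binormal_scores():
    """~95% coverage of the true AUC (binormal model, reduced replicates)."""
    rng = np.random.default_rng(4)
    mu = 1.0
    true_auc = 0.7602  # Phi(mu / sqrt(2))
    cover = 0
    reps = 120
    for _ in range(reps):
        s = np.concatenate([rng.normal(mu, 1, 100), rng.normal(0, 1, 100)])
        y = np.array([1] * 100 + [0] * 100)
        _, lo, hi = roc_auc_ci(s, y)
        cover += lo <= true_auc <= hi
    assert 0.88 <= cover / reps <= 0.995


# ------------------------------------------------- threshold & metrics


def test_confusion_metrics_examples():
    y = np.array([0, 0, 1, 1])
    perfect = np.array([0.1, 0.2, 0.8, 0.9])
    m = confusion_metrics(perfect, y, 0.5)
    assert all(m[k] == 1.0 for k in ("accuracy", "sensitivity", "specificity",
                                     "ppv", "npv"))

    allpos = confusion_metrics(np.ones(4), y, 0.5)
    assert allpos["sensitivity"] == 1.0 and allpos["specificity"] == 0.0
    assert allpos["ppv"] == 0.5  # prevalence
    assert np.isnan(allpos["npv"])  # zero denominator reported missing

    # TP=3 FP=1 TN=4 FN=2 arithmetic
    y2 = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
    s2 = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0], dtype=float)
    m2 = confusion_metrics(s2, y2, 0.5)
    assert (m2["tp"], m2["fp"], m2["tn"], m2["fn"]) == (3, 1, 4, 2)
    assert m2["accuracy"] == pytest.approx(0.7)
    assert m2["sensitivity"] == pytest.approx(0.6)
    assert m2["specificity"] == pytest.approx(0.8)
    assert m2["ppv"] == pytest.approx(0.75)
    assert m2["npv"] == pytest.approx(2 / 3)


def test_choose_threshold_maximizes_youden():
    y = np.array([0, 0, 0, 1, 1, 1])
    s = np.array([0.1, 0.2, 0.6, 0.5, 0.8, 0.9])
    thr = choose_threshold(s, y)
    pred = s >= thr
    j = (pred[y == 1].mean()) + ((~pred)[y == 0].mean()) - 1
    # no other cut does better
    for c in np.linspace(0, 1, 101):
        pj = (s >= c)
        jj = pj[y == 1].mean() + (~pj)[y == 0].mean() - 1
        assert jj <= j + 1e-12


# ----------------------------------------------------------------- DCA


def test_decision_curve_reference_identities():
    rng = np.random.default_rng(5)
    p = rng.random(40)
    y = (rng.random(40) < 0.4).astype(int)
    grid = np.array([0.1, 0.25, 0.5, 0.75])
    dca = decision_curve(p, y, grid)
    assert np.all(dca["treat_none"] == 0.0)
    prev = y.mean()
    for _, row in dca.iterrows():
        pt = row["pt"]
        assert row["treat_all"] == pytest.approx(prev - (1 - prev) * pt / (1 - pt))

    # 4-sample toy at pt = 0.5: TP and FP counted by hand
    p4 = np.array([0.9, 0.6, 0.4, 0.2])
    y4 = np.array([1, 0, 1, 0])
    nb = decision_curve(p4, y4, np.array([0.5]))["net_benefit"].iloc[0]
    assert nb == pytest.approx(1 / 4 - 1 / 4 * 1.0)  # TP=1, FP=1, odds=1

    with pytest.raises(ValueError):
        decision_curve(p4, y4, np.array([0.0]))


def test_useless_model_never_beats_references_materially():
    rng = np.random.default_rng(6)
    y = (rng.random(400) < 0.36).astype(int)
    p = np.full(400, y.mean())
    dca = decision_curve(p, y)
    excess = dca["net_benefit"] - np.maximum(dca["treat_all"], dca["treat_none"])
    assert excess.max() <= 1e-9


# --------------------------------------------------- calibration & HL


def test_hl_chi2_zero_for_perfectly_calibrated_bins():
    # predicted probability exactly equals observed rate in each bin
    p = np.concatenate([np.full(20, 0.2), np.full(20, 0.8)])
    y = np.concatenate([np.zeros(16), np.ones(4), np.zeros(4), np.ones(16)])
    bins, chi2, df, pval = calibration_and_hl(p, y, groups=2)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert pval == pytest.approx(1.0)


def test_hl_two_bin_hand_computation():
    p = np.concatenate([np.full(10, 0.3), np.full(10, 0.7)])
    y = np.concatenate([np.ones(5), np.zeros(5), np.ones(6), np.zeros(4)])
    bins, chi2, df, pval = calibration_and_hl(p, y, groups=2)
    # bin 1: O=5, E=3, n=10; bin 2: O=6, E=7, n=10
    hand = (5 - 3) ** 2 / (3 * (1 - 0.3)) + (6 - 7) ** 2 / (7 * (1 - 0.7))
    assert chi2 == pytest.approx(hand)


def test_hl_type_one_error_on_well_specified_model():
    """p > 0.05 in most replicates when the LR model is correctly specified."""
    rng = np.random.default_rng(7)
    ok = 0
    reps = 25
    for _ in range(reps):
        x = rng.normal(size=300)
        prob = 1 / (1 + np.exp(-(x - 0.5)))
        y = (rng.random(300) < prob).astype(int)
        _, _, _, pval = calibration_and_hl(prob, y, groups=10)
        ok += pval > 0.05
    assert ok >= 0.75 * reps


def test_evaluate_report_confusion_sums_to_n():
    rng = np.random.default_rng(8)
    p = rng.random(60)
    y = (rng.random(60) < 0.4).astype(int)
    rep = evaluate(p, y, threshold=0.5)
    m = rep.metrics
    assert m["tp"] + m["tn"] + m["fp"] + m["fn"] == 60
    s = rep.summary()
    assert 0 <= s["auc"] <= 1
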