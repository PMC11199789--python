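"""Selection cascade: ICC, standardization, t-screen, pruning, LASSO, score."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from habitatrad.selection import (
    composite_score,
    icc_2_1,
    icc_filter,
    lasso_cv_select,
    pearson_prune,
    run_selection_cascade,
    ttest_filter,
    zscore_apply,
    zscore_fit,
)


# ------------------------------------------------------------------ ICC


def test_icc_identical_measurements_is_one():
    x = np.array([1.0, 5.0, 3.0, 8.0, 2.0, 9.0])
    assert icc_2_1(x, x) == pytest.approx(1.0)


def test_icc_matches_pingouin_on_toy_table():
    """Two-way random-effects absolute-agreement ICC vs an independent
    implementation on a 6-subject, 2-rater table."""
    pingouin = pytest.importorskip("pingouin")
    r1 = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
    r2 = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
    ours = icc_2_1(r1, r2)
    df = pd.DataFrame({
        "subject": list(range(6)) * 2,
        "rater": ["a"] * 6 + ["b"] * 6,
        "score": np.concatenate([r1, r2]),
    })
    ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                   ratings="score")
    # absolute agreement, single rater: pingouin's ICC(A,1)
    ref_icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    assert ours == pytest.approx(ref_icc2, abs=1e-10)


def test_icc_filter_drops_noise_keeps_reproducible():
    rng = np.random.default_rng(8)
    n = 50
    signal = rng.normal(0, 10, n)
    t1 = pd.DataFrame({
        "stable": signal + rng.normal(0, 0.5, n),
        "noise": rng.normal(0, 1, n),
        "flat": np.ones(n),
    })
    t2 = pd.DataFrame({
        "stable": signal + rng.normal(0, 0.5, n),
        "noise": rng.normal(0, 1, n),
        "flat": np.ones(n),
    })
    retained, iccs = icc_filter(t1, t2, threshold=0.75)
    assert "stable" in retained
    assert "noise" not in retained and abs(iccs["noise"]) < 0.3
    assert "flat" not in retained and np.isnan(iccs["flat"])


# -------------------------------------------------------------- z-score


def test_zscore_train_transform_and_frozen_apply():
    rng = np.random.default_rng(1)
    train = pd.DataFrame({"a": rng.normal(5, 2, 100), "b": rng.normal(-3, 7, 100),
                          "const": np.full(100, 2.0)})
    params = zscore_fit(train)
    assert params.dropped == ["const"]
    z = zscore_apply(train, params)
    assert np.allclose(z.mean(), 0.0, atol=1e-12)
    assert np.allclose(z.std(ddof=0), 1.0, atol=1e-12)

    # a shifted validation column keeps its shift (no leakage/refit)
    val = train[["a", "b"]] + 10.0
    zv = zscore_apply(val, params)
    assert zv["a"].mean() == pytest.approx(10.0 / train["a"].std(ddof=0), rel=1e-6)


# --------------------------------------------------------------- t-test


def test_ttest_hand_computed_welch_example():
    """4+4 toy sample checked against the textbook Welch formulas."""
    a = np.array([5.0, 6.0, 7.0, 8.0])
    b = np.array([1.0, 2.0, 3.0, 4.0])
    table = pd.DataFrame({"f": np.concatenate([a, b])})
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    retained, rep = ttest_filter(table, y)
    va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
    t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
    assert rep.loc["f", "t"] == pytest.approx(t_hand)
    assert retained == ["f"]


def test_ttest_identical_distributions_dropped():
    vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    table = pd.DataFrame({"f": vals})
    y = np.array([1, 1, 1, 0, 0, 0])
    retained, rep = ttest_filter(table, y)
    assert rep.loc["f", "t"] == 0.0 and rep.loc["f", "p"] == pytest.approx(1.0)
    assert retained == []


def test_ttest_large_effect_retained_and_degenerate_class_errors():
    rng = np.random.default_rng(4)
    table = pd.DataFrame({"f": np.concatenate([rng.normal(3, 1, 30),
                                               rng.normal(0, 1, 30)])})
    y = np.array([1] * 30 + [0] * 30)
    retained, _ = ttest_filter(table, y)
    assert retained == ["f"]
    with pytest.raises(ValueError):
        ttest_filter(table, np.array([1] + [0] * 59))


# ------------------------------------------------------------- pruning


def test_pearson_prune_rules():
    rng = np.random.default_rng(6)
    base = rng.normal(size=200)
    table = pd.DataFrame({
        "a": base,
        "dup": base.copy(),
        "ortho": rng.normal(size=200),
    })
    imp = pd.Series({"a": 5.0, "dup": 1.0, "ortho": 2.0})
    kept = pearson_prune(table, threshold=0.9, importance=imp)
    assert "a" in kept and "dup" not in kept and "ortho" in kept

    # three mutually correlated columns, |t| = 3 > 2 > 1: only the first stays
    x = rng.normal(size=300)
    tri = pd.DataFrame({
        "f1": x + rng.normal(0, 0.2, 300),
        "f2": x + rng.normal(0, 0.2, 300),
        "f3": x + rng.normal(0, 0.2, 300),
    })
    imp = pd.Series({"f1": 3.0, "f2": 2.0, "f3": 1.0})
    assert pearson_prune(tri, 0.9, imp) == ["f1"]

    # no remaining pair above threshold
    kept = pearson_prune(table, 0.9, None)
    corr = table[kept].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    assert corr.max() <= 0.9


# ----------------------------------------------------------------- LASSO


def test_lasso_full_shrinkage_at_large_lambda():
    from habitatrad.selection import _l1_logistic

    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 5))
    y = (rng.random(60) < 0.5).astype(int)
    model = _l1_logistic(X, y, lam=10.0)
    assert np.all(model.coef_ == 0.0)


def test_lasso_recovers_single_planted_predictor():
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n, p = 200, 20
        X = rng.normal(size=(n, p))
        logit = 2.0 * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        table = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
        res = lasso_cv_select(table, y, folds=5, seed=seed)
        if "f0" in res.selected and res.coefficients["f0"] > 0:
            hits += 1
    assert hits >= 4


def test_duplicated_predictors_handled_by_prune_then_lasso():
    """Twin columns: the L1 optimum only pins down their combined weight
    (any same-sign split has identical loss and identical penalty), so the
    cascade's guarantee is structural — Pearson pruning removes one twin
    before LASSO ever sees the pair."""
    from habitatrad.selection import _l1_logistic

    rng = np.random.default_rng(9)
    n = 150
    x = rng.normal(size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
    table = pd.DataFrame({"a": x, "b": x.copy(), "noise": rng.normal(size=n)})
    rep = run_selection_cascade(table, y, folds=5, seed=0)
    assert not {"a", "b"} <= set(rep.after_pearson)

    # the combined twin weight approximates the single-column solution
    X = np.column_stack([x, x.copy()])
    lam = np.abs(X.T @ (y - y.mean())).max() / n / 5
    both = _l1_logistic(X, y, lam).coef_[0]
    single = _l1_logistic(x.reshape(-1, 1), y, lam).coef_[0]
    assert both.sum() == pytest.approx(single[0], rel=0.05)


def test_lasso_cv_is_deterministic_under_seed():
    rng = np.random.default_rng(9)
    n = 150
    x = rng.normal(size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
    table = pd.DataFrame({"a": x, "b": x.copy(), "noise": rng.normal(size=n)})
    r1 = lasso_cv_select(table, y, folds=5, seed=0)
    r2 = lasso_cv_select(table, y, folds=5, seed=0)
    assert r1.lambda_star == r2.lambda_star
    pd.testing.assert_series_equal(r1.coefficients, r2.coefficients)


# --------------------------------------------------------------- score


def test_composite_score_contracts():
    coefs = pd.Series({"a": 0.0, "b": 0.0})
    assert composite_score({"a": 5, "b": 7}, coefs, intercept=1.5) == 1.5

    coefs = pd.Series({"a": 1.0})
    assert composite_score({"a": 2.0}, coefs, intercept=0.0) == 2.0

    with pytest.raises(KeyError, match="missing"):
        composite_score({"b": 1.0}, pd.Series({"a": 1.0}))

    # linearity: score(u+v) = score(u) + score(v) - intercept
    coefs = pd.Series({"a": 2.0, "b": -1.0})
    u, v = {"a": 1.0, "b": 2.0}, {"a": 3.0, "b": -1.0}
    uv = {k: u[k] + v[k] for k in u}
    s = lambda r: composite_score(r, coefs, intercept=0.7)
    assert s(uv) == pytest.approx(s(u) + s(v) - 0.7)


# -------------------------------------------------------------- cascade


def test_cascade_stages_strictly_nested():
    rng = np.random.default_rng(12)
    n, p = 80, 60
    X = rng.normal(size=(n, p))
    y = np.array([0, 1] * (n // 2))
    X[:, 0] += 1.5 * y
    X[:, 1] += 1.2 * y
    table = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    rep = run_selection_cascade(table, y, folds=5, seed=0)
    assert set(rep.after_lasso) <= set(rep.after_pearson)
    assert set(rep.after_pearson) <= set(rep.after_ttest)
    assert set(rep.after_ttest) <= set(rep.initial)
    assert "f0" in rep.after_ttest


def test_cascade_handles_missing_values_by_train_median():
    rng = np.random.default_rng(13)
    n = 60
    X = pd.DataFrame({"good": rng.normal(size=n), "holey": rng.normal(size=n)})
    y = np.array([0, 1] * (n // 2))
    X.loc[:4, "holey"] = np.nan
    X["good"] += 2.0 * y
    rep = run_selection_cascade(X, y, folds=5, seed=1)
    assert "good" in rep.after_lasso
    assert np.isfinite(rep.medians["holey"])
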