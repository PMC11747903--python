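"""Welch tests, single-feature AUROC, correlation pruning, selection rule."""

import numpy as np
import pandas as pd
import pytest

from octava import feateng
from octava.feateng import (FeatureStats, correlation_matrix, feature_auroc,
                            rf_importance, select_features, welch_test)

# --------------------------------------------------------------------------
# Welch


def test_welch_identical_groups():
    t, df, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_welch_clear_separation():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    t, df, p = welch_test(a, a + 10.0)
    assert p < 0.001


def test_welch_matches_textbook_formula():
    a = np.array([2.1, 2.5, 2.3])
    b = np.array([3.0, 3.4, 3.1])
    t, df, p = welch_test(a, b)
    # independent direct evaluation of Welch's statistic and Satterthwaite df
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se = np.sqrt(va / 3 + vb / 3)
    t_ref = (a.mean() - b.mean()) / se
    df_ref = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
    from scipy.stats import t as t_dist
    p_ref = 2 * t_dist.sf(abs(t_ref), df_ref)
    assert t == pytest.approx(t_ref, abs=1e-8)
    assert df == pytest.approx(df_ref, abs=1e-8)
    assert p == pytest.approx(p_ref, abs=1e-8)


def test_welch_degenerate_zero_variance():
    t, df, p = welch_test([5.0, 5.0], [5.0, 5.0])
    assert (t, p) == (0.0, 1.0)


def test_welch_requires_two_values_per_group():
    with pytest.raises(ValueError):
        welch_test([1.0], [1.0, 2.0])


# --------------------------------------------------------------------------
# AUROC


def test_auroc_perfect_and_pairwise():
    vals = np.array([1.0, 2.0, 3.0, 4.0])
    assert feature_auroc(vals, np.array([0, 0, 1, 1])) == pytest.approx(1.0)
    # swap one pair: 3 of 4 PV/LA pairs still ordered correctly
    assert feature_auroc(vals, np.array([0, 1, 0, 1])) == pytest.approx(0.75)


def test_auroc_random_labels_near_half(rng):
    vals = rng.random(10_000)
    labels = rng.integers(0, 2, 10_000)
    assert feature_auroc(vals, labels) == pytest.approx(0.5, abs=0.02)


def test_auroc_single_class_rejected():
    with pytest.raises(ValueError):
        feature_auroc(np.array([1.0, 2.0]), np.array([1, 1]))


# --------------------------------------------------------------------------
# Pearson


def test_correlation_matrix_basics():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
    df["b"] = 2 * df["a"] + 1
    df["c"] = [2.0, 1.0, 4.0, 3.0, 5.0]
    rho, p = correlation_matrix(df, features=["a", "b", "c"])
    assert rho.loc["a", "a"] == pytest.approx(1.0)
    assert rho.loc["a", "b"] == pytest.approx(1.0)
    assert np.allclose(rho.values, rho.values.T)


def test_correlation_matches_hand_computation():
    x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
    rho, _ = correlation_matrix(pd.DataFrame({"x": x, "y": y}), features=["x", "y"])
    xc, yc = x - x.mean(), y - y.mean()
    ref = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    assert rho.loc["x", "y"] == pytest.approx(ref, abs=1e-10)


def test_correlation_constant_column_flagged_nan():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [7.0, 7.0, 7.0]})
    rho, _ = correlation_matrix(df, features=["a", "b"])
    assert np.isnan(rho.loc["a", "b"])


# --------------------------------------------------------------------------
# RF importance


def test_rf_importance_finds_informative_feature(rng):
    from octava.classify import train_rf
    n = 400
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 10))
    X[:, 3] += 2.0 * y  # the only informative column
    names = [f"f{i}" for i in range(10)]
    folds = []
    for seed in range(3):
        tm = train_rf(X, y, names, seed=seed)
        imp = tm.training_log["importances"]
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        folds.append(imp)
    avg = rf_importance(folds, names)
    assert avg.idxmax() == "f3"
    assert avg.sum() == pytest.approx(1.0, abs=1e-9)


def test_rf_importance_split_sharing_on_duplicated_column(rng):
    from octava.classify import train_rf
    n = 600
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 5))
    X[:, 0] += 1.5 * y
    base = rf_importance([train_rf(X, y, [f"f{i}" for i in range(5)],
                                   seed=s).training_log["importances"]
                          for s in range(3)])
    X_dup = np.column_stack([X, X[:, 0]])
    dup = rf_importance([train_rf(X_dup, y, [f"f{i}" for i in range(6)],
                                  seed=s).training_log["importances"]
                         for s in range(3)])
    combined = dup["f0"] + dup["f5"]
    assert combined == pytest.approx(base["f0"], rel=0.2)
    assert dup["f0"] < base["f0"]  # each copy individually diluted


def test_rf_importance_rejects_unnormalized():
    with pytest.raises(ValueError):
        rf_importance([np.array([0.5, 0.2])])
    with pytest.raises(ValueError):
        rf_importance([])


# --------------------------------------------------------------------------
# selection rule


def _stats(auroc: dict, rho_pairs: dict, importance: dict) -> FeatureStats:
    names = list(auroc)
    auroc_s = pd.Series(auroc)
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for (a, b), v in rho_pairs.items():
        rho.loc[a, b] = rho.loc[b, a] = v
    return FeatureStats(
        welch=pd.DataFrame(index=names, columns=["t", "df", "p"]),
        auroc=auroc_s,
        auroc_oriented=np.maximum(auroc_s, 1 - auroc_s),
        pearson_rho=rho,
        pearson_p=rho * 0.0,
        rf_importance=pd.Series(importance),
    )


def test_selection_reconstructs_reference_behavior():
    """AUROC gate removes entropy/kurtosis/mean; of the correlated
    variance/attenuation-SD pair the less important member (variance) is
    pruned; the four survivors with highest importance are selected."""
    names = ["correlation", "attenuation_sd", "variance", "energy", "skewness",
             "contrast", "homogeneity", "attenuation", "entropy", "kurtosis", "mean"]
    auroc = dict(zip(names, [0.80, 0.78, 0.77, 0.74, 0.72, 0.68, 0.63, 0.62,
                             0.58, 0.55, 0.52]))
    imp = dict(zip(names, [0.20, 0.25, 0.10, 0.12, 0.13, 0.05, 0.01, 0.08,
                           0.02, 0.02, 0.02]))
    stats = _stats(auroc, {("variance", "attenuation_sd"): 0.85}, imp)
    sel = select_features(stats, k=4)
    assert sel.selected == ["attenuation_sd", "correlation", "skewness", "energy"]
    assert sel.rejection_reason["variance"] == "correlation_prune"
    for f in ("entropy", "kurtosis", "mean"):
        assert sel.rejection_reason[f] == "auroc_gate"
    assert sel.rejection_reason["contrast"] == "not_top_k"


def test_selection_all_chance_features_empty():
    names = ["a", "b", "c"]
    stats = _stats({n: 0.5 for n in names}, {}, {n: 1 / 3 for n in names})
    sel = select_features(stats, k=4)
    assert sel.selected == []
    assert all(r == "auroc_gate" for r in sel.rejection_reason.values())


def _selection_oracle(stats: FeatureStats, k: int):
    """Exhaustive restatement of the three-stage rule."""
    gated = [f for f in stats.auroc_oriented.index if stats.auroc_oriented[f] >= 0.6]
    order = sorted(gated, key=lambda f: -stats.rf_importance[f])
    kept = []
    for f in order:
        if all(not (np.isfinite(stats.pearson_rho.loc[f, g])
                    and abs(stats.pearson_rho.loc[f, g]) >= 0.7) for g in kept):
            kept.append(f)
    return kept[:k]


def test_selection_matches_rule_oracle_on_random_stats(rng):
    names = [f"f{i}" for i in range(8)]
    for _ in range(25):
        auroc = dict(zip(names, rng.uniform(0.3, 1.0, 8)))
        imp = rng.dirichlet(np.ones(8))
        pairs = {}
        for _ in range(rng.integers(0, 4)):
            i, j = rng.choice(8, 2, replace=False)
            pairs[(names[i], names[j])] = rng.uniform(-1, 1)
        stats = _stats(auroc, pairs, dict(zip(names, imp)))
        sel = select_features(stats, k=4)
        assert sel.selected == _selection_oracle(stats, 4)


def test_selection_is_deterministic(small_cohort):
    from octava import pipeline
    from octava.evaluate import make_cv_plan
    _, table, _ = small_cohort
    plan = make_cv_plan(sorted(table.junction_id.unique()), seed=9)
    s1, sel1 = pipeline.run_feature_engineering(table, plan, seed=9)
    s2, sel2 = pipeline.run_feature_engineering(table, plan, seed=9)
    assert sel1.selected == sel2.selected
    assert sel1.rejection_reason == sel2.rejection_reason


def test_attenuation_sd_selected_on_default_phantom(cohort_result):
    """Attenuation-map SD survives every gate on the default cohort."""
    assert "attenuation_sd" in cohort_result.selection.selected
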