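"""Feature engineering: Welch tests, AUROC, correlation pruning, selection.

The selection procedure mirrors how the discriminative feature set was
derived for the venoatrial classification task:

1. Welch-corrected unpaired t-tests on per-junction average feature values
   (one LA and one PV average per junction; at most 26 per group).
2. Single-feature ROC analysis on patch-level values (PV positive); features
   whose oriented AUROC is below 0.6 are gated out.
3. Pearson correlation over patches; of each pair with |rho| >= 0.7, the
   member with the lower random-forest importance is pruned (greedy, in
   descending importance order).
4. The top ``k`` survivors by mean-decrease-in-impurity importance, averaged
   across the CV folds, form the selected set (default k = 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .features import FEATURE_NAMES
from .volume_io import Label

AUROC_GATE = 0.6
RHO_PRUNE = 0.7
P_SIGNIFICANT = 0.05


@dataclass
class FeatureStats:
    """Per-feature statistics feeding the selection rule."""

    welch: pd.DataFrame  # index: feature; columns t, df, p
    auroc: pd.Series  # raw orientation, PV positive
    auroc_oriented: pd.Series  # max(a, 1-a), used for gating/ranking
    pearson_rho: pd.DataFrame  # symmetric, unit diagonal
    pearson_p: pd.DataFrame
    rf_importance: pd.Series  # mean decrease in impurity, averaged over folds


@dataclass
class SelectionResult:
    ranked: list[str]  # survivors, descending rf importance
    selected: list[str]
    rejection_reason: dict[str, str]  # feature -> {auroc_gate, correlation_prune, not_top_k}


def welch_test(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unpaired t-test: (t, Satterthwaite df, two-sided p).

    Degenerate case: both groups constant with equal means -> t=0, p=1
    (no evidence of a difference), df = n_a + n_b - 2.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    # Satterthwaite df
    na, nb = a.size, b.size
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def feature_auroc(values: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC with PV as the positive class (ties count 1/2).

    ``labels`` may be Label values or {0,1} with 1 = PV.
    """
    labels = np.asarray(labels)
    y = (labels == Label.PV).astype(int) if labels.max() > 1 else labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(values, dtype=np.float64)))


def correlation_matrix(feature_table: pd.DataFrame,
                       features: list[str] = FEATURE_NAMES,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson rho over patches, with two-sided p-values.

    Constant columns yield NaN rho (flagged by NaN) off-diagonal.
    """
    if len(feature_table) < 3:
        raise ValueError("need at least 3 rows")
    cols = [c for c in features if c in feature_table.columns]
    n = len(cols)
    rho = np.eye(n)
    pval = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi = feature_table[cols[i]].to_numpy(dtype=np.float64)
            xj = feature_table[cols[j]].to_numpy(dtype=np.float64)
            if xi.std() == 0 or xj.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(xi, xj)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pval, index=cols, columns=cols))


def per_junction_averages(feature_table: pd.DataFrame,
                          features: list[str] = FEATURE_NAMES) -> pd.DataFrame:
    """Average feature values per (junction, class) — the Welch-test units."""
    return (feature_table.groupby(["junction_id", "label"], as_index=False)[features]
            .mean())


def rf_importance(per_fold_importances: list[np.ndarray] | list[pd.Series],
                  features: list[str] | None = None) -> pd.Series:
    """Average mean-decrease-in-impurity importances across folds.

    Each fold's importances must sum to 1 (sklearn normalization); the
    average therefore also sums to 1.
    """
    if not per_fold_importances:
        raise ValueError("no trained folds supplied")
    arrs = []
    for imp in per_fold_importances:
        v = np.asarray(imp, dtype=np.float64)
        if not np.isclose(v.sum(), 1.0, atol=1e-6):
            raise ValueError("per-fold importances must sum to 1 (untrained fold?)")
        arrs.append(v)
    mean = np.mean(arrs, axis=0)
    if features is None and isinstance(per_fold_importances[0], pd.Series):
        features = list(per_fold_importances[0].index)
    return pd.Series(mean, index=features)


def compute_feature_stats(feature_table: pd.DataFrame,
                          per_fold_importances: list[pd.Series],
                          features: list[str] = FEATURE_NAMES) -> FeatureStats:
    """Assemble all selection inputs from a patch-level feature table."""
    avgs = per_junction_averages(feature_table, features)
    welch_rows = {}
    for f in features:
        a = avgs.loc[avgs.label == "LA", f].to_numpy()
        b = avgs.loc[avgs.label == "PV", f].to_numpy()
        t, df, p = welch_test(a, b)
        welch_rows[f] = {"t": t, "df": df, "p": p}
    welch = pd.DataFrame(welch_rows).T

    labels = feature_table["label"].map({"LA": 0, "PV": 1}).to_numpy()
    auroc = pd.Series({f: feature_auroc(feature_table[f].to_numpy(), labels)
                       for f in features})
    rho, pval = correlation_matrix(feature_table, features)
    imp = rf_importance(per_fold_importances, features)
    return FeatureStats(
        welch=welch,
        auroc=auroc,
        auroc_oriented=np.maximum(auroc, 1.0 - auroc),
        pearson_rho=rho,
        pearson_p=pval,
        rf_importance=imp,
    )


def select_features(stats_: FeatureStats, k: int = 4,
                    auroc_gate: float = AUROC_GATE,
                    rho_prune: float = RHO_PRUNE) -> SelectionResult:
    """Apply the three-stage selection rule; deterministic given the stats."""
    reasons: dict[str, str] = {}
    survivors = []
    for f in stats_.auroc_oriented.index:
        if stats_.auroc_oriented[f] < auroc_gate:
            reasons[f] = "auroc_gate"
        else:
            survivors.append(f)

    # greedy correlation pruning, descending importance: the more important
    # member of each |rho| >= threshold pair is kept
    order = sorted(survivors, key=lambda f: -stats_.rf_importance[f])
    kept: list[str] = []
    for f in order:
        clash = any(
            np.isfinite(stats_.pearson_rho.loc[f, g])
            and abs(stats_.pearson_rho.loc[f, g]) >= rho_prune
            for g in kept
        )
        if clash:
            reasons[f] = "correlation_prune"
        else:
            kept.append(f)

    selected = kept[:k]
    for f in kept[k:]:
        reasons[f] = "not_top_k"
    if len(selected) < k:
        import logging
        logging.getLogger(__name__).warning(
            "only %d features survived selection (k=%d)", len(selected), k)
    return SelectionResult(ranked=kept, selected=selected, rejection_reason=reasons)
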