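"""End-to-end synthetic study: phantom cohort -> classifiers -> metrics.

This module wires the stages together the way the real analysis runs:
generate (or load) a cohort of junction volumes, detect the surface and
flatten, tile and QC-filter patches, extract the 11 features, run the
feature-engineering selection, then evaluate the classifiers under
junction-grouped sevenfold cross-validation.

Default cohort: 26 junctions of 512 x 40 A-lines each, yielding roughly
3000 accepted 64 x 128 patches with an LA-majority class balance. The ML
models run all seven folds; the CNNs, whose CPU cost dominates, are
evaluated on a configurable subset of folds with a capped number of
training patches and epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import classify, feateng, features, patching, synthgen, volume_io
from .evaluate import CVPlan, confusion_and_metrics, make_cv_plan, metrics_summary
from .volume_io import Label

#: per-junction phantom geometry for the default cohort
COHORT_CONFIG = synthgen.PhantomConfig(grid_nx=512, grid_ny=40, transition_width=24)
N_JUNCTIONS_DEFAULT = 26


def volume_to_patches(
    display: volume_io.OCTVolume,
    linear: volume_io.OCTVolume,
    labels: volume_io.LabelMap,
    patch_shape: tuple[int, int] = patching.DEFAULT_PATCH_SHAPE,
) -> tuple[list[patching.Patch], dict[str, int]]:
    """Surface-detect, flatten (both domains, same shifts), tile and QC."""
    surface = volume_io.detect_surface(display)
    flat_display = volume_io.flatten(display, surface)
    flat_linear = volume_io.flatten(linear, surface)
    candidates = patching.tile(flat_display, labels, patch_shape, linear_volume=flat_linear)
    return patching.qc_filter(candidates)


def build_patch_dataset(
    n_junctions: int = N_JUNCTIONS_DEFAULT,
    base_config: synthgen.PhantomConfig = COHORT_CONFIG,
    seed: int = 0,
) -> tuple[list[patching.Patch], pd.DataFrame, dict[str, int]]:
    """Generate the phantom cohort and return (patches, feature table,
    QC rejection counts)."""
    cohort = synthgen.generate_junction_set(n_junctions, base_config, seed)
    patches: list[patching.Patch] = []
    rejects = {"nonzero_fraction": 0, "mixed_or_invalid_label": 0, "zero_aline": 0}
    for jid, phantom in cohort:
        accepted, rej = volume_to_patches(
            phantom.as_volume("log8bit", jid),
            phantom.as_volume("linear", jid),
            phantom.labels,
        )
        patches.extend(accepted)
        for k, v in rej.items():
            rejects[k] += v
    table = features.compute_feature_table(patches)
    return patches, table, rejects


def _rows_for(table: pd.DataFrame, junctions: tuple[str, ...]) -> pd.DataFrame:
    return table[table["junction_id"].isin(junctions)]


def run_feature_engineering(table: pd.DataFrame, plan: CVPlan,
                            seed: int = 0, k: int = 4
                            ) -> tuple[feateng.FeatureStats, feateng.SelectionResult]:
    """Per-fold RF importances (all 11 features, train+validation rows),
    then the full statistics and the selection rule."""
    per_fold_imp = []
    for fold in plan.folds:
        rows = _rows_for(table, fold.train + fold.validation)
        rf = classify.train_rf(rows, rows["label"], features.FEATURE_NAMES, seed=seed)
        per_fold_imp.append(rf.training_log["importances"])
    stats = feateng.compute_feature_stats(table, per_fold_imp)
    selection = feateng.select_features(stats, k=k)
    return stats, selection


def _patch_arrays(patches: list[patching.Patch], table: pd.DataFrame,
                  junctions: tuple[str, ...], selected: list[str]
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel stack, labels and selected-feature rows for a junction subset,
    aligned with the feature table (patches dropped there are dropped here)."""
    keyed = {(p.junction_id, p.grid_x, p.grid_y): p for p in patches}
    rows = _rows_for(table, junctions)
    pix = np.stack([keyed[(r.junction_id, r.grid_x, r.grid_y)].pixels
                    for r in rows.itertuples()])
    y = (rows["label"] == "PV").to_numpy().astype(int)
    feats = rows[selected].to_numpy(dtype=np.float64)
    return pix, y, feats


@dataclass
class PipelineResult:
    plan: CVPlan
    stats: feateng.FeatureStats
    selection: feateng.SelectionResult
    per_fold: dict[str, list[dict]]  # model kind -> metric rows
    n_patches: int
    qc_rejects: dict[str, int]
    label_counts: dict[str, int]
    predictions: pd.DataFrame | None = None  # per test patch, all models

    def summary(self) -> dict[str, pd.DataFrame]:
        return {kind: metrics_summary(rows) for kind, rows in self.per_fold.items() if rows}

    def to_json(self) -> str:
        payload = {
            "seed": self.plan.seed,
            "n_patches": self.n_patches,
            "label_counts": self.label_counts,
            "qc_rejects": self.qc_rejects,
            "selected_features": self.selection.selected,
            "rejection_reason": self.selection.rejection_reason,
            "per_fold": {
                kind: [{k: (v if not isinstance(v, float) or np.isfinite(v) else None)
                        for k, v in row.items()}
                       for row in rows]
                for kind, rows in self.per_fold.items()
            },
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def run_pipeline(
    seed: int = 0,
    *,
    n_junctions: int = N_JUNCTIONS_DEFAULT,
    base_config: synthgen.PhantomConfig = COHORT_CONFIG,
    models: tuple[str, ...] = ("logreg", "rf", "cnn"),
    cnn_folds: tuple[int, ...] | str = (0,),
    cnn_max_epochs: int = 20,
    cnn_max_train: int = 1024,
    cnn_patience: int = 3,
    k_features: int = 4,
    shuffle_labels: bool = False,
) -> PipelineResult:
    """Run the whole synthetic study under one seed.

    ``shuffle_labels`` permutes patch labels within the whole table before
    any training (a leakage guard: grouped held-out AUROC must then hover
    at chance for every model). CNN variants accepted in ``models``:
    "cnn", "cnn-v1", "cnn-v2".
    """
    rng = np.random.default_rng(seed)
    patches, table, rejects = build_patch_dataset(n_junctions, base_config, seed)
    if shuffle_labels:
        table = table.copy()
        table["label"] = rng.permutation(table["label"].to_numpy())
        for p, lab in zip(patches, table["label"]):
            p.label = int(Label[lab])

    junction_ids = sorted(table["junction_id"].unique())
    plan = make_cv_plan(junction_ids, seed=seed)
    stats, selection = run_feature_engineering(table, plan, seed=seed, k=k_features)
    selected = selection.selected

    per_fold: dict[str, list[dict]] = {m: [] for m in models}
    for m in models:
        if m not in ("logreg", "rf", "cnn", "cnn-v1", "cnn-v2"):
            raise ValueError(f"unknown model {m!r}")

    if cnn_folds == "auto":
        # first fold whose test set carries both classes (AUROC defined)
        cnn_folds = ()
        for fi, fold in enumerate(plan.folds):
            test_labels = _rows_for(table, fold.test)["label"]
            if test_labels.nunique() == 2:
                cnn_folds = (fi,)
                break

    pred_rows: list[pd.DataFrame] = []

    def _record(kind: str, fi: int, rows: pd.DataFrame, p_pv: np.ndarray) -> None:
        pred_rows.append(pd.DataFrame({
            "model": kind, "fold": fi,
            "junction_id": rows["junction_id"].to_numpy(),
            "grid_x": rows["grid_x"].to_numpy(),
            "grid_y": rows["grid_y"].to_numpy(),
            "label": rows["label"].to_numpy(),
            "p_pv": p_pv,
        }))

    for fi, fold in enumerate(plan.folds):
        fit_rows = _rows_for(table, fold.train + fold.validation)
        test_rows = _rows_for(table, fold.test)
        y_test = (test_rows["label"] == "PV").to_numpy().astype(int)
        if "logreg" in models:
            lr = classify.train_logreg(fit_rows, fit_rows["label"], selected, seed=seed)
            p = lr.predict_proba(test_rows)
            per_fold["logreg"].append(confusion_and_metrics(y_test, p) | {"fold": fi})
            _record("logreg", fi, test_rows, p)
        if "rf" in models:
            rf = classify.train_rf(fit_rows, fit_rows["label"], selected, seed=seed)
            p = rf.predict_proba(test_rows)
            per_fold["rf"].append(confusion_and_metrics(y_test, p) | {"fold": fi})
            _record("rf", fi, test_rows, p)

        cnn_kinds = [m for m in models if m.startswith("cnn")]
        if cnn_kinds and fi in cnn_folds:
            pix_tr, y_tr, f_tr = _patch_arrays(patches, table, fold.train, selected)
            pix_va, y_va, f_va = _patch_arrays(patches, table, fold.validation, selected)
            pix_te, y_te, f_te = _patch_arrays(patches, table, fold.test, selected)
            if len(pix_tr) > cnn_max_train:
                sub = rng.choice(len(pix_tr), size=cnn_max_train, replace=False)
                pix_tr, y_tr, f_tr = pix_tr[sub], y_tr[sub], f_tr[sub]
            for kind in cnn_kinds:
                variant = "plain" if kind == "cnn" else kind.split("-")[1]
                model = classify.build_cnn(variant, seed=seed, n_features=len(selected))
                tm = classify.train_cnn(
                    model, pix_tr, y_tr, pix_va, y_va,
                    train_features=f_tr if variant != "plain" else None,
                    val_features=f_va if variant != "plain" else None,
                    feature_names=selected, seed=seed,
                    max_epochs=cnn_max_epochs, patience=cnn_patience,
                )
                p_te = tm.predict_proba(f_te if variant != "plain" else None, pixels=pix_te)
                per_fold[kind].append(
                    confusion_and_metrics(y_te, p_te) | {"fold": fi})
                _record(kind, fi, _rows_for(table, fold.test), p_te)

    label_counts = table["label"].value_counts().to_dict()
    return PipelineResult(
        plan=plan, stats=stats, selection=selection, per_fold=per_fold,
        n_patches=len(table), qc_rejects=rejects,
        label_counts={str(k): int(v) for k, v in label_counts.items()},
        predictions=pd.concat(pred_rows, ignore_index=True) if pred_rows else None,
    )
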