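"""Shared fixtures: phantoms and (expensive) trained-pipeline results.

The cohort-scale fixtures are session-scoped because they are the costly
part of the suite; every test that needs a trained model or a large patch
set shares them.
"""

from __future__ import annotations

import numpy as np
import pytest

from octava import classify, pipeline, synthgen

COHORT_SEED = 7
SMALL_SEED = 101
NULL_FEATURES = ["correlation", "skewness", "attenuation_sd", "energy"]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_phantom():
    """The default 200 x 40 phantom, speckle on."""
    return synthgen.generate_volume(synthgen.PhantomConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Speckle-free default phantom (surface undulation kept)."""
    return synthgen.generate_volume(synthgen.PhantomConfig(seed=11, speckle=False))


@pytest.fixture(scope="session")
def small_cohort():
    """10 phantom junctions with specimen variability -> patches + features."""
    patches, table, rejects = pipeline.build_patch_dataset(n_junctions=10, seed=SMALL_SEED)
    return patches, table, rejects


@pytest.fixture(scope="session")
def cohort_result():
    """The full default study: 26 junctions, ~3000 patches, LR/RF over all
    seven folds, the patch CNN on one two-class fold."""
    return pipeline.run_pipeline(
        seed=COHORT_SEED,
        models=("logreg", "rf", "cnn"),
        cnn_folds="auto",
        cnn_max_epochs=8,
        cnn_max_train=896,
        cnn_patience=3,
    )


@pytest.fixture(scope="session")
def trained_small_cnn(small_cohort):
    """A patch-only CNN trained on the small cohort (for Grad-CAM and
    probability-map tests); returns (TrainedModel, patches, table)."""
    patches, table, _ = small_cohort
    junctions = sorted(table["junction_id"].unique())
    train_j, val_j = tuple(junctions[:7]), tuple(junctions[7:9])
    pix_tr, y_tr, _ = pipeline._patch_arrays(patches, table, train_j, NULL_FEATURES)
    pix_va, y_va, _ = pipeline._patch_arrays(patches, table, val_j, NULL_FEATURES)
    rng = np.random.default_rng(3)
    if len(pix_tr) > 640:
        sub = rng.choice(len(pix_tr), 640, replace=False)
        pix_tr, y_tr = pix_tr[sub], y_tr[sub]
    model = classify.build_cnn("plain", seed=3)
    tm = classify.train_cnn(model, pix_tr, y_tr, pix_va, y_va,
                            seed=3, max_epochs=6, patience=2)
    return tm, patches, table


@pytest.fixture(scope="session")
def null_aurocs(small_cohort):
    """Held-out AUROC of all five classifiers after a global label shuffle.

    Shuffling destroys any patch-label association, so held-out AUROC must
    hover at chance for every model; a systematic shift would indicate
    leakage through the preprocessing (standardizer, class weights) or the
    split. CNNs get a short, small-sample training run: an undertrained
    null model is still a valid leakage guard.
    """
    patches, table, _ = small_cohort
    rng = np.random.default_rng(42)
    table = table.copy()
    table["label"] = rng.permutation(table["label"].to_numpy())
    all_j = tuple(sorted(table["junction_id"].unique()))
    pix, y, feats = pipeline._patch_arrays(patches, table, all_j, NULL_FEATURES)
    order = rng.permutation(len(y))
    tr, va, te = order[:256], order[256:384], order[384:]
    from sklearn.metrics import roc_auc_score

    out = {}
    fit = np.concatenate([tr, va])
    lr = classify.train_logreg(feats[fit], y[fit], NULL_FEATURES, seed=0)
    out["logreg"] = roc_auc_score(y[te], lr.predict_proba(feats[te]))
    rf = classify.train_rf(feats[fit], y[fit], NULL_FEATURES, seed=0)
    out["rf"] = roc_auc_score(y[te], rf.predict_proba(feats[te]))
    for variant, kind in (("plain", "cnn"), ("v1", "cnn-v1"), ("v2", "cnn-v2")):
        model = classify.build_cnn(variant, seed=0)
        tm = classify.train_cnn(
            model, pix[tr], y[tr], pix[va], y[va],
            train_features=feats[tr] if variant != "plain" else None,
            val_features=feats[va] if variant != "plain" else None,
            feature_names=NULL_FEATURES, seed=0, max_epochs=2, patience=2)
        p = tm.predict_proba(feats[te] if variant != "plain" else None, pixels=pix[te])
        out[kind] = roc_auc_score(y[te], p)
    return out
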