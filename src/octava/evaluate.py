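"""Grouped cross-validation, metrics, ROC, probability maps, Grad-CAM.

All evaluation is junction-grouped: every patch from one venoatrial
junction stays in the same split, so reported performance reflects
generalization to unseen specimens. Seven folds cover every junction's
patches exactly once as test data; with 26 junctions the splits are
train/validation/test = 18/4/4 for the first six folds and 20/4/2 for the
last.

PV is the positive class throughout; a patch is called PV when
P(PV) >= 0.5. Metrics per test split: accuracy, sensitivity, specificity,
MCC (with normMCC = (MCC+1)/2), and AUROC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .classify import TrainedModel
from .patching import Patch
from .volume_io import Label

N_FOLDS = 7
PV_THRESHOLD = 0.5


@dataclass
class Fold:
    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]


@dataclass
class CVPlan:
    folds: list[Fold]
    seed: int

    def to_json(self) -> str:
        return json.dumps([{"train": f.train, "validation": f.validation,
                            "test": f.test} for f in self.folds])


def make_cv_plan(junction_ids: list[str], seed: int, n_folds: int = N_FOLDS) -> CVPlan:
    """Partition junctions into grouped CV folds.

    A seeded permutation is cut into ``n_folds`` test blocks of size
    ceil(n / n_folds), the last block absorbing the remainder (every block
    kept non-empty); for n = 26 this reproduces test sizes
    (4,4,4,4,4,4,2). Validation junctions are drawn (seeded) from the
    non-test remainder with the same nominal size, giving the 18/4/4 and
    20/4/2 train/validation/test splits; the rest train. Each junction is
    tested exactly once and plays a single role within any fold.
    """
    ids = list(junction_ids)
    n = len(ids)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} junctions, got {n}")
    if len(set(ids)) != n:
        raise ValueError("junction ids must be unique")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]

    block = int(np.ceil(n / n_folds))
    sizes = []
    remaining = n
    for i in range(n_folds):
        take = min(block, remaining - (n_folds - i - 1))
        sizes.append(take)
        remaining -= take
    test_blocks = []
    pos = 0
    for s in sizes:
        test_blocks.append(tuple(perm[pos:pos + s]))
        pos += s

    folds = []
    for i, test in enumerate(test_blocks):
        rest = [j for j in perm if j not in test]
        val_size = min(block, len(rest) - 1)  # keep at least one train junction
        val_idx = rng.choice(len(rest), size=val_size, replace=False)
        validation = tuple(rest[k] for k in sorted(val_idx))
        train = tuple(j for j in rest if j not in validation)
        folds.append(Fold(train=train, validation=validation, test=test))
    return CVPlan(folds=folds, seed=seed)


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient of a 2x2 confusion matrix.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 by
    convention when any marginal is empty.
    """
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def confusion_and_metrics(y_true, p_pv: np.ndarray,
                          threshold: float = PV_THRESHOLD) -> dict:
    """One metrics row from true labels and P(PV) scores (PV positive).

    Metrics with an empty denominator are returned as NaN and listed under
    ``undefined``; MCC falls back to 0 by convention in that case.
    """
    y = np.asarray(y_true)
    if y.dtype.kind in "UO":
        y = (y == "PV").astype(int)
    elif y.max(initial=0) > 1:
        y = (y == Label.PV).astype(int)
    p = np.asarray(p_pv, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError("label/score length mismatch")
    call = p >= threshold
    tp = int(np.sum(call & (y == 1)))
    fp = int(np.sum(call & (y == 0)))
    tn = int(np.sum(~call & (y == 0)))
    fn = int(np.sum(~call & (y == 1)))

    undefined = []
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    if not tp + fn:
        undefined.append("sensitivity")
    if not tn + fp:
        undefined.append("specificity")
    m = mcc(tp, tn, fp, fn)
    if (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn) == 0:
        undefined.append("mcc_convention_zero")
    try:
        auroc = roc_curve(y, p)[2] if len(np.unique(y)) > 1 else np.nan
    except ValueError:
        auroc = np.nan
    if np.isnan(auroc):
        undefined.append("auroc")
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": (tp + tn) / y.size,
        "sensitivity": sens,
        "specificity": spec,
        "mcc": m,
        "norm_mcc": (m + 1.0) / 2.0,
        "auroc": auroc,
        "undefined": undefined,
    }


def roc_curve(y_true, p_pv) -> tuple[np.ndarray, np.ndarray, float]:
    """(fpr, tpr, auroc) by threshold sweep over the unique scores.

    Trapezoidal AUROC; identical to the rank-based (Mann-Whitney)
    formulation, ties counted one half.
    """
    y = np.asarray(y_true)
    if y.dtype.kind in "UO":
        y = (y == "PV").astype(int)
    elif y.max(initial=0) > 1:
        y = (y == Label.PV).astype(int)
    p = np.asarray(p_pv, dtype=np.float64)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    distinct = np.r_[np.diff(p_sorted) != 0, True]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auroc


def metrics_summary(per_fold: list[dict]) -> pd.DataFrame:
    """Mean +/- SD across folds (Table-style presentation), NaNs skipped."""
    df = pd.DataFrame(per_fold)
    cols = ["accuracy", "sensitivity", "specificity", "mcc", "norm_mcc", "auroc"]
    return pd.DataFrame({"mean": df[cols].mean(), "sd": df[cols].std(ddof=1)})


def probability_map(patches: list[Patch], p_pv: np.ndarray) -> np.ndarray:
    """En-face map of P(PV) on the tile grid; absent tiles are NaN.

    Tiling is non-overlapping, so colliding grid coordinates (within one
    junction) are an error.
    """
    if len(patches) != len(p_pv):
        raise ValueError("patch/score length mismatch")
    gx = np.array([p.grid_x for p in patches])
    gy = np.array([p.grid_y for p in patches])
    grid = np.full((gx.max() + 1, gy.max() + 1), np.nan)
    for x, y, prob in zip(gx, gy, p_pv):
        if np.isfinite(grid[x, y]):
            raise ValueError(f"colliding grid cell ({x}, {y}): tiling is non-overlapping")
        grid[x, y] = prob
    return grid


def gradcam(trained: TrainedModel, patch_pixels: np.ndarray,
            target_class: Label | str = Label.PV,
            patch_features: np.ndarray | None = None) -> np.ndarray:
    """Grad-CAM heat map (64 x 128, values in [0, 1]) for one patch.

    Channel-wise gradients of the target-class score at the last conv
    layer's activation are globally average-pooled into channel weights;
    the weighted activation sum is rectified, bilinearly upsampled to the
    patch size, and max-normalized. The binary PV logit serves as the PV
    score and its negation as the LA score. A saturated prediction with
    all-zero gradients yields an all-zero map.
    """
    model = trained.model
    if not isinstance(model, nn.CNNClassifier):
        raise TypeError("Grad-CAM requires a CNN model")
    if isinstance(target_class, str):
        target_class = Label[target_class]
    if target_class not in (Label.LA, Label.PV):
        raise ValueError("target_class must be LA or PV")

    x = (np.asarray(patch_pixels, dtype=np.float32) / 255.0)[None, None]
    feats = None
    if model.variant != "plain":
        if patch_features is None:
            raise ValueError("Grad-CAM on a fusion variant needs the patch's "
                             "raw engineered features")
        feats = trained.standardizer.transform(
            np.asarray(patch_features, dtype=np.float64)[None]).astype(np.float32)
    model.forward(x, feats, train=False, capture=True)
    sign = 1.0 if target_class == Label.PV else -1.0
    dact = model.backward(np.array([sign], dtype=np.float32))
    act = model.captured_activation[0]  # (h, w, C)
    grad = dact[0]
    weights = grad.mean(axis=(0, 1))
    cam = np.maximum((act * weights).sum(axis=-1), 0.0)
    H, W = patch_pixels.shape
    cam = ndimage.zoom(cam, (H / cam.shape[0], W / cam.shape[1]), order=1)
    top = cam.max()
    return cam / top if top > 0 else cam


def heatmap_depth_centroid(cam: np.ndarray) -> float:
    """Mean depth (rows) of a heat map's mass; NaN for an all-zero map."""
    total = cam.sum()
    if total <= 0:
        return float("nan")
    rows = np.arange(cam.shape[0])
    return float((cam.sum(axis=1) * rows).sum() / total)


# ---------------------------------------------------------------------------
# figures


def plot_roc(curves: dict[str, tuple[np.ndarray, np.ndarray, float]], path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, (fpr, tpr, auroc) in curves.items():
        ax.plot(fpr, tpr, label=f"{name} (AUROC {auroc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_probability_map(grid: np.ndarray, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(grid.T, origin="lower", vmin=0.0, vmax=1.0, cmap="viridis",
                   aspect="auto", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="P(PV)")
    ax.set_xlabel("tile x")
    ax.set_ylabel("tile y")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gradcam_panel(patch_pixels: np.ndarray, cam_la: np.ndarray,
                       cam_pv: np.ndarray, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(10, 3))
    axes[0].imshow(patch_pixels, cmap="gray")
    axes[0].set_title("patch")
    axes[1].imshow(cam_la, cmap="inferno", vmin=0, vmax=1)
    axes[1].set_title("LA gradient")
    axes[2].imshow(cam_pv, cmap="inferno", vmin=0, vmax=1)
    axes[2].set_title("PV gradient")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
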