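"""The five patch classifiers and their training recipes.

* **Logistic regression** — L2 penalty with coefficient 1.0, on selected
  features standardized with training-set statistics; train and validation
  junctions are merged for fitting.
* **Random forest** — 100 trees, Gini criterion, unscaled features, train +
  validation merged; exposes impurity importances for feature engineering.
* **CNNs** — the patch-only network and the V1/V2 feature-fusion variants
  (architecture in :mod:`octava.nn`): Adam at learning rate 1e-4, batch
  size 256, dropout 0.15, class-weighted cross-entropy, 50% left-right flip
  augmentation of training patches, early stopping on validation AUROC with
  the best checkpoint restored. Pixels are mapped from uint8 to [0, 1];
  engineered features (v1/v2) are standardized with the training
  Standardizer.

Test-set leakage is excluded by construction: the Standardizer and the
class weights are functions of training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from . import nn
from .patching import Patch
from .volume_io import Label

logger = logging.getLogger(__name__)

LEARNING_RATE = 1e-4
BATCH_SIZE = 256
DROPOUT_P = 0.15
MAX_EPOCHS = 100
EARLY_STOP_PATIENCE = 10


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on training rows only.

    Zero-variance columns transform to 0 rather than dividing by zero.
    """

    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        self.mean = X.mean(axis=0)
        self.sd = X.std(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("Standardizer not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.mean.size:
            raise ValueError("feature-count mismatch")
        sd = np.where(self.sd > 0, self.sd, 1.0)
        Z = (X - self.mean) / sd
        Z[:, self.sd == 0] = 0.0
        return Z


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it faithfully."""

    kind: str  # {"logreg", "rf", "cnn", "cnn-v1", "cnn-v2"}
    model: object
    standardizer: Standardizer | None
    feature_names: list[str] | None
    seed: int
    training_log: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray | pd.DataFrame | None = None,
                      pixels: np.ndarray | None = None) -> np.ndarray:
        """P(PV) per item. ML models take features; CNNs take uint8 pixel
        stacks (N, 64, 128) and, for v1/v2, the raw selected features."""
        if self.kind in ("logreg", "rf"):
            X = self._feature_matrix(X)
            if self.standardizer is not None:
                X = self.standardizer.transform(X)
            return self.model.predict_proba(X)[:, 1]
        x = _pixels_to_input(pixels)
        feats = None
        if self.kind != "cnn":
            feats = self.standardizer.transform(self._feature_matrix(X)).astype(np.float32)
        return self.model.predict_proba(x, feats)

    def _feature_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        if self.feature_names is not None and X.shape[1] != len(self.feature_names):
            raise ValueError("feature-count mismatch")
        return X


def _labels_01(labels: np.ndarray | pd.Series) -> np.ndarray:
    """Map labels to {0: LA, 1: PV}."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == "PV").astype(int)
    return (arr == Label.PV).astype(int) if arr.max() > 1 else arr.astype(int)


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")


def train_logreg(features: pd.DataFrame | np.ndarray, labels, feature_names: list[str],
                 seed: int = 0) -> TrainedModel:
    """L2 logistic regression (penalty coefficient 1.0) on standardized
    selected features; fit on train+validation rows combined."""
    X = features[feature_names].to_numpy() if isinstance(features, pd.DataFrame) else np.asarray(features)
    y = _labels_01(labels)
    _check_two_classes(y)
    std = Standardizer().fit(X)
    # sklearn's default penalty is the L2 norm; C=1.0 sets its coefficient
    clf = LogisticRegression(C=1.0, random_state=seed, max_iter=1000)
    clf.fit(std.transform(X), y)
    return TrainedModel("logreg", clf, std, feature_names, seed)


def train_rf(features: pd.DataFrame | np.ndarray, labels, feature_names: list[str],
             seed: int = 0, n_trees: int = 100) -> TrainedModel:
    """Random forest: 100 trees, Gini criterion, unscaled features."""
    X = features[feature_names].to_numpy() if isinstance(features, pd.DataFrame) else np.asarray(features)
    y = _labels_01(labels)
    _check_two_classes(y)
    clf = RandomForestClassifier(n_estimators=n_trees, criterion="gini", random_state=seed)
    clf.fit(X, y)
    tm = TrainedModel("rf", clf, None, feature_names, seed)
    tm.training_log["importances"] = pd.Series(clf.feature_importances_, index=feature_names)
    return tm


def build_cnn(variant: str = "plain", seed: int = 0, n_features: int = 4,
              dropout_p: float = DROPOUT_P) -> nn.CNNClassifier:
    """Build an untrained CNN of the given variant ('plain', 'v1', 'v2')."""
    return nn.CNNClassifier(variant=variant, n_features=n_features,
                            dropout_p=dropout_p, seed=seed)


def _pixels_to_input(pixels: np.ndarray) -> np.ndarray:
    """uint8 (N, 64, 128) -> float32 (N, 1, 64, 128) in [0, 1]."""
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        pixels = pixels[None]
    return (pixels.astype(np.float32) / 255.0)[:, None, :, :]


def class_weights(y: np.ndarray) -> np.ndarray:
    """Per-class weights proportional to inverse frequency, mean 1 over the
    training rows; computed from training labels only."""
    y = np.asarray(y)
    n = y.size
    w_pos = n / (2.0 * max(y.sum(), 1))
    w_neg = n / (2.0 * max(n - y.sum(), 1))
    per_row = np.where(y == 1, w_pos, w_neg).astype(np.float64)
    return per_row / per_row.mean()


def train_cnn(
    model: nn.CNNClassifier,
    train_pixels: np.ndarray,
    train_labels,
    val_pixels: np.ndarray | None,
    val_labels=None,
    train_features: np.ndarray | None = None,
    val_features: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    *,
    seed: int = 0,
    max_epochs: int = MAX_EPOCHS,
    patience: int = EARLY_STOP_PATIENCE,
    learning_rate: float = LEARNING_RATE,
    batch_size: int = BATCH_SIZE,
    augment: bool = True,
) -> TrainedModel:
    """Train a CNN with the stated recipe and return the best checkpoint.

    ``train_features``/``val_features`` are the RAW selected feature values
    for v1/v2; they are standardized here with training-set statistics.
    With no validation set, training falls back to running all
    ``max_epochs`` and keeping the final weights.
    """
    rng = np.random.default_rng(seed)
    y_train = _labels_01(train_labels)
    _check_two_classes(y_train)
    x_train = _pixels_to_input(train_pixels)

    std = None
    f_train = f_val = None
    if model.variant != "plain":
        if train_features is None:
            raise ValueError(f"variant {model.variant} requires engineered features")
        std = Standardizer().fit(np.asarray(train_features))
        f_train = std.transform(train_features).astype(np.float32)
        if val_features is not None:
            f_val = std.transform(val_features).astype(np.float32)

    have_val = val_pixels is not None and len(val_pixels) > 0
    if have_val:
        x_val = _pixels_to_input(val_pixels)
        y_val = _labels_01(val_labels)
    else:
        logger.warning("no validation set: fixed-epoch training, final weights kept")

    w_row = class_weights(y_train)
    opt = nn.Adam(model.params(), lr=learning_rate)

    best_auroc, best_state, best_epoch, since_best = -np.inf, None, -1, 0
    history = []
    n = x_train.shape[0]
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            xb = x_train[idx]
            if augment:
                flip = rng.random(len(idx)) < 0.5
                xb = xb.copy()
                xb[flip] = xb[flip, :, :, ::-1]
            fb = f_train[idx] if f_train is not None else None
            logits = model.forward(xb, fb, train=True)
            loss, dz = nn.weighted_bce_with_logits(logits, y_train[idx], w_row[idx])
            model.backward(dz)
            opt.step()
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        row = {"epoch": epoch, "train_loss": epoch_loss}
        if have_val:
            p_val = model.predict_proba(x_val, f_val)
            val_auroc = roc_auc_score(y_val, p_val) if len(np.unique(y_val)) > 1 else np.nan
            row["val_auroc"] = val_auroc
            if np.isfinite(val_auroc) and val_auroc > best_auroc:
                best_auroc, best_state, best_epoch = val_auroc, model.state_dict(), epoch
                since_best = 0
            else:
                since_best += 1
        history.append(row)
        if have_val and (since_best >= patience or best_auroc >= 0.999):
            break
    if best_state is not None:
        model.load_state_dict(best_state)

    kind = "cnn" if model.variant == "plain" else f"cnn-{model.variant}"
    tm = TrainedModel(kind, model, std, feature_names, seed)
    tm.training_log = {"history": history, "best_epoch": best_epoch,
                       "best_val_auroc": best_auroc if have_val else None}
    return tm


def predict_proba(trained: TrainedModel, features=None, pixels=None) -> np.ndarray:
    """P(PV) per item; hard label is PV when P(PV) >= 0.5."""
    return trained.predict_proba(features, pixels)
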