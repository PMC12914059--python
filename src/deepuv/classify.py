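"""Image- and feature-based T cell classification.

Two estimator families share a common metric surface:

* :class:`ResidualNetClassifier` — a small residual conv-net (numpy) on
  single-channel static crops (activated / dead / quiescent) or 4-channel
  dynamic crops [attenuation, phasor g, phasor s, power-law slope] for
  CD4-like vs CD8-like subtyping;
* :class:`LinearBaselineClassifier` — a deterministic linear discriminant
  on standardized per-cell feature vectors, used as a fast baseline and as
  the test surface for composition estimation.

Helpers compute stratified 80/20 training with held-out confusion
matrices, stratified k-fold cross-validation with pooled metrics, per-
sample composition (viability %, activation %) and linear agreement fits
against a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from ._resnet import Adam, ResNet, softmax_cross_entropy


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: 80/20 split, ~30 epochs, translation/reflection
    augmentation, 5-fold cross-validation."""

    split: float = 0.8
    epochs: int = 30
    augment_translation: bool = True
    augment_reflection: bool = True
    max_translate: int = 8  # px, at the original crop scale
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.split < 1:
            raise ValueError("split must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def build_crops(static_crops, dynamic_channels=None) -> np.ndarray:
    """Assemble classifier inputs as an ``(n, C, H, W)`` array.

    With only static crops the result is single-channel; with
    ``dynamic_channels`` (a sequence of per-cell ``(3, H, W)`` arrays
    holding phasor g, phasor s and power-law slope crops) the result is
    the fixed 4-channel order [attenuation, g, s, beta].  The exterior of
    the cell mask is zero in every channel.
    """
    imgs = [c.image if hasattr(c, "image") else np.asarray(c, dtype=float) for c in static_crops]
    x = np.stack(imgs)[:, None, :, :]
    if dynamic_channels is None:
        return x
    dyn = np.stack([np.asarray(d, dtype=float) for d in dynamic_channels])
    if dyn.shape[0] != x.shape[0] or dyn.shape[1] != 3 or dyn.shape[2:] != x.shape[2:]:
        raise ValueError("dynamic channels must be (n, 3, H, W) congruent with crops")
    out = np.concatenate([x, dyn], axis=1)
    # dynamic maps may be NaN outside the analyzed mask; crops are zero-padded
    return np.nan_to_num(out, nan=0.0)


def _block_pool(x: np.ndarray, side: int) -> np.ndarray:
    """Average-pool (n, C, H, W) down to (n, C, side, side)."""
    n, c, h, w = x.shape
    if h == side and w == side:
        return x
    if h % side or w % side:
        raise ValueError(f"crop side {h} is not a multiple of network input side {side}")
    fh, fw = h // side, w // side
    return x.reshape(n, c, side, fh, side, fw).mean(axis=(3, 5))


def _augment_batch(x: np.ndarray, rng, max_shift: int, reflect: bool) -> np.ndarray:
    out = x.copy()
    n = x.shape[0]
    if max_shift > 0:
        for i in range(n):
            dy, dx = rng.integers(-max_shift, max_shift + 1, size=2)
            shifted = np.roll(out[i], (dy, dx), axis=(1, 2))
            if dy > 0:
                shifted[:, :dy, :] = 0
            elif dy < 0:
                shifted[:, dy:, :] = 0
            if dx > 0:
                shifted[:, :, :dx] = 0
            elif dx < 0:
                shifted[:, :, dx:] = 0
            out[i] = shifted
    if reflect:
        flips = rng.integers(0, 2, size=(n, 2)).astype(bool)
        out[flips[:, 0]] = out[flips[:, 0], :, ::-1, :]
        out[flips[:, 1]] = out[flips[:, 1], :, :, ::-1]
    return out


class ResidualNetClassifier(BaseEstimator, ClassifierMixin):
    """Small residual network on (n, C, H, W) cell crops.

    Stem convolution, three residual blocks (16/32/64 channels with
    stride-2 between), global average pooling and a linear softmax head,
    trained with cross-entropy and Adam.  Inputs larger than
    ``input_side`` are average-pooled down before the network; channels
    are standardized with statistics from the training set.

    Parameters mirror the training protocol: 80/20-style epochs count,
    translation/reflection augmentation, explicit seed.
    """

    def __init__(self, input_side=32, widths=(16, 32, 64), epochs=30,
                 batch_size=32, lr=1e-3, augment=True, max_translate=8,
                 seed=0):
        self.input_side = input_side
        self.widths = widths
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.augment = augment
        self.max_translate = max_translate
        self.seed = seed

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        x = _block_pool(np.asarray(X, dtype=np.float64), self.input_side)
        return (x - self.channel_mean_[None, :, None, None]) / self.channel_std_[None, :, None, None]

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError("X must be (n, C, H, W)")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need >= 2 classes")
        pooled = _block_pool(X, self.input_side)
        self.channel_mean_ = pooled.mean(axis=(0, 2, 3))
        self.channel_std_ = pooled.std(axis=(0, 2, 3))
        self.channel_std_[self.channel_std_ == 0] = 1.0
        xz = (pooled - self.channel_mean_[None, :, None, None]) / self.channel_std_[None, :, None, None]

        rng = np.random.default_rng(self.seed)
        net = ResNet(X.shape[1], len(self.classes_), widths=self.widths, seed=self.seed)
        opt = Adam(net.params, lr=self.lr)
        n = xz.shape[0]
        shift = max(1, round(self.max_translate * self.input_side / X.shape[2])) if self.augment else 0
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = xz[idx]
                if self.augment:
                    xb = _augment_batch(xb, rng, shift, reflect=True)
                logits, cache = net.forward(xb, want_cache=True)
                loss, dlogits = softmax_cross_entropy(logits, y_idx[idx])
                grads = net.backward(dlogits, cache)
                opt.step(net.params, grads)
                epoch_loss += loss * len(idx)
            self.loss_history_.append(epoch_loss / n)
        self.net_ = net
        return self

    def decision_function(self, X):
        check_is_fitted(self, "net_")
        return self.net_.forward(self._prepare(X))

    def predict_proba(self, X):
        logits = self.decision_function(X)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class LinearBaselineClassifier(BaseEstimator, ClassifierMixin):
    """Linear discriminant on standardized per-cell features.

    Deterministic counterpart to the conv-net with the same metric
    interface; falls back to ridge-style shrinkage when the within-class
    covariance is singular.  Constant features carry no discriminative
    information and are tolerated (zero-variance columns are left at zero
    after standardization, so predictions ignore them).
    """

    def __init__(self, shrinkage_fallback: float = 1e-3):
        self.shrinkage_fallback = shrinkage_fallback

    def fit(self, X, y):
        X = self._to_array(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need >= 2 classes")
        self.scaler_ = StandardScaler().fit(X)
        Xz = self.scaler_.transform(X)
        lda = LinearDiscriminantAnalysis()
        try:
            with np.errstate(all="ignore"):
                lda.fit(Xz, y)
                if not np.all(np.isfinite(lda.coef_)):
                    raise np.linalg.LinAlgError("non-finite discriminant")
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn("singular within-class covariance; using shrinkage LDA")
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=self.shrinkage_fallback)
            lda.fit(Xz, y)
        self.lda_ = lda
        self.classes_ = lda.classes_
        return self

    @staticmethod
    def _to_array(X):
        X = pd.DataFrame(X).to_numpy(dtype=float) if not isinstance(X, np.ndarray) else X.astype(float)
        return np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)

    def predict(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.predict(self.scaler_.transform(self._to_array(X)))

    def predict_proba(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.predict_proba(self.scaler_.transform(self._to_array(X)))


@dataclass
class ClassifierReport:
    """Held-out evaluation: confusion matrix plus per-class metrics."""

    classes: list
    confusion: np.ndarray  # rows = true class, cols = predicted
    accuracy: float
    precision: dict = field(default_factory=dict)
    recall: dict = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        """Recall of the first class (2-class convention)."""
        return self.recall[self.classes[0]]

    @property
    def specificity(self) -> float:
        """Recall of the second class (2-class convention)."""
        return self.recall[self.classes[1]]


def evaluate(y_true, y_pred, classes=None) -> ClassifierReport:
    classes = list(classes) if classes is not None else sorted(np.unique(np.concatenate([y_true, y_pred])))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    acc = float(np.trace(cm) / cm.sum())
    precision, recall = {}, {}
    for i, c in enumerate(classes):
        col = cm[:, i].sum()
        row = cm[i, :].sum()
        precision[c] = float(cm[i, i] / col) if col else float("nan")
        recall[c] = float(cm[i, i] / row) if row else float("nan")
    return ClassifierReport(classes, cm, acc, precision, recall)


def train_cnn(crops: np.ndarray, labels, config: TrainConfig = TrainConfig()):
    """Stratified 80/20 train/test of the residual network.

    Returns ``(model, report, (train_idx, test_idx))``; the report holds
    the held-out confusion matrix and per-class precision/recall.
    """
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, train_size=config.split, stratify=labels, random_state=config.seed)
    model = ResidualNetClassifier(
        epochs=config.epochs, augment=config.augment_translation or config.augment_reflection,
        max_translate=config.max_translate, seed=config.seed)
    model.fit(crops[train_idx], labels[train_idx])
    pred = model.predict(crops[test_idx])
    report = evaluate(labels[test_idx], pred, classes=list(model.classes_))
    return model, report, (train_idx, test_idx)


def cross_validate(estimator, X, y, folds: int = 5, seed: int = 0):
    """Stratified k-fold cross-validation with pooled confusion matrix.

    Returns ``(pooled_report, per_fold_reports)``.  Works for any
    estimator with the sklearn fit/predict contract, including the
    residual network and the linear baseline.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes")
    X_arr = X if isinstance(X, np.ndarray) else pd.DataFrame(X).to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    classes = sorted(np.unique(y))
    y_true_all, y_pred_all, fold_reports = [], [], []
    for train_idx, test_idx in skf.split(X_arr, y):
        model = clone(estimator)
        model.fit(X_arr[train_idx], y[train_idx])
        pred = model.predict(X_arr[test_idx])
        fold_reports.append(evaluate(y[test_idx], pred, classes=classes))
        y_true_all.append(y[test_idx])
        y_pred_all.append(pred)
    pooled = evaluate(np.concatenate(y_true_all), np.concatenate(y_pred_all), classes=classes)
    return pooled, fold_reports


def predict_composition(model, X) -> tuple[float, float]:
    """Sample composition from per-cell 3-class predictions.

    viability % = 100 * (1 - dead/total); activation % = 100 * activated /
    (activated + quiescent) among live cells (NaN if no live cells).
    """
    X_arr = X if isinstance(X, np.ndarray) else pd.DataFrame(X).to_numpy(dtype=float)
    if len(X_arr) == 0:
        raise ValueError("empty sample")
    pred = np.asarray(model.predict(X_arr))
    total = len(pred)
    dead = int(np.sum(pred == "dead"))
    activated = int(np.sum(pred == "activated"))
    quiescent = int(np.sum(pred == "quiescent"))
    viability = 100.0 * (1.0 - dead / total)
    live = activated + quiescent
    activation = 100.0 * activated / live if live else float("nan")
    return viability, activation


def agreement_fit(predicted, reference) -> tuple[float, float, float]:
    """OLS of predicted on reference; returns (slope, intercept, r^2)."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.size < 3:
        raise ValueError("need >= 3 paired samples")
    if reference.std() == 0:
        raise ValueError("reference has zero variance")
    slope, intercept, r, _, _ = stats.linregress(reference, predicted)
    return float(slope), float(intercept), float(r * r)
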