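"""Training protocol, classification metrics, and reference baselines.

Training uses mini-batch Adam with a one-step learning-rate schedule
(0.001 dropped to 0.0001 at the switch epoch), categorical cross-entropy,
batch size 8, 150 epochs by default — fully seeded and reproducible.

Evaluation follows the one-vs-rest reduction: per-class TP/FP/FN/TN from
the confusion matrix (rows = true class), then

    P = TP / (TP + FP) * 100        R = TP / (TP + FN) * 100
    F1 = 2 P R / (P + R)            Acc = correct / total * 100

with AP the macro average of per-class precision.  ROC curves and AUC are
one-vs-rest on predicted probabilities (trapezoid rule).  SVM (RBF) and
random-forest baselines with fixed reference hyperparameters are provided
for comparison experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.svm import SVC

from .autodiff import Tensor, cross_entropy
from .fusion import fit_standardizer
from .heads import HeadConfig, build_head, predict_proba
from .nn import Adam, Module

__all__ = [
    "TrainConfig", "EvalReport", "train_head", "evaluate",
    "evaluate_predictions", "baseline_classifiers", "compare_pipelines",
]


@dataclass(frozen=True)
class TrainConfig:
    lr_initial: float = 0.001
    lr_final: float = 0.0001
    lr_switch_epoch: int = 75
    epochs: int = 150
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.lr_final > self.lr_initial:
            raise ValueError("lr_final must be <= lr_initial")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


def _mean_loss(model: Module, X: np.ndarray, y: np.ndarray,
               batch_size: int) -> float:
    total, n = 0.0, len(y)
    for s in range(0, n, batch_size):
        xb, yb = X[s:s + batch_size], y[s:s + batch_size]
        total += float(cross_entropy(model(Tensor(xb)), yb).data) * len(yb)
    return total / n


def train_head(model: Module, features: np.ndarray, labels: np.ndarray,
               split: np.ndarray | None = None,
               config: TrainConfig = TrainConfig(),
               forward_input=None) -> tuple[Module, dict[str, list[float]]]:
    """Train any feature-in classifier module; returns (model, loss curves).

    ``split`` restricts updates to samples flagged ``"train"`` and records a
    validation loss on ``"val"`` samples each epoch.  ``forward_input`` is an
    optional hook mapping a raw feature batch to the model input array
    (used when fine-tuning image backbones on NCHW stacks).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise ValueError("features and labels differ in length")
    if split is None:
        tr = np.arange(len(y))
        va = np.array([], dtype=int)
    else:
        split = np.asarray(split)
        tr = np.flatnonzero(split == "train")
        va = np.flatnonzero(split == "val")
    if config.epochs == 0:
        return model, {"train_loss": [], "val_loss": []}
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr_initial)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    model.train()
    for epoch in range(config.epochs):
        opt.lr = config.lr_initial if epoch < config.lr_switch_epoch \
            else config.lr_final
        order = tr[rng.permutation(len(tr))]
        for s in range(0, len(order), config.batch_size):
            idx = order[s:s + config.batch_size]
            xb = X[idx] if forward_input is None else forward_input(X[idx])
            opt.zero_grad()
            loss = cross_entropy(model(Tensor(xb)), y[idx])
            loss.backward()
            opt.step()
        model.eval()
        if forward_input is None:
            history["train_loss"].append(_mean_loss(model, X[tr], y[tr],
                                                    config.batch_size))
            if len(va):
                history["val_loss"].append(_mean_loss(model, X[va], y[va],
                                                      config.batch_size))
        else:
            history["train_loss"].append(
                _mean_loss(model, forward_input(X[tr]), y[tr], config.batch_size))
            if len(va):
                history["val_loss"].append(
                    _mean_loss(model, forward_input(X[va]), y[va],
                               config.batch_size))
        model.train()
    model.eval()
    return model, history


@dataclass
class EvalReport:
    """Confusion matrix plus per-class and macro metrics, all in percent."""

    confusion: np.ndarray
    class_names: list[str]
    precision: np.ndarray   # per class, %
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float         # %
    ap: float               # macro-averaged precision, %
    ap_literal_sum: float   # un-normalized sum of per-class precision fractions
    auc: np.ndarray | None = None       # per class, 0..1
    macro_auc: float | None = None
    roc_curves: list | None = None      # per class (fpr, tpr) arrays
    present: np.ndarray | None = None   # classes with >= 1 true sample

    @property
    def macro_precision(self) -> float:
        return float(self.precision[self.present].mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall[self.present].mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1[self.present].mean())

    def to_dict(self) -> dict:
        d = {
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "accuracy": self.accuracy,
            "ap": self.ap,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }
        if self.macro_auc is not None:
            d["macro_auc"] = self.macro_auc
            d["auc"] = self.auc.tolist()
        return d


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                         scores: np.ndarray | None = None,
                         class_names: list[str] | None = None,
                         n_classes: int | None = None) -> EvalReport:
    """Metrics from hard predictions (and optional per-class scores for ROC)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if n_classes is None:
        n_classes = scores.shape[1] if scores is not None \
            else int(max(y_true.max(), y_pred.max())) + 1
    if class_names is None:
        class_names = [str(i) for i in range(n_classes)]
    C = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(C, (y_true, y_pred), 1)
    tp = np.diag(C).astype(float)
    fp = C.sum(axis=0) - tp
    fn = C.sum(axis=1) - tp
    present = C.sum(axis=1) > 0
    if not present.all():
        absent = [class_names[i] for i in np.flatnonzero(~present)]
        warnings.warn(f"classes absent from labels, excluded from macro "
                      f"averages: {absent}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_frac = np.where(tp + fp > 0, tp / np.where(tp + fp > 0, tp + fp, 1), 0.0)
        r_frac = np.where(tp + fn > 0, tp / np.where(tp + fn > 0, tp + fn, 1), 0.0)
    P, R = 100.0 * p_frac, 100.0 * r_frac
    F1 = np.where(P + R > 0, 2.0 * P * R / np.where(P + R > 0, P + R, 1), 0.0)
    acc = 100.0 * tp.sum() / C.sum()
    ap = float(P[present].mean())
    auc_vals = macro_auc = curves = None
    if scores is not None:
        auc_vals = np.full(n_classes, np.nan)
        curves = [None] * n_classes
        for c in np.flatnonzero(present):
            if (y_true == c).all():
                continue  # ROC undefined without negatives
            fpr, tpr, _ = _roc_curve(y_true == c, scores[:, c])
            curves[c] = (fpr, tpr)
            auc_vals[c] = _trapezoid_auc(fpr, tpr)
        if np.isfinite(auc_vals).any():
            macro_auc = float(np.nanmean(auc_vals))
    return EvalReport(C, class_names, P, R, F1, float(acc), ap,
                      float(p_frac[present].sum()), auc_vals, macro_auc,
                      curves, present)


def evaluate(model: Module, features: np.ndarray, labels: np.ndarray,
             class_names: list[str] | None = None) -> EvalReport:
    """Evaluate a trained head on features via its softmax probabilities."""
    proba = predict_proba(model, np.asarray(features, dtype=float))
    return evaluate_predictions(labels, proba.argmax(axis=1), scores=proba,
                                class_names=class_names,
                                n_classes=proba.shape[1])


# reference baseline hyperparameters; the SVM "radius parameter" 8 is the
# RBF kernel width sigma, so gamma = 1 / (2 sigma^2)
_SVM_PARAMS = dict(kernel="rbf", gamma=1.0 / (2.0 * 8.0 ** 2), C=20.0)
_RF_PARAMS = dict(max_depth=13, min_samples_leaf=20, min_samples_split=120,
                  max_features=7)


def baseline_classifiers(features: np.ndarray, labels: np.ndarray,
                         split: np.ndarray, which: str, seed: int = 0,
                         class_names: list[str] | None = None,
                         params: dict | None = None) -> EvalReport:
    """SVM (RBF) or random-forest baseline: fit on train, report on test."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    split = np.asarray(split)
    tr, te = split == "train", split == "test"
    if which == "svm":
        clf = SVC(**(params or _SVM_PARAMS), random_state=seed)
    elif which == "random_forest":
        clf = RandomForestClassifier(**(params or _RF_PARAMS), random_state=seed)
    else:
        raise ValueError(f"unknown baseline {which!r}")
    clf.fit(X[tr], y[tr])
    pred = clf.predict(X[te])
    if hasattr(clf, "predict_proba"):
        scores_full = np.zeros((te.sum(), int(y.max()) + 1))
        scores_full[:, clf.classes_] = clf.predict_proba(X[te])
        scores = scores_full
    else:
        df = clf.decision_function(X[te])
        scores_full = np.full((te.sum(), int(y.max()) + 1), -np.inf)
        scores_full[:, clf.classes_] = df if df.ndim == 2 \
            else np.column_stack([-df, df])
        scores = scores_full
    return evaluate_predictions(y[te], pred, scores=scores,
                                class_names=class_names,
                                n_classes=int(y.max()) + 1)


def compare_pipelines(feature_sources: dict[str, np.ndarray],
                      labels: np.ndarray, split: np.ndarray,
                      head_types: tuple[str, ...] = ("F", "FC", "FA"),
                      config: TrainConfig = TrainConfig(),
                      class_names: list[str] | None = None,
                      head_kwargs: dict | None = None) -> pd.DataFrame:
    """Train every (feature source x head) arm on a shared split and seed.

    Each source's features are standardized on its training split, every
    head is built from the same seed, and test-split metrics are tabulated
    (accuracy, macro P/R/F1, AP) — one row per arm.
    """
    labels = np.asarray(labels, dtype=int)
    split = np.asarray(split)
    n_classes = int(labels.max()) + 1
    rows = []
    for source, X in feature_sources.items():
        X = np.asarray(X, dtype=float)
        std = fit_standardizer(X[split == "train"])
        Xs = std.transform(X)
        for ht in head_types:
            cfg = HeadConfig(head_type=ht, input_dim=X.shape[1],
                             n_classes=n_classes, seed=config.seed,
                             **(head_kwargs or {}))
            model = build_head(cfg)
            model, _ = train_head(model, Xs, labels, split=split, config=config)
            rep = evaluate(model, Xs[split == "test"], labels[split == "test"],
                           class_names=class_names)
            rows.append({"source": source, "head": ht,
                         "accuracy": rep.accuracy,
                         "precision": rep.macro_precision,
                         "recall": rep.macro_recall,
                         "f1": rep.macro_f1, "ap": rep.ap})
    return pd.DataFrame(rows)
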