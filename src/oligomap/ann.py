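"""Binarized-expression ANN ensemble for cross-dataset cell-identity transfer.

The feature space is the union of variable genes of the source (labelled
atlas) and target datasets; expression is binarized to detected (UMI > 0) /
undetected.  Each ensemble member is a two-hidden-layer network (64 and 32
ReLU units, L1 penalty 0.001 on both hidden weight matrices) with a softmax
output over the source labels, trained with class-balanced resampled
minibatches (16 examples per class per step) under RMSprop on the softmax
cross-entropy.  Labels are split into stratified folds; model i trains on
all folds but i and validates on fold i, and target cells are labelled by
plurality vote over the ensemble, ties broken by the highest mean softmax
probability.

Everything here is plain NumPy so that training is bit-reproducible from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    precision_score,
    recall_score,
)

from .containers import CountMatrix
from .errors import ValidationError

LOG_CLIP = 1e-12


def build_feature_space(source_hvg, target_hvg) -> list:
    """Sorted, deduplicated union of source and target variable genes."""
    union = sorted(set(source_hvg) | set(target_hvg))
    if not union:
        raise ValidationError("empty feature-space union")
    return union


def binarize(m: CountMatrix, feature_space: list) -> np.ndarray:
    """Cells x features {0,1} detection matrix; absent features give 0 columns."""
    idx_map = m.gene_index()
    out = np.zeros((m.n_cells, len(feature_space)), dtype=np.float64)
    csc = sp.csc_matrix(m.values)
    for j, g in enumerate(feature_space):
        i = idx_map.get(g)
        if i is not None:
            col = np.asarray((csc[i] > 0).todense()).ravel()
            out[:, j] = col
    return out


@dataclass
class ANNConfig:
    hidden1: int = 64
    hidden2: int = 32
    l1_lambda: float = 0.001
    n_labels: int = 0  # set from the data


@dataclass
class TrainingConfig:
    n_folds: int = 5
    epochs: int = 100
    steps_per_epoch: int = 256
    per_class_per_step: int = 16
    learning_rate: float = 0.001
    rho: float = 0.9
    epsilon: float = 1.0e-7
    seed: int = 0


@dataclass
class ANNModel:
    """Weights of one ensemble member plus its training history."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    classes: list
    l1_lambda: float = 0.001
    history: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.W1.shape[0]

    def params(self) -> list:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]


def init_model(n_features: int, cfg: ANNConfig, classes, rng: np.random.Generator) -> ANNModel:
    """Glorot-uniform initialised network; biases start at zero."""

    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    k = len(classes)
    return ANNModel(
        W1=glorot(n_features, cfg.hidden1),
        b1=np.zeros(cfg.hidden1),
        W2=glorot(cfg.hidden1, cfg.hidden2),
        b2=np.zeros(cfg.hidden2),
        W3=glorot(cfg.hidden2, k),
        b3=np.zeros(k),
        classes=list(classes),
        l1_lambda=cfg.l1_lambda,
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(model: ANNModel, X: np.ndarray, return_hidden: bool = False):
    """p = softmax(relu(relu(X W1 + b1) W2 + b2) W3 + b3); rows sum to 1."""
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"input has {X.shape[1]} features, model expects {model.n_features}"
        )
    Z1 = X @ model.W1 + model.b1
    H1 = np.maximum(Z1, 0.0)
    Z2 = H1 @ model.W2 + model.b2
    H2 = np.maximum(Z2, 0.0)
    P = _softmax(H2 @ model.W3 + model.b3)
    if return_hidden:
        return P, (Z1, H1, Z2, H2)
    return P


def loss(model: ANNModel, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean cross-entropy plus L1 penalty on the two hidden weight matrices."""
    P = forward(model, X)
    ce = -np.mean(np.sum(Y * np.log(np.clip(P, LOG_CLIP, 1.0)), axis=1))
    l1 = model.l1_lambda * (np.abs(model.W1).sum() + np.abs(model.W2).sum())
    return float(ce + l1)


def gradients(model: ANNModel, X: np.ndarray, Y: np.ndarray) -> list:
    """Analytic gradient of :func:`loss` in the order of ``model.params()``."""
    B = X.shape[0]
    P, (Z1, H1, Z2, H2) = forward(model, X, return_hidden=True)
    dZ3 = (P - Y) / B
    gW3 = H2.T @ dZ3
    gb3 = dZ3.sum(axis=0)
    dH2 = dZ3 @ model.W3.T
    dZ2 = dH2 * (Z2 > 0)
    gW2 = H1.T @ dZ2 + model.l1_lambda * np.sign(model.W2)
    gb2 = dZ2.sum(axis=0)
    dH1 = dZ2 @ model.W2.T
    dZ1 = dH1 * (Z1 > 0)
    gW1 = X.T @ dZ1 + model.l1_lambda * np.sign(model.W1)
    gb1 = dZ1.sum(axis=0)
    return [gW1, gb1, gW2, gb2, gW3, gb3]


def one_hot(labels, classes) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(labels):
        Y[r, index[lab]] = 1.0
    return Y


def stratified_folds(labels, n_folds: int, seed: int = 0) -> np.ndarray:
    """Per-class even split into folds; deterministic given the seed."""
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for c in sorted(set(labels), key=str):
        idx = np.flatnonzero(labels == c)
        if len(idx) < n_folds:
            raise ValidationError(
                f"class {c!r} has {len(idx)} members, fewer than {n_folds} folds"
            )
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def balanced_batches(
    X: np.ndarray, labels, classes, per_class: int, rng: np.random.Generator
):
    """Infinite stream of class-balanced minibatches (sampled with replacement)."""
    labels = np.asarray(labels, dtype=object)
    pools = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) == 0:
            raise ValidationError(f"class {c!r} absent from training data")
        pools.append(idx)
    Y_all = one_hot(labels, classes)
    while True:
        take = np.concatenate([rng.choice(pool, size=per_class, replace=True) for pool in pools])
        yield X[take], Y_all[take]


def train_ann(
    X_train: np.ndarray,
    y_train,
    X_val: np.ndarray,
    y_val,
    ann_cfg: ANNConfig,
    train_cfg: TrainingConfig,
    classes=None,
) -> ANNModel:
    """Train one network with RMSprop on class-balanced batches.

    History records training loss and validation balanced accuracy per epoch.
    """
    if classes is None:
        classes = sorted(set(np.asarray(y_train, dtype=object)), key=str)
    rng = np.random.default_rng(train_cfg.seed)
    cfg = ANNConfig(
        hidden1=ann_cfg.hidden1,
        hidden2=ann_cfg.hidden2,
        l1_lambda=ann_cfg.l1_lambda,
        n_labels=len(classes),
    )
    model = init_model(X_train.shape[1], cfg, classes, rng)
    batches = balanced_batches(X_train, y_train, classes, train_cfg.per_class_per_step, rng)
    v = [np.zeros_like(p) for p in model.params()]
    history = {"train_loss": [], "val_balanced_accuracy": []}
    y_val = np.asarray(y_val, dtype=object)
    for _epoch in range(train_cfg.epochs):
        epoch_loss = 0.0
        for _step in range(train_cfg.steps_per_epoch):
            Xb, Yb = next(batches)
            grads = gradients(model, Xb, Yb)
            params = model.params()
            for i, (p, g) in enumerate(zip(params, grads)):
                v[i] = train_cfg.rho * v[i] + (1.0 - train_cfg.rho) * g * g
                p -= train_cfg.learning_rate * g / (np.sqrt(v[i]) + train_cfg.epsilon)
            epoch_loss += loss(model, Xb, Yb)
        mean_loss = epoch_loss / train_cfg.steps_per_epoch
        if not np.isfinite(mean_loss):
            raise ValidationError(f"non-finite training loss at epoch {_epoch}")
        history["train_loss"].append(mean_loss)
        if len(y_val):
            pred = predict_labels(model, X_val)
            history["val_balanced_accuracy"].append(
                float(balanced_accuracy_score(y_val, pred))
            )
    model.history = history
    return model


def predict_labels(model: ANNModel, X: np.ndarray) -> np.ndarray:
    P = forward(model, X)
    return np.asarray([model.classes[i] for i in P.argmax(axis=1)], dtype=object)


def train_ensemble(
    X: np.ndarray,
    labels,
    ann_cfg: ANNConfig,
    train_cfg: TrainingConfig,
) -> tuple[list, pd.DataFrame]:
    """Stratified-fold ensemble: model i trains on folds != i, validates on fold i.

    Returns the models and a per-fold validation metric table.
    """
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels), key=str)
    folds = stratified_folds(labels, train_cfg.n_folds, seed=train_cfg.seed)
    models = []
    rows = []
    for i in range(train_cfg.n_folds):
        tr = folds != i
        va = folds == i
        fold_cfg = TrainingConfig(**{**train_cfg.__dict__, "seed": train_cfg.seed + 1000 * (i + 1)})
        model = train_ann(
            X[tr], labels[tr], X[va], labels[va], ann_cfg, fold_cfg, classes=classes
        )
        pred = predict_labels(model, X[va])
        metrics = evaluate(pred, labels[va], classes=classes)
        rows.append(
            {
                "fold": i,
                "balanced_accuracy": metrics["balanced_accuracy"],
                "macro_precision": metrics["macro_precision"],
                "macro_recall": metrics["macro_recall"],
            }
        )
        models.append(model)
    return models, pd.DataFrame(rows)


def ensemble_predict(
    models: list, X_target: np.ndarray, confidence_threshold: float = 0.0
) -> pd.DataFrame:
    """Plurality vote over the ensemble; ties broken by mean softmax probability.

    Returns per-cell final label, per-label vote counts, mean maximum
    probability and a tie flag.  There is no reject option by default; a
    positive ``confidence_threshold`` relabels cells whose mean maximum
    probability falls below it as ``"unassigned"``.
    """
    if not models:
        raise ValidationError("empty model list")
    classes = models[0].classes
    for m in models:
        if m.classes != classes or m.n_features != models[0].n_features:
            raise ValidationError("ensemble members disagree on feature space or labels")
    n = X_target.shape[0]
    k = len(classes)
    votes = np.zeros((n, k), dtype=int)
    mean_p = np.zeros((n, k))
    for m in models:
        P = forward(m, X_target)
        votes[np.arange(n), P.argmax(axis=1)] += 1
        mean_p += P
    mean_p /= len(models)
    final = np.empty(n, dtype=object)
    tie = np.zeros(n, dtype=bool)
    for i in range(n):
        top = votes[i].max()
        winners = np.flatnonzero(votes[i] == top)
        if len(winners) > 1:
            tie[i] = True
            winners = winners[np.argsort(-mean_p[i, winners], kind="stable")]
        final[i] = classes[winners[0]]
    max_p = mean_p.max(axis=1)
    if confidence_threshold > 0:
        final = np.where(max_p < confidence_threshold, "unassigned", final)
    out = pd.DataFrame(
        {
            "final_label": final,
            "tie_broken": tie,
            "mean_max_probability": max_p,
        }
    )
    for j, c in enumerate(classes):
        out[f"votes_{c}"] = votes[:, j]
    return out


def evaluate(pred_labels, true_labels, classes=None) -> dict:
    """Balanced accuracy, macro precision/recall and the confusion matrix."""
    pred = np.asarray(pred_labels, dtype=object)
    true = np.asarray(true_labels, dtype=object)
    if len(pred) == 0 or len(pred) != len(true):
        raise ValidationError("evaluate requires equal-length non-empty label vectors")
    if classes is None:
        classes = sorted(set(true) | set(pred), key=str)
    cm = confusion_matrix(true, pred, labels=classes)
    return {
        "balanced_accuracy": float(balanced_accuracy_score(true, pred)),
        "macro_precision": float(
            precision_score(true, pred, labels=classes, average="macro", zero_division=0)
        ),
        "macro_recall": float(
            recall_score(true, pred, labels=classes, average="macro", zero_division=0)
        ),
        "confusion_matrix": pd.DataFrame(cm, index=classes, columns=classes),
    }


def save_ensemble(models: list, feature_space: list, path) -> None:
    """Persist ensemble weights + feature space as a portable .npz archive."""
    arrays = {"n_models": np.array(len(models))}
    arrays["feature_space"] = np.asarray(feature_space, dtype=str)
    arrays["classes"] = np.asarray(models[0].classes, dtype=str)
    arrays["l1_lambda"] = np.array(models[0].l1_lambda)
    for i, m in enumerate(models):
        for name, p in zip(("W1", "b1", "W2", "b2", "W3", "b3"), m.params()):
            arrays[f"m{i}_{name}"] = p
    np.savez(path, **arrays)


def load_ensemble(path) -> tuple[list, list]:
    data = np.load(path)
    n = int(data["n_models"])
    classes = list(data["classes"])
    models = []
    for i in range(n):
        models.append(
            ANNModel(
                W1=data[f"m{i}_W1"],
                b1=data[f"m{i}_b1"],
                W2=data[f"m{i}_W2"],
                b2=data[f"m{i}_b2"],
                W3=data[f"m{i}_W3"],
                b3=data[f"m{i}_b3"],
                classes=classes,
                l1_lambda=float(data["l1_lambda"]),
            )
        )
    return models, list(data["feature_space"])
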