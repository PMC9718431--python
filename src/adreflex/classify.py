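"""Feed-forward neural classifier for AD detection and stimulus discrimination.

The network is five layers in total — an input layer of the five selected
features, three ReLU hidden layers (default 32/16/8) and an output layer with
one logistic unit for the binary AD-vs-non-AD task or one softmax unit per
class for the four-way stimulus task.  Data are split into stratified
train (70%) / validation (15%) / test (15%) sets; the validation set drives
early stopping, the test set is only used for the final report, and
stratified 10-fold cross-validation gauges stability.

Optimization uses scikit-learn's MLPClassifier driven by an explicit
``partial_fit`` loop so that early stopping monitors the held-out validation
split rather than an internal one.  Trained weights are frozen into a plain
:class:`MLPModel` (pure numpy forward pass) which serializes to a documented
JSON bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import (accuracy_score, confusion_matrix, f1_score,
                             log_loss, precision_score, recall_score,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

__all__ = [
    "TrainConfig",
    "EvalReport",
    "MLPModel",
    "split_stratified",
    "train_model",
    "evaluate",
    "cross_validate",
    "most_confused_class",
]


@dataclass(frozen=True)
class TrainConfig:
    hidden_layers: tuple[int, ...] = (32, 16, 8)
    train_frac: float = 0.70
    test_frac: float = 0.15
    val_frac: float = 0.15
    cv_folds: int = 10
    seed: int = 0
    task: str = "binary"              # "binary" | "multiclass"
    max_epochs: int = 300
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 20
    tol: float = 1e-5
    class_weight: str | None = None   # None (protocol default) | "balanced"

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.test_frac + self.val_frac - 1.0) > 1e-9:
            raise ValueError("train/test/val fractions must sum to 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.task not in ("binary", "multiclass"):
            raise ValueError("task must be 'binary' or 'multiclass'")


@dataclass
class EvalReport:
    """Classifier metrics; confusion rows are true classes, columns predictions."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    auc_roc: float | None
    confusion: np.ndarray
    labels: list[str]
    per_class_precision: dict[str, float]
    per_class_recall: dict[str, float]
    cv_mean: float | None = None
    cv_sd: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        return d


class MLPModel:
    """Frozen ReLU feed-forward network (numpy forward pass, JSON-serializable)."""

    def __init__(self, coefs: list[np.ndarray], intercepts: list[np.ndarray],
                 classes: np.ndarray, task: str, feature_names: list[str] | None = None):
        self.coefs = [np.asarray(c, dtype=float) for c in coefs]
        self.intercepts = [np.asarray(b, dtype=float) for b in intercepts]
        self.classes = np.asarray(classes)
        self.task = task
        self.feature_names = list(feature_names or [])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        z = h @ self.coefs[-1] + self.intercepts[-1]
        if z.shape[1] == 1:  # single logistic output unit
            p1 = 1.0 / (1.0 + np.exp(-z[:, 0]))
            return np.column_stack([1.0 - p1, p1])
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        if self.task == "binary":
            return self.classes[(proba[:, 1] >= 0.5).astype(int)]
        return self.classes[np.argmax(proba, axis=1)]

    def to_json(self) -> str:
        return json.dumps({
            "task": self.task,
            "classes": self.classes.tolist(),
            "feature_names": self.feature_names,
            "layer_sizes": [self.coefs[0].shape[0]] + [c.shape[1] for c in self.coefs],
            "coefs": [c.tolist() for c in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        return cls(coefs=[np.array(c) for c in d["coefs"]],
                   intercepts=[np.array(b) for b in d["intercepts"]],
                   classes=np.array(d["classes"]), task=d["task"],
                   feature_names=d["feature_names"])


def split_stratified(labels: np.ndarray, config: TrainConfig
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified 70/15/15 index partition (exact total sizes, seeded).

    Class proportions in each split are within one sample of exact
    stratification; every class needs at least 3 members.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 3):
        bad = classes[counts < 3]
        raise ValueError(f"classes {bad.tolist()} have <3 windows; cannot stratify into 3 sets")
    idx = np.arange(y.size)
    n_test = int(round(config.test_frac * y.size))
    n_val = int(round(config.val_frac * y.size))
    rest, test = train_test_split(idx, test_size=n_test, stratify=y,
                                  random_state=config.seed, shuffle=True)
    rest_sorted = np.sort(rest)
    train, val = train_test_split(rest_sorted, test_size=n_val, stratify=y[rest_sorted],
                                  random_state=config.seed + 1, shuffle=True)
    return np.sort(train), np.sort(val), np.sort(test)


def _check_finite(X: np.ndarray) -> None:
    bad = np.flatnonzero(~np.isfinite(np.asarray(X, dtype=float)).all(axis=1))
    if bad.size:
        raise ValueError(f"non-finite feature values in windows {bad[:20].tolist()}"
                         + (" ..." if bad.size > 20 else ""))


def train_model(X_train: np.ndarray, y_train: np.ndarray,
                X_val: np.ndarray, y_val: np.ndarray,
                config: TrainConfig,
                feature_names: list[str] | None = None) -> MLPModel:
    """Train the network with early stopping on the validation split."""
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    _check_finite(X_train)
    _check_finite(X_val)
    y_train = np.asarray(y_train)
    classes = np.unique(np.concatenate([y_train, np.asarray(y_val)]))

    clf = MLPClassifier(hidden_layer_sizes=tuple(config.hidden_layers),
                        activation="relu", solver="adam",
                        learning_rate_init=config.learning_rate,
                        random_state=config.seed, max_iter=1)
    rng = np.random.default_rng(config.seed)
    if config.class_weight == "balanced":
        # no sample_weight in partial_fit: balance by seeded oversampling instead
        target = int(np.max([np.sum(y_train == c) for c in classes]))
        parts = []
        for c in classes:
            idx = np.flatnonzero(y_train == c)
            extra = rng.choice(idx, size=target - idx.size, replace=True) if idx.size < target else []
            parts.append(np.concatenate([idx, np.asarray(extra, dtype=int)]))
        resampled = np.concatenate(parts)
        X_train = X_train[resampled]
        y_train = y_train[resampled]
    n = X_train.shape[0]
    best_loss = np.inf
    best_weights = None
    stale = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings from 1-step fits
        for _epoch in range(config.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                batch = order[start:start + config.batch_size]
                clf.partial_fit(X_train[batch], y_train[batch], classes=classes)
            val_loss = log_loss(y_val, clf.predict_proba(X_val), labels=classes)
            if val_loss < best_loss - config.tol:
                best_loss = val_loss
                best_weights = ([c.copy() for c in clf.coefs_],
                                [b.copy() for b in clf.intercepts_])
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    coefs, intercepts = best_weights if best_weights else (clf.coefs_, clf.intercepts_)
    return MLPModel(coefs, intercepts, classes, config.task, feature_names)


def evaluate(model: MLPModel, X_test: np.ndarray, y_test: np.ndarray,
             task: str | None = None) -> EvalReport:
    """Metrics on a held-out set: accuracy, sensitivity/specificity, F1, AUC-ROC,
    confusion matrix and per-class precision/recall."""
    task = task or model.task
    X_test = np.asarray(X_test, dtype=float)
    _check_finite(X_test)
    y_test = np.asarray(y_test)
    labels = list(model.classes)
    pred = model.predict(X_test)
    cm = confusion_matrix(y_test, pred, labels=labels)
    acc = accuracy_score(y_test, pred)
    prec = precision_score(y_test, pred, labels=labels, average=None, zero_division=0)
    rec = recall_score(y_test, pred, labels=labels, average=None, zero_division=0)
    per_prec = {c: float(p) for c, p in zip(labels, prec)}
    per_rec = {c: float(r) for c, r in zip(labels, rec)}

    flags: list[str] = []
    sens = spec = f1 = auc = None
    if task == "binary":
        pos = "ad" if "ad" in labels else labels[1]
        present = np.unique(y_test)
        if present.size < 2:
            flags.append("single-class test set: sensitivity/specificity/AUC undefined")
        else:
            neg = [c for c in labels if c != pos][0]
            sens = per_rec[pos]
            spec = per_rec[neg]
            f1 = float(f1_score(y_test, pred, pos_label=pos, zero_division=0))
            proba = model.predict_proba(X_test)[:, list(model.classes).index(pos)]
            auc = float(roc_auc_score((y_test == pos).astype(int), proba))
    else:
        f1 = float(f1_score(y_test, pred, labels=labels, average="weighted", zero_division=0))
    return EvalReport(accuracy=float(acc), sensitivity=sens, specificity=spec,
                      f1=f1, auc_roc=auc, confusion=cm, labels=labels,
                      per_class_precision=per_prec, per_class_recall=per_rec,
                      flags=flags)


def cross_validate(X: np.ndarray, y: np.ndarray, config: TrainConfig) -> dict:
    """Stratified k-fold CV; returns mean/SD of accuracy and a pooled confusion.

    Within each fold, 15% of the training portion is carved out (stratified)
    for early stopping, matching the main protocol.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < config.cv_folds):
        raise ValueError(f"every class needs >= cv_folds={config.cv_folds} windows")
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    labels = list(classes)
    accs = []
    pooled = np.zeros((len(labels), len(labels)), dtype=int)
    fold_indices = []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        tr_in, tr_val = train_test_split(tr, test_size=0.15, stratify=y[tr],
                                         random_state=config.seed + 100 + k, shuffle=True)
        fold_cfg = TrainConfig(**{**asdict(config), "seed": config.seed + 100 + k})
        model = train_model(X[tr_in], y[tr_in], X[tr_val], y[tr_val], fold_cfg)
        pred = model.predict(X[te])
        accs.append(accuracy_score(y[te], pred))
        pooled += confusion_matrix(y[te], pred, labels=labels)
        fold_indices.append(np.sort(te))
    return {
        "cv_mean": float(np.mean(accs)),
        "cv_sd": float(np.std(accs, ddof=1)),
        "fold_accuracies": [float(a) for a in accs],
        "confusion": pooled,
        "labels": [str(c) for c in labels],
        "fold_test_indices": fold_indices,
    }


def most_confused_class(confusion: np.ndarray, labels: list[str],
                        baseline: str = "none") -> str:
    """True class contributing the most false-detection errors.

    Counts, for each true class, the samples misclassified as an *event* class
    (any predicted class other than ``baseline``): these are the errors that
    raise false alarms.  Missed detections (event windows predicted as
    baseline) are accounted by per-class sensitivity instead.  When the
    baseline label is absent, plain off-diagonal row sums are used.
    """
    cm = np.asarray(confusion)
    if baseline in labels:
        b = labels.index(baseline)
        fp = np.array([sum(cm[i, j] for j in range(len(labels)) if j != i and j != b)
                       for i in range(len(labels))])
    else:
        fp = cm.sum(axis=1) - np.diag(cm)
    return labels[int(np.argmax(fp))]
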