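"""Two-layer feedforward gesture classification.

The model is a pattern-recognition network with one hidden layer of logistic
sigmoid units and a softmax output over the six movement classes, trained by
Adam on the cross-entropy loss with patience-based early stopping monitored
on a held-out validation partition.  The interface follows the fitted-model
convention: :class:`GestureClassifier` is built from a feature matrix and a
configuration, and its :meth:`~GestureClassifier.fit` returns a
:class:`GestureResults` object carrying per-partition confusion matrices,
per-class sensitivity and precision, the training history and a
``summary()`` table.

Inputs are min-max scaled to [-1, 1] with scaling parameters fitted on the
training partition only.  All randomness (splits, weight initialisation,
mini-batch order) derives from the configuration seed, so identical
configurations reproduce identical fits.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, log_loss
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import MinMaxScaler

HIDDEN_SIZES = (34, 49, 63)


class TrainingError(RuntimeError):
    """Optimization produced a non-finite loss or could not proceed."""


@dataclass(frozen=True)
class NetConfig:
    """Configuration of the pattern-recognition network and its training run."""

    hidden_size: int = 49
    split_fractions: tuple = (0.70, 0.15, 0.15)
    max_epochs: int = 1000
    patience: int = 6
    batch_size: int = 32
    learning_rate: float = 1e-3
    alpha: float = 1e-4
    scale_inputs: bool = True
    tol: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        f = self.split_fractions
        if len(f) != 3 or any(x < 0 for x in f) or f[0] <= 0 or abs(sum(f) - 1) > 1e-9:
            raise ValueError("split_fractions must be non-negative, train > 0, and sum to 1")
        if self.max_epochs < 1 or self.patience < 0:
            raise ValueError("max_epochs >= 1 and patience >= 0 required")


def split_dataset(y, config: NetConfig | None = None) -> dict:
    """Stratified, seeded train/validation/test partition of instance indices.

    Partition sizes are ``round(n * fraction)`` for test and validation, the
    remainder training; class proportions are preserved within each partition.
    Returns a dict of sorted index arrays; the partitions are disjoint and
    exhaustive.
    """
    config = config or NetConfig()
    y = np.asarray(y)
    if y.ndim == 2:
        y = np.argmax(y, axis=1)
    n = y.size
    idx = np.arange(n)
    n_test = int(round(n * config.split_fractions[2]))
    n_val = int(round(n * config.split_fractions[1]))
    try:
        if n_test > 0:
            rest, test = train_test_split(idx, test_size=n_test, stratify=y,
                                          random_state=config.seed)
        else:
            rest, test = idx, np.array([], dtype=int)
        if n_val > 0:
            train, val = train_test_split(rest, test_size=n_val, stratify=y[rest],
                                          random_state=config.seed + 1)
        else:
            train, val = rest, np.array([], dtype=int)
    except ValueError as exc:
        raise ValueError(f"class too small to stratify: {exc}") from exc
    return {"train": np.sort(train), "validation": np.sort(val), "test": np.sort(test)}


@dataclass
class ConfusionReport:
    """Confusion matrix of one partition with the derived per-class metrics."""

    partition: str
    confusion: np.ndarray
    accuracy: float
    sensitivity: np.ndarray
    precision: np.ndarray
    n: int

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int, partition: str) -> "ConfusionReport":
        cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
        total = cm.sum()
        accuracy = float(np.trace(cm) / total) if total else 0.0
        row = cm.sum(axis=1)
        col = cm.sum(axis=0)
        sensitivity = np.divide(np.diag(cm), row, out=np.zeros(n_classes, float), where=row > 0)
        precision = np.divide(np.diag(cm), col, out=np.zeros(n_classes, float), where=col > 0)
        return cls(partition, cm, accuracy, sensitivity, precision, int(total))


def evaluate(predict, X, y, partitions: dict, n_classes: int) -> dict:
    """Confusion reports for each partition plus the pooled 'overall' report."""
    reports = {}
    all_idx = np.concatenate([partitions[k] for k in ("train", "validation", "test")])
    for name, idx in {**partitions, "overall": all_idx}.items():
        if len(idx) == 0:
            continue
        reports[name] = ConfusionReport.from_predictions(y[idx], predict(X[idx]),
                                                         n_classes, name)
    return reports


class GestureClassifier:
    """Feedforward-network model over a movement-feature matrix.

    Parameters
    ----------
    X, y : feature matrix (instances x features) and integer or one-hot labels.
    config : NetConfig, optional
    class_names : names of the label classes, in label order.
    """

    def __init__(self, X, y, config: NetConfig | None = None, class_names=None):
        self.X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if y.ndim == 2:
            y = np.argmax(y, axis=1)
        self.y = y.astype(int)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on the number of instances")
        self.config = config or NetConfig()
        self.n_classes = int(self.y.max()) + 1 if class_names is None else len(class_names)
        self.class_names = tuple(class_names) if class_names is not None else tuple(
            f"C{i}" for i in range(self.n_classes))

    @classmethod
    def from_dataset(cls, dataset, config: NetConfig | None = None) -> "GestureClassifier":
        """Build the model from a :class:`~semgband.features.DatasetMatrix`."""
        return cls(dataset.X, dataset.y, config=config, class_names=dataset.class_names)

    def fit(self, partitions: dict | None = None) -> "GestureResults":
        """Train the network and return a results object.

        Training runs mini-batch Adam epochs over the training partition and
        stops after ``patience`` consecutive epochs without validation-loss
        improvement (or at ``max_epochs``); the weights of the best validation
        epoch are restored.
        """
        cfg = self.config
        partitions = partitions or split_dataset(self.y, cfg)
        train_idx = partitions["train"]
        val_idx = partitions["validation"]
        if cfg.patience > 0 and len(val_idx) == 0:
            raise ValueError("patience-based early stopping requires a non-empty "
                             "validation partition (got split_fractions with val = 0)")

        scaler = None
        Xs = self.X
        if cfg.scale_inputs:
            scaler = MinMaxScaler(feature_range=(-1, 1))
            scaler.fit(self.X[train_idx])
            Xs = scaler.transform(self.X)

        classes = np.arange(self.n_classes)
        clf = MLPClassifier(hidden_layer_sizes=(cfg.hidden_size,), activation="logistic",
                            solver="adam", alpha=cfg.alpha,
                            learning_rate_init=cfg.learning_rate, random_state=cfg.seed)
        rng = np.random.default_rng(cfg.seed)
        Xtr, ytr = Xs[train_idx], self.y[train_idx]
        bs = min(cfg.batch_size, len(train_idx))

        best_loss = np.inf
        best_params = None
        failures = 0
        history = []
        t0 = time.perf_counter()
        epochs_run = 0
        for _ in range(cfg.max_epochs):
            order = rng.permutation(len(train_idx))
            for start in range(0, len(order), bs):
                sel = order[start:start + bs]
                clf.partial_fit(Xtr[sel], ytr[sel], classes=classes)
            epochs_run += 1
            if len(val_idx):
                loss = log_loss(self.y[val_idx], clf.predict_proba(Xs[val_idx]), labels=classes)
            else:
                loss = log_loss(ytr, clf.predict_proba(Xtr), labels=classes)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite validation loss at epoch {epochs_run}")
            history.append(float(loss))
            if loss < best_loss - cfg.tol:
                best_loss = loss
                best_params = ([w.copy() for w in clf.coefs_],
                               [b.copy() for b in clf.intercepts_])
                failures = 0
            else:
                failures += 1
                if cfg.patience and failures >= cfg.patience:
                    break
        train_time = time.perf_counter() - t0
        if best_params is not None:
            clf.coefs_, clf.intercepts_ = best_params

        reports = evaluate(lambda A: clf.predict(A), Xs, self.y, partitions, self.n_classes)
        return GestureResults(config=cfg, class_names=self.class_names,
                              partitions=partitions, reports=reports,
                              epochs_run=epochs_run, train_time_s=train_time,
                              history=history, _clf=clf, _scaler=scaler)


@dataclass
class GestureResults:
    """Fitted network plus its evaluation: the return value of ``fit()``."""

    config: NetConfig
    class_names: tuple
    partitions: dict
    reports: dict
    epochs_run: int
    train_time_s: float
    history: list
    _clf: MLPClassifier = field(repr=False, default=None)
    _scaler: MinMaxScaler | None = field(repr=False, default=None)

    def _transform(self, X):
        X = np.asarray(X, dtype=float)
        return self._scaler.transform(X) if self._scaler is not None else X

    def predict(self, X) -> np.ndarray:
        return self._clf.predict(self._transform(X))

    def predict_proba(self, X) -> np.ndarray:
        return self._clf.predict_proba(self._transform(X))

    def accuracy(self, partition: str = "test") -> float:
        return self.reports[partition].accuracy

    def summary(self) -> str:
        """Human-readable report: per-partition accuracy and test per-class metrics."""
        lines = [f"Gesture classifier (hidden={self.config.hidden_size}, "
                 f"epochs={self.epochs_run}, train time {self.train_time_s:.1f} s)"]
        part = pd.DataFrame({
            name: {"n": rep.n, "accuracy %": 100 * rep.accuracy}
            for name, rep in self.reports.items()
        }).T
        part["n"] = part["n"].astype(int)
        lines.append(part.to_string(float_format=lambda v: f"{v:.1f}"))
        if "test" in self.reports:
            rep = self.reports["test"]
            cls_table = pd.DataFrame({
                "sensitivity %": 100 * rep.sensitivity,
                "precision %": 100 * rep.precision,
            }, index=list(self.class_names))
            lines.append("test partition per-class metrics:")
            lines.append(cls_table.to_string(float_format=lambda v: f"{v:.1f}"))
        return "\n".join(lines)

    def save(self, path) -> Path:
        """Write a portable text weights file (JSON: dims, weights, scaling, reports)."""
        path = Path(path)
        payload = {
            "config": {**asdict(self.config), "split_fractions": list(self.config.split_fractions)},
            "class_names": list(self.class_names),
            "coefs": [w.tolist() for w in self._clf.coefs_],
            "intercepts": [b.tolist() for b in self._clf.intercepts_],
            "scaler": None if self._scaler is None else {
                "scale": self._scaler.scale_.tolist(), "min": self._scaler.min_.tolist()},
            "epochs_run": self.epochs_run,
            "train_time_s": self.train_time_s,
            "reports": {
                name: {"confusion": rep.confusion.tolist(), "accuracy": rep.accuracy,
                       "sensitivity": rep.sensitivity.tolist(),
                       "precision": rep.precision.tolist(), "n": rep.n}
                for name, rep in self.reports.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path

    def plot_confusion(self, partition: str = "test", ax=None):
        """Render the partition's confusion matrix as an annotated heat map."""
        import matplotlib.pyplot as plt

        rep = self.reports[partition]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4.5))
        return _draw_confusion(ax, rep.confusion, self.class_names,
                               f"{partition} (accuracy {100 * rep.accuracy:.1f}%)")


def _draw_confusion(ax, cm, class_names, title):
    cm = np.asarray(cm)
    ax.imshow(cm, cmap="Blues")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center", fontsize=8)
    ax.set_xticks(range(len(class_names)), class_names, fontsize=8)
    ax.set_yticks(range(len(class_names)), class_names, fontsize=8)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title, fontsize=9)
    return ax


class _LoadedNetwork:
    """Forward-only network reconstructed from a saved weights file."""

    def __init__(self, payload: dict):
        self.class_names = tuple(payload["class_names"])
        self.coefs = [np.asarray(w) for w in payload["coefs"]]
        self.intercepts = [np.asarray(b) for b in payload["intercepts"]]
        self.scaler = payload.get("scaler")
        self.reports = payload.get("reports", {})

    def predict_proba(self, X) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        if self.scaler is not None:
            a = a * np.asarray(self.scaler["scale"]) + np.asarray(self.scaler["min"])
        a = 1.0 / (1.0 + np.exp(-(a @ self.coefs[0] + self.intercepts[0])))
        z = a @ self.coefs[1] + self.intercepts[1]
        if z.ndim == 2 and z.shape[1] > 1:
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        p = 1.0 / (1.0 + np.exp(-z.ravel()))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def load_network(path) -> _LoadedNetwork:
    """Load a weights file written by :meth:`GestureResults.save`."""
    with open(path) as fh:
        return _LoadedNetwork(json.load(fh))


def run_experiment_grid(segments, modes=("full", "average"), hidden_sizes=HIDDEN_SIZES,
                        config: NetConfig | None = None, seed: int | None = None):
    """Train the full mode x hidden-size grid and tabulate accuracies.

    Returns ``(table, results)``: a DataFrame with one row per grid cell
    (train/validation/test/overall accuracy, epochs, wall time) mirroring the
    study's summary tables, and the per-cell results objects keyed by
    ``(mode, hidden)``.
    """
    from .features import assemble_matrix

    cfg = config or NetConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rows, results = [], {}
    for mode in modes:
        ds = assemble_matrix(segments, mode=mode)
        for h in hidden_sizes:
            model = GestureClassifier.from_dataset(ds, replace(cfg, hidden_size=h))
            res = model.fit()
            rows.append({
                "mode": mode, "hidden": h,
                "train %": 100 * res.accuracy("train"),
                "validation %": 100 * res.accuracy("validation"),
                "test %": 100 * res.accuracy("test"),
                "overall %": 100 * res.accuracy("overall"),
                "epochs": res.epochs_run,
                "time_s": res.train_time_s,
            })
            results[(mode, h)] = res
    return pd.DataFrame(rows), results
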