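"""MLP grade classification and confusion-matrix evaluation.

The neural route to grading: standardize the measured feature vectors,
one-hot encode the four grade labels, and train a small feed-forward
network by gradient back-propagation (scikit-learn's ``MLPClassifier``
with seeded weights, so training is reproducible).  Any grader — network
or Q-score — is evaluated through a 4x4 confusion matrix (rows = real
class, columns = anticipated class) reduced one-vs-rest per grade:

    sensitivity = TP/(TP+FN) * 100
    specificity = TN/(TN+FP) * 100

and overall accuracy is the micro average trace/total * 100.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .color import FeatureVector

__all__ = [
    "GRADES",
    "MLP_FEATURE_COLUMNS",
    "MLPConfig",
    "FeatureScaler",
    "MLPModel",
    "ConfusionMatrix",
    "feature_matrix",
    "build_vectors",
    "train_mlp",
    "predict_mlp",
    "confusion_matrix",
    "class_sensitivity",
    "class_specificity",
    "overall_accuracy",
    "evaluation_report",
    "train_test_split_stratified",
]

GRADES = (1, 2, 3, 4)

#: every measured quantity feeds the network (raw channels, chromaticities,
#: HSI, size, weight); constant columns are neutralized by the scaler floor
MLP_FEATURE_COLUMNS = ("R", "G", "B", "r", "g", "b", "H", "S", "I", "size_px", "weight_g")


@dataclass(frozen=True)
class MLPConfig:
    """Network architecture and training hyperparameters."""

    hidden_sizes: tuple[int, ...] = (10,)
    activation: str = "logistic"
    learning_rate: float = 0.01
    epochs: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) < 1 or any(h < 1 for h in self.hidden_sizes):
            raise ValueError(f"need at least one positive hidden layer, got {self.hidden_sizes}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class FeatureScaler:
    """Per-column z-score standardization with the sd floored for constants."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, sd_floor: float = 1e-8) -> "FeatureScaler":
        X = np.asarray(X, dtype=np.float64)
        sd = X.std(axis=0)
        return cls(mean=X.mean(axis=0), sd=np.maximum(sd, sd_floor))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.mean.size:
            raise ValueError(f"expected {self.mean.size} feature columns, got {X.shape[1]}")
        return (X - self.mean) / self.sd


def feature_matrix(features: Sequence[FeatureVector]) -> np.ndarray:
    """Raw (n, 11) design matrix in ``MLP_FEATURE_COLUMNS`` order."""
    rows = [fv.as_row() for fv in features]
    return np.array([[row[c] for c in MLP_FEATURE_COLUMNS] for row in rows], dtype=np.float64)


def build_vectors(
    features: Sequence[FeatureVector],
    labels: Sequence[int],
    scaler: FeatureScaler | None = None,
) -> tuple[np.ndarray, np.ndarray, FeatureScaler]:
    """Standardized training matrix and one-hot target matrix.

    A scaler fitted elsewhere (the training split) can be passed to
    standardize held-out data consistently.
    """
    if len(features) != len(labels):
        raise ValueError(f"{len(features)} feature vectors vs {len(labels)} labels")
    labels = np.asarray(labels, dtype=np.int64)
    if not np.isin(labels, GRADES).all():
        raise ValueError(f"labels must be grades 1-4, got {sorted(set(labels.tolist()))}")
    X = feature_matrix(features)
    if scaler is None:
        scaler = FeatureScaler.fit(X)
    T = np.zeros((len(labels), 4), dtype=np.float64)
    T[np.arange(len(labels)), labels - 1] = 1.0
    return scaler.transform(X), T, scaler


@dataclass
class MLPModel:
    """Trained network plus the scaler that standardized its inputs."""

    clf: MLPClassifier
    config: MLPConfig
    scaler: FeatureScaler | None = None
    n_features: int = 0

    def save(self, path: str | Path) -> None:
        doc = {
            "config": {
                "hidden_sizes": list(self.config.hidden_sizes),
                "activation": self.config.activation,
                "learning_rate": self.config.learning_rate,
                "epochs": self.config.epochs,
                "rng_seed": self.config.rng_seed,
            },
            "n_features": self.n_features,
            "coefs": [w.tolist() for w in self.clf.coefs_],
            "intercepts": [b.tolist() for b in self.clf.intercepts_],
            "scaler": None
            if self.scaler is None
            else {"mean": self.scaler.mean.tolist(), "sd": self.scaler.sd.tolist()},
        }
        Path(path).write_text(json.dumps(doc) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        doc = json.loads(Path(path).read_text())
        config = MLPConfig(
            hidden_sizes=tuple(doc["config"]["hidden_sizes"]),
            activation=doc["config"]["activation"],
            learning_rate=doc["config"]["learning_rate"],
            epochs=doc["config"]["epochs"],
            rng_seed=doc["config"]["rng_seed"],
        )
        clf = _make_classifier(config)
        clf.coefs_ = [np.array(w) for w in doc["coefs"]]
        clf.intercepts_ = [np.array(b) for b in doc["intercepts"]]
        clf.n_layers_ = len(clf.coefs_) + 1
        clf.n_outputs_ = 4
        clf.classes_ = np.array(GRADES)
        clf.out_activation_ = "softmax"
        clf.n_features_in_ = doc["n_features"]
        from sklearn.preprocessing import LabelBinarizer

        lb = LabelBinarizer()
        lb.fit(np.array(GRADES))
        clf._label_binarizer = lb
        scaler = None
        if doc["scaler"] is not None:
            scaler = FeatureScaler(np.array(doc["scaler"]["mean"]), np.array(doc["scaler"]["sd"]))
        return cls(clf=clf, config=config, scaler=scaler, n_features=doc["n_features"])


def _make_classifier(config: MLPConfig) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_sizes),
        activation=config.activation,
        solver="sgd",
        momentum=0.9,
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        n_iter_no_change=config.epochs,  # train the full epoch budget
        tol=0.0,
        random_state=config.rng_seed,
        shuffle=True,
    )


def train_mlp(X: np.ndarray, T: np.ndarray, config: MLPConfig | None = None) -> MLPModel:
    """Back-propagation training on a standardized matrix and one-hot targets.

    Identical (data, config, seed) gives an identical model.
    """
    config = config or MLPConfig()
    X = np.asarray(X, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    if X.shape[0] != T.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but T has {T.shape[0]}")
    if np.isnan(X).any():
        raise ValueError("training matrix contains NaNs")
    if T.shape[1] != 4 or not np.allclose(T.sum(axis=1), 1.0):
        raise ValueError("targets must be one-hot over the four grades")
    labels = T.argmax(axis=1) + 1
    clf = _make_classifier(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, labels)
    return MLPModel(clf=clf, config=config, n_features=X.shape[1])


def predict_mlp(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Grades 1-4 by argmax over the four output units."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"expected (n, {model.n_features}) input, got {X.shape}")
    proba = model.clf.predict_proba(X)
    return np.asarray(GRADES)[proba.argmax(axis=1)]


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows = real class, columns = anticipated class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValueError(f"confusion matrix must be 4x4, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=list(GRADES), columns=list(GRADES))
        df.index.name = "grade"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        if df.shape != (4, 4):
            raise ValueError(f"expected a 4x4 confusion table, got {df.shape} in {path}")
        return cls(df.to_numpy())


def confusion_matrix(true: Sequence[int], predicted: Sequence[int]) -> ConfusionMatrix:
    """counts[i][j] = number of samples with real grade i predicted as j."""
    true = np.asarray(true, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if true.shape != predicted.shape:
        raise ValueError(f"{true.size} true labels vs {predicted.size} predictions")
    for name, arr in (("true", true), ("predicted", predicted)):
        if not np.isin(arr, GRADES).all():
            raise ValueError(f"{name} labels must be grades 1-4")
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (true - 1, predicted - 1), 1)
    return ConfusionMatrix(counts)


def _ovr(cm: ConfusionMatrix, grade: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, TN, FN) for a grade."""
    if grade not in GRADES:
        raise ValueError(f"grade must be 1-4, got {grade}")
    i = grade - 1
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fn - fp
    return tp, fp, tn, fn


def class_sensitivity(cm: ConfusionMatrix, grade: int) -> float:
    """TP/(TP+FN) * 100 for one grade (its recall, in percent)."""
    tp, _, _, fn = _ovr(cm, grade)
    if tp + fn == 0:
        raise ValueError(f"no samples of grade {grade}: sensitivity undefined")
    return 100.0 * tp / (tp + fn)


def class_specificity(cm: ConfusionMatrix, grade: int) -> float:
    """TN/(TN+FP) * 100 for one grade (in percent)."""
    tp, fp, tn, fn = _ovr(cm, grade)
    if tn + fp == 0:
        raise ValueError(f"all samples are grade {grade}: specificity undefined")
    return 100.0 * tn / (tn + fp)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Micro-averaged accuracy: trace/total * 100."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def evaluation_report(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-grade sensitivity/specificity and overall accuracy in one table."""
    rows = [
        {
            "grade": g,
            "n": int(cm.counts[g - 1].sum()),
            "sensitivity_pct": class_sensitivity(cm, g),
            "specificity_pct": class_specificity(cm, g),
        }
        for g in GRADES
    ]
    df = pd.DataFrame(rows)
    df.attrs["overall_accuracy_pct"] = overall_accuracy(cm)
    return df


def report_text(cm: ConfusionMatrix) -> str:
    """Pretty-printable evaluation summary."""
    df = evaluation_report(cm)
    lines = ["confusion matrix (rows = real, cols = anticipated):"]
    lines += ["  " + "  ".join(f"{v:4d}" for v in row) for row in cm.counts]
    for _, r in df.iterrows():
        lines.append(
            f"grade {int(r['grade'])}: sensitivity {r['sensitivity_pct']:6.2f}%  "
            f"specificity {r['specificity_pct']:6.2f}%  (n={int(r['n'])})"
        )
    lines.append(f"overall accuracy: {df.attrs['overall_accuracy_pct']:.2f}%")
    return "\n".join(lines)


def train_test_split_stratified(
    labels: Sequence[int], test_fraction: float = 0.5, rng_seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-grade split; returns (train_idx, test_idx)."""
    labels = np.asarray(labels, dtype=np.int64)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0,1)")
    rng = np.random.default_rng(rng_seed)
    train, test = [], []
    for g in GRADES:
        idx = np.nonzero(labels == g)[0]
        idx = idx[rng.permutation(idx.size)]
        n_test = int(round(idx.size * test_fraction))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))
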