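"""Stimulus-frequency recognizers.

Four classifiers map an epoch (or its autoencoder feature vector) to one of
the flicker frequencies:

* :class:`EuclideanMLPClassifier` — a from-scratch fully connected network
  with ReLU hidden units, trained by backpropagation on the squared
  Euclidean distance between the output scores and one-hot targets;
* :class:`CCAFrequencyClassifier` — the standard training-free SSVEP
  recognizer: maximal canonical correlation between the signal and a bank of
  sin/cos references at each candidate frequency and its harmonics;
* :func:`svm_baseline` / :class:`GMMBayesClassifier` — baselines built on
  scikit-learn's SVC and per-class Gaussian mixtures.

For a single-channel signal the canonical correlation against a reference
matrix reduces to the multiple correlation coefficient, i.e. the square root
of the R^2 of regressing the (centered) signal on the (centered) references;
it is computed by least squares rather than a generalized eigenproblem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.mixture import GaussianMixture
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "relu",
    "DNNTrainConfig",
    "EuclideanMLPClassifier",
    "CCAFrequencyClassifier",
    "GMMBayesClassifier",
    "svm_baseline",
    "gmm_baseline",
    "dnn_forward",
    "dnn_train",
    "reference_bank",
    "cca_classify",
    "save_mlp",
    "load_mlp",
]


def relu(z):
    """Rectified linear unit, ``max(0, z)`` (elementwise on arrays)."""
    return np.maximum(0.0, z)


# ---------------------------------------------------------------------------
# feed-forward network


@dataclass(frozen=True)
class DNNTrainConfig:
    learning_rate: float = 0.01
    n_epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    hidden_widths: tuple[int, ...] = (150, 150)

    def __post_init__(self):
        if min(self.learning_rate, self.n_epochs, self.batch_size) <= 0:
            raise ValueError("learning_rate, n_epochs and batch_size must be positive")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")


class EuclideanMLPClassifier(ClassifierMixin, BaseEstimator):
    """Fully connected ReLU network trained on a squared Euclidean loss.

    Hidden layers apply an affine map followed by ReLU; the output layer is
    affine only, so scores may be negative.  Targets are one-hot vectors and
    the loss is ``(1/2N) sum_n ||scores_n - onehot_n||^2``, minimized by
    mini-batch stochastic gradient descent with exact backpropagation.
    Prediction is the argmax of the scores (ties to the lowest class index).

    Weights are initialized Glorot-uniform from a seeded generator, so
    training is fully reproducible.
    """

    def __init__(
        self,
        hidden_widths: tuple[int, ...] = (150, 150),
        learning_rate: float = 0.01,
        n_epochs: int = 200,
        batch_size: int = 32,
        seed: int = 0,
    ):
        self.hidden_widths = hidden_widths
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.seed = seed

    def _init_layers(self, widths: list[int], rng: np.random.Generator):
        layers = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            s = np.sqrt(6.0 / (fan_in + fan_out))
            W = rng.uniform(-s, s, size=(fan_out, fan_in))
            b = np.zeros(fan_out)
            layers.append([W, b])
        return layers

    @staticmethod
    def _forward(layers, X):
        """Returns (scores, activations); activations[i] feeds layer i."""
        acts = [X]
        A = X
        for k, (W, b) in enumerate(layers):
            Zk = A @ W.T + b
            A = Zk if k == len(layers) - 1 else relu(Zk)
            acts.append(A)
        return acts[-1], acts

    @staticmethod
    def _loss_and_grads(layers, X, T):
        """Squared Euclidean loss (1/2N)sum||s-t||^2 and its exact gradients."""
        n = X.shape[0]
        scores, acts = EuclideanMLPClassifier._forward(layers, X)
        diff = scores - T
        loss = 0.5 * float(np.sum(diff**2)) / n
        grads = [None] * len(layers)
        delta = diff / n
        for k in range(len(layers) - 1, -1, -1):
            W, _ = layers[k]
            A_in = acts[k]
            grads[k] = (delta.T @ A_in, delta.sum(axis=0))
            if k > 0:
                delta = (delta @ W) * (acts[k] > 0)  # ReLU mask of layer k's input
        return loss, grads

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EuclideanMLPClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty 2-D array")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        k = len(self.classes_)
        T = np.eye(k)[y_idx]

        rng = np.random.default_rng(self.seed)
        widths = [d, *self.hidden_widths, k]
        layers = self._init_layers(widths, rng)

        lr = self.learning_rate
        bsz = min(self.batch_size, n)
        trace = []
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, bsz):
                idx = order[start : start + bsz]
                loss, grads = self._loss_and_grads(layers, X[idx], T[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError("training loss became non-finite")
                for (W, b), (gW, gb) in zip(layers, grads):
                    W -= lr * gW
                    b -= lr * gb
            epoch_loss, _ = self._loss_and_grads(layers, X, T)
            trace.append(epoch_loss)
        self.layers_ = layers
        self.loss_trace_ = np.asarray(trace)
        self.n_features_in_ = d
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        scores, _ = self._forward(self.layers_, X)
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def dnn_forward(model: EuclideanMLPClassifier, x: np.ndarray) -> np.ndarray:
    """Scores of a single feature vector."""
    return model.decision_function(np.asarray(x, dtype=float))[0]


def dnn_train(features, labels, cfg: DNNTrainConfig | None = None) -> EuclideanMLPClassifier:
    cfg = cfg or DNNTrainConfig()
    est = EuclideanMLPClassifier(
        hidden_widths=tuple(cfg.hidden_widths),
        learning_rate=cfg.learning_rate,
        n_epochs=cfg.n_epochs,
        batch_size=cfg.batch_size,
        seed=cfg.seed,
    )
    return est.fit(np.asarray(features, dtype=float), np.asarray(labels))


# ---------------------------------------------------------------------------
# CCA recognizer


def reference_bank(
    frequencies, fs: float, n_samples: int, n_harmonics: int = 4
) -> list[np.ndarray]:
    """Per-frequency matrix of sin/cos references at harmonics 1..H."""
    t = np.arange(n_samples, dtype=float) / fs
    bank = []
    for f in frequencies:
        cols = []
        for h in range(1, n_harmonics + 1):
            if h * f >= fs / 2.0:
                break  # drop harmonics at/above Nyquist
            cols.append(np.sin(2.0 * np.pi * h * f * t))
            cols.append(np.cos(2.0 * np.pi * h * f * t))
        bank.append(np.column_stack(cols))
    return bank


def _max_canonical_correlation(x: np.ndarray, R: np.ndarray) -> float:
    """Multiple correlation of a 1-D signal with a reference matrix.

    Equals the maximal canonical correlation when one side is univariate:
    sqrt(R^2) of the least-squares regression of the centered signal on the
    centered references.
    """
    xc = x - x.mean()
    ss_tot = float(xc @ xc)
    if ss_tot <= 0:
        raise ValueError("zero-variance signal has no defined correlation")
    Rc = R - R.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Rc, xc, rcond=None)
    fitted = Rc @ coef
    r2 = float(fitted @ fitted) / ss_tot
    return float(np.sqrt(min(max(r2, 0.0), 1.0)))


class CCAFrequencyClassifier(ClassifierMixin, BaseEstimator):
    """Training-free SSVEP recognizer by canonical correlation.

    For each candidate flicker frequency a reference matrix of sin/cos pairs
    at harmonics 1..``n_harmonics`` is built; an epoch is assigned to the
    frequency with the largest canonical correlation.  Scores lie in [0, 1]
    and are invariant to the epoch's amplitude and phase.
    """

    def __init__(self, frequencies=None, fs: float = 100.0, n_harmonics: int = 4):
        self.frequencies = frequencies
        self.fs = fs
        self.n_harmonics = n_harmonics

    def fit(self, X: np.ndarray = None, y=None) -> "CCAFrequencyClassifier":
        if self.frequencies is None or len(self.frequencies) == 0:
            raise ValueError("frequencies must be a nonempty sequence")
        if X is None:
            raise ValueError("X is required to fix the epoch length")
        X = np.asarray(X, dtype=float)
        n_samples = X.shape[-1]
        self.bank_ = reference_bank(
            self.frequencies, self.fs, n_samples, self.n_harmonics
        )
        self.classes_ = np.arange(len(self.frequencies))
        self.n_features_in_ = n_samples
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "bank_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected epochs of length {self.n_features_in_}, got {X.shape[1]}"
            )
        scores = np.empty((X.shape[0], len(self.bank_)))
        for i, x in enumerate(X):
            for j, R in enumerate(self.bank_):
                scores[i, j] = _max_canonical_correlation(x, R)
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def cca_classify(epoch_signal: np.ndarray, frequencies, fs: float, n_harmonics: int = 4):
    """Label index and per-frequency correlations for one epoch."""
    x = np.asarray(epoch_signal, dtype=float)
    clf = CCAFrequencyClassifier(frequencies=frequencies, fs=fs, n_harmonics=n_harmonics)
    clf.fit(x[None, :])
    scores = clf.decision_function(x)[0]
    return int(np.argmax(scores)), scores


# ---------------------------------------------------------------------------
# baselines


def svm_baseline(seed: int = 0) -> SVC:
    """Multiclass margin baseline: RBF-kernel SVC, one-vs-rest decisions."""
    return SVC(kernel="rbf", decision_function_shape="ovr", random_state=seed)


class GMMBayesClassifier(ClassifierMixin, BaseEstimator):
    """Per-class Gaussian mixture (diagonal covariance) likelihood classifier."""

    def __init__(self, n_components: int = 4, seed: int = 0):
        self.n_components = n_components
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GMMBayesClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        counts = np.bincount(y_idx)
        if counts.min() < self.n_components:
            raise ValueError(
                f"every class needs at least {self.n_components} samples; "
                f"smallest class has {counts.min()}"
            )
        proto = GaussianMixture(
            n_components=self.n_components,
            covariance_type="diag",
            random_state=self.seed,
            reg_covar=1e-6,
        )
        self.mixtures_ = []
        self.log_priors_ = np.log(counts / counts.sum())
        for k in range(len(self.classes_)):
            gm = clone(proto)
            gm.fit(X[y_idx == k])
            self.mixtures_.append(gm)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "mixtures_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        ll = np.column_stack([gm.score_samples(X) for gm in self.mixtures_])
        return ll + self.log_priors_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def gmm_baseline(n_components: int = 4, seed: int = 0) -> GMMBayesClassifier:
    return GMMBayesClassifier(n_components=n_components, seed=seed)


# ---------------------------------------------------------------------------
# JSON persistence for the MLP


def save_mlp(model: EuclideanMLPClassifier, path: str | Path) -> None:
    check_is_fitted(model, "layers_")
    doc = {
        "kind": "euclidean_mlp",
        "hidden_widths": list(model.hidden_widths),
        "learning_rate": model.learning_rate,
        "n_epochs": model.n_epochs,
        "batch_size": model.batch_size,
        "seed": model.seed,
        "classes": np.asarray(model.classes_).tolist(),
        "n_features_in": model.n_features_in_,
        "layers": [
            {"shape": list(W.shape), "W": W.ravel().tolist(), "b": b.tolist()}
            for W, b in model.layers_
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_mlp(path: str | Path) -> EuclideanMLPClassifier:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "euclidean_mlp":
        raise ValueError(f"{path} is not an MLP model file")
    est = EuclideanMLPClassifier(
        hidden_widths=tuple(doc["hidden_widths"]),
        learning_rate=doc["learning_rate"],
        n_epochs=doc["n_epochs"],
        batch_size=doc["batch_size"],
        seed=doc["seed"],
    )
    est.classes_ = np.asarray(doc["classes"])
    est.n_features_in_ = doc["n_features_in"]
    est.layers_ = [
        [
            np.asarray(layer["W"], dtype=float).reshape(layer["shape"]),
            np.asarray(layer["b"], dtype=float),
        ]
        for layer in doc["layers"]
    ]
    return est
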