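"""Affine denoising autoencoder with ideal-sine targets.

The encoder maps a standardized 100-sample epoch to a low-dimensional hidden
representation ``y = W x + b``; the decoder reconstructs ``x' = W' y + b'``.
Both maps are affine: with squared-error loss the global optimum is the
reduced-rank least-squares regression from epochs onto their targets, which
makes the trained network directly checkable against a closed form.

Targets come in three flavours:

* ``"AP"`` — a zero-phase ideal sine at the epoch's flicker frequency,
* ``"IP"`` — an ideal sine whose phase is matched to the input epoch by
  cross-correlation (integer-lag search over one period),
* ``"AE"`` — the input itself (a plain autoencoder baseline).

Phase matching is what makes the affine network effective: a linear map can
pass a sine of arbitrary phase through to a phase-matched target, but cannot
rotate every random phase to zero, so "AP" reconstructions lose the phase
information and most of the signal power with it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

TARGET_MODES = ("AP", "IP", "AE")
#: amplitude of the ideal-sine target; sqrt(2) gives the target unit variance,
#: matching the unit variance of the standardized input epochs.
TARGET_AMPLITUDE = float(np.sqrt(2.0))

__all__ = [
    "TARGET_MODES",
    "TARGET_AMPLITUDE",
    "DAETrainConfig",
    "LinearDenoisingAutoencoder",
    "estimate_phase_xcorr",
    "build_target",
    "standardize_epochs",
    "dae_encode",
    "dae_decode",
    "train_dae",
    "denoise_epoch",
    "save_dae",
    "load_dae",
]


def estimate_phase_xcorr(x: np.ndarray, f: float, fs: float) -> float:
    """Estimate the phase of the ``f``-Hz component of ``x`` by lag search.

    Cross-correlates ``x`` with ``sin(2*pi*f*(t+lag)/fs)`` over integer lags
    spanning one period (``0 <= lag < ceil(fs/f)``, enough to cover the full
    phase circle) and returns ``2*pi*f*lag*/fs mod 2*pi`` for the lag
    maximizing the inner product.  Ties break toward the smallest lag.

    The correlation window is trimmed to the largest whole number of cycles
    that fits in ``x``: over whole cycles the inner product with a clean sine
    is exactly proportional to ``cos(phase - lag_phase)``, so the estimate is
    exact when the true phase lies on the lag grid and otherwise off by at
    most half the grid step, ``pi*f/fs``.  (With a fractional trailing cycle
    the second-harmonic cross-term can push the error slightly past that
    bound.)
    """
    if f <= 0 or fs <= 0:
        raise ValueError("f and fs must be positive")
    x = np.asarray(x, dtype=float)
    period = fs / f
    if len(x) < period:
        raise ValueError("signal must span at least one period of f")
    n_lags = int(np.ceil(period))
    # largest window holding an integer number of cycles (if any does)
    n_use = len(x)
    cycles = n_use * f / fs
    if abs(cycles - round(cycles)) > 1e-9:
        for w in range(int(np.floor(cycles)), 0, -1):
            candidate = w * period
            if abs(candidate - round(candidate)) < 1e-9:
                n_use = int(round(candidate))
                break
    x = x[:n_use]
    t = np.arange(len(x), dtype=float)
    lags = np.arange(n_lags, dtype=float)
    # refs[k] = sin(2*pi*f*(t+k)/fs); argmax of x.refs over k
    refs = np.sin(2.0 * np.pi * f * (t[None, :] + lags[:, None]) / fs)
    scores = refs @ x
    best = int(np.argmax(scores))  # argmax returns the first (smallest) lag on ties
    return float((2.0 * np.pi * f * best / fs) % (2.0 * np.pi))


def _ideal_sine(f: float, fs: float, n: int, phase: float, amplitude: float) -> np.ndarray:
    t = np.arange(n, dtype=float)
    return amplitude * np.sin(2.0 * np.pi * f * t / fs + phase)


def build_target(
    x: np.ndarray,
    label_freq: float,
    fs: float,
    mode: str,
    amplitude: float = TARGET_AMPLITUDE,
) -> np.ndarray:
    """Ideal-sine training target for one (standardized) epoch."""
    x = np.asarray(x, dtype=float)
    if mode == "AE":
        return x.copy()
    if mode == "AP":
        phase = 0.0
    elif mode == "IP":
        phase = estimate_phase_xcorr(x, label_freq, fs)
    else:
        raise ValueError(f"unknown target mode {mode!r}; expected one of {TARGET_MODES}")
    return _ideal_sine(label_freq, fs, len(x), phase, amplitude)


def standardize_epochs(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch zero-mean unit-variance scaling; returns (Z, mean, std)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


@dataclass(frozen=True)
class DAETrainConfig:
    learning_rate: float = 0.01
    n_iterations: int = 2000
    batch_size: int = 32
    seed: int = 0
    init_scale: float = 0.1

    def __post_init__(self):
        if min(self.learning_rate, self.n_iterations, self.batch_size, self.init_scale) <= 0:
            raise ValueError("all training hyperparameters must be positive")


class LinearDenoisingAutoencoder(TransformerMixin, BaseEstimator):
    """Affine denoising autoencoder trained by mini-batch gradient descent.

    Parameters
    ----------
    hidden_size : int
        Width of the hidden representation (the feature dimension).
    mode : {"AP", "IP", "AE"}
        Target construction: zero-phase sine, phase-matched sine, or identity.
    fs : float
        Sampling rate of the epochs in Hz.
    learning_rate, n_iterations, batch_size, init_scale, seed
        Plain mini-batch gradient-descent hyperparameters; initial weights
        are drawn uniform on ``(-init_scale, init_scale)``.
    encoder_activation : None or "sigmoid"
        The default (None) keeps both maps purely affine.  A sigmoid encoder
        is available for users who expect a classical nonlinear autoencoder.

    Attributes
    ----------
    W_, b_ : encoder weight matrix (hidden x input) and bias.
    W_dec_, b_dec_ : decoder weight matrix (input x hidden) and bias.
    loss_trace_ : per-iteration mini-batch loss, ``mean_i ||x'_i - target_i||^2``.
    """

    def __init__(
        self,
        hidden_size: int = 25,
        mode: str = "IP",
        fs: float = 100.0,
        learning_rate: float = 0.01,
        n_iterations: int = 2000,
        batch_size: int = 32,
        init_scale: float = 0.1,
        seed: int = 0,
        encoder_activation: str | None = None,
    ):
        self.hidden_size = hidden_size
        self.mode = mode
        self.fs = fs
        self.learning_rate = learning_rate
        self.n_iterations = n_iterations
        self.batch_size = batch_size
        self.init_scale = init_scale
        self.seed = seed
        self.encoder_activation = encoder_activation

    # -- core maps ----------------------------------------------------------

    def _encode(self, Z: np.ndarray) -> np.ndarray:
        H = Z @ self.W_.T + self.b_
        if self.encoder_activation == "sigmoid":
            H = 1.0 / (1.0 + np.exp(-H))
        return H

    def _decode(self, H: np.ndarray) -> np.ndarray:
        return H @ self.W_dec_.T + self.b_dec_

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray | None = None) -> "LinearDenoisingAutoencoder":
        """Train on epochs ``X`` (n_epochs x n_samples).

        ``y`` gives each epoch's flicker frequency in Hz and is required for
        the sine-target modes ("AP"/"IP"); it is ignored for "AE".
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty 2-D array of epochs")
        if self.mode not in TARGET_MODES:
            raise ValueError(f"unknown target mode {self.mode!r}")
        if self.mode in ("AP", "IP"):
            if y is None:
                raise ValueError(f"mode {self.mode!r} needs per-epoch label frequencies y")
            freqs = np.asarray(y, dtype=float)
            if freqs.shape[0] != X.shape[0]:
                raise ValueError("y must hold one frequency per epoch")
        n, d = X.shape

        Z, _, _ = standardize_epochs(X)
        T = np.empty_like(Z)
        for i in range(n):
            f_i = freqs[i] if self.mode in ("AP", "IP") else 0.0
            T[i] = build_target(Z[i], f_i, self.fs, self.mode)

        rng = np.random.default_rng(self.seed)
        h = int(self.hidden_size)
        self.W_ = rng.uniform(-self.init_scale, self.init_scale, size=(h, d))
        self.b_ = rng.uniform(-self.init_scale, self.init_scale, size=h)
        self.W_dec_ = rng.uniform(-self.init_scale, self.init_scale, size=(d, h))
        self.b_dec_ = rng.uniform(-self.init_scale, self.init_scale, size=d)

        lr = self.learning_rate
        bsz = min(self.batch_size, n)
        trace = np.empty(self.n_iterations)
        sigmoid = self.encoder_activation == "sigmoid"
        full_batch = bsz >= n
        for it in range(self.n_iterations):
            idx = slice(None) if full_batch else rng.integers(0, n, size=bsz)
            Zb, Tb = Z[idx], T[idx]
            # overflow is tolerated here: divergence is caught by the
            # finiteness check on the loss just below
            with np.errstate(over="ignore", invalid="ignore"):
                Hb = Zb @ self.W_.T + self.b_
                if sigmoid:
                    Hb = 1.0 / (1.0 + np.exp(-Hb))
                Rb = Hb @ self.W_dec_.T + self.b_dec_
                E = Rb - Tb
                loss = float(np.mean(np.sum(E**2, axis=1)))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training loss diverged (non-finite) at iteration {it}"
                )
            trace[it] = loss
            dR = (2.0 / bsz) * E
            gW_dec = dR.T @ Hb
            gb_dec = dR.sum(axis=0)
            dH = dR @ self.W_dec_
            if sigmoid:
                dH = dH * Hb * (1.0 - Hb)
            gW = dH.T @ Zb
            gb = dH.sum(axis=0)
            self.W_dec_ -= lr * gW_dec
            self.b_dec_ -= lr * gb_dec
            self.W_ -= lr * gW
            self.b_ -= lr * gb

        self.loss_trace_ = trace
        self.n_features_in_ = d
        # full-data training loss at the final parameters
        R = self._decode(self._encode(Z))
        self.final_loss_ = float(np.mean(np.sum((R - T) ** 2, axis=1)))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Hidden representation ``y = W x + b`` of standardized epochs."""
        check_is_fitted(self, "W_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected epochs of length {self.n_features_in_}, got {X.shape[1]}"
            )
        Z, _, _ = standardize_epochs(X)
        return self._encode(Z)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Denoised epochs ``x' = W'(W x + b) + b'``, mapped back to input units."""
        check_is_fitted(self, "W_")
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected epochs of length {self.n_features_in_}, got {X.shape[1]}"
            )
        Z, mu, sd = standardize_epochs(X)
        R = self._decode(self._encode(Z)) * sd + mu
        return R[0] if squeeze else R


# ---------------------------------------------------------------------------
# functional wrappers


def dae_encode(model: LinearDenoisingAutoencoder, x: np.ndarray) -> np.ndarray:
    """Hidden feature vector of one raw vector (no standardization applied)."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != model.W_.shape[1]:
        raise ValueError(f"expected input of length {model.W_.shape[1]}, got {x.shape[0]}")
    return model._encode(x[None, :])[0]


def dae_decode(model: LinearDenoisingAutoencoder, y: np.ndarray) -> np.ndarray:
    """Reconstruction of one hidden vector."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != model.W_dec_.shape[1]:
        raise ValueError(f"expected hidden vector of length {model.W_dec_.shape[1]}, got {y.shape[0]}")
    return model._decode(y[None, :])[0]


def train_dae(table, mode: str, hidden_size: int, cfg: DAETrainConfig | None = None) -> LinearDenoisingAutoencoder:
    """Fit a :class:`LinearDenoisingAutoencoder` on an epoch table."""
    cfg = cfg or DAETrainConfig()
    if len(table) == 0:
        raise ValueError("epoch table is empty")
    est = LinearDenoisingAutoencoder(
        hidden_size=hidden_size,
        mode=mode,
        fs=table.fs,
        learning_rate=cfg.learning_rate,
        n_iterations=cfg.n_iterations,
        batch_size=cfg.batch_size,
        init_scale=cfg.init_scale,
        seed=cfg.seed,
    )
    return est.fit(table.X, table.label_frequencies)


def denoise_epoch(model: LinearDenoisingAutoencoder, epoch) -> np.ndarray:
    """Denoised signal of one epoch (``Epoch`` object or plain sample vector)."""
    samples = getattr(epoch, "samples", epoch)
    return model.reconstruct(np.asarray(samples, dtype=float))


# ---------------------------------------------------------------------------
# JSON persistence (bit-exact: floats survive a JSON round trip in Python)


def save_dae(model: LinearDenoisingAutoencoder, path: str | Path) -> None:
    check_is_fitted(model, "W_")
    doc = {
        "kind": "linear_denoising_autoencoder",
        "mode": model.mode,
        "fs": model.fs,
        "hidden_size": model.hidden_size,
        "encoder_activation": model.encoder_activation,
        "n_features_in": model.n_features_in_,
        "train_config": {
            "learning_rate": model.learning_rate,
            "n_iterations": model.n_iterations,
            "batch_size": model.batch_size,
            "init_scale": model.init_scale,
            "seed": model.seed,
        },
        "W": model.W_.ravel().tolist(),
        "b": model.b_.tolist(),
        "W_dec": model.W_dec_.ravel().tolist(),
        "b_dec": model.b_dec_.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_dae(path: str | Path) -> LinearDenoisingAutoencoder:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "linear_denoising_autoencoder":
        raise ValueError(f"{path} is not a denoising-autoencoder model file")
    cfg = doc["train_config"]
    est = LinearDenoisingAutoencoder(
        hidden_size=doc["hidden_size"],
        mode=doc["mode"],
        fs=doc["fs"],
        learning_rate=cfg["learning_rate"],
        n_iterations=cfg["n_iterations"],
        batch_size=cfg["batch_size"],
        init_scale=cfg["init_scale"],
        seed=cfg["seed"],
        encoder_activation=doc["encoder_activation"],
    )
    d = doc["n_features_in"]
    h = doc["hidden_size"]
    est.W_ = np.asarray(doc["W"], dtype=float).reshape(h, d)
    est.b_ = np.asarray(doc["b"], dtype=float)
    est.W_dec_ = np.asarray(doc["W_dec"], dtype=float).reshape(d, h)
    est.b_dec_ = np.asarray(doc["b_dec"], dtype=float)
    est.n_features_in_ = d
    return est
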