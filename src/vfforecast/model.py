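"""Masked bidirectional GRU regressor, implemented directly in NumPy.

Architecture (fixed apart from the sizes in :class:`ModelConfig`)::

    input (80 x 115)
      -> masking of all-zero rows
      -> bidirectional GRU (128 units per direction, states concatenated)
      -> dense 64, tanh
      -> dropout 0.1 (training only)
      -> dense 57, tanh

trained with Adam (lr 0.001) on mean squared error, batch size 20, a 9:1
train/validation split, and early stopping (patience 20) that restores the
best-validation weights.

The masking rule matches the usual recurrent-masking semantics: a row whose
115 values are all exactly zero is skipped — the hidden state is carried
through unchanged in the forward direction, and the backward direction reads
only the valid prefix in reverse.  Predictions are therefore invariant to
the amount of trailing padding, which is what lets a fixed 80-row container
hold anywhere from 3 to 80 exams.

This module contains the full forward pass, backpropagation through time,
and the Adam update; no deep-learning framework is involved.  GRU update:
``h_t = (1-z) * h_{t-1} + z * c`` with gates ``z, r`` (logistic) and
candidate ``c`` (tanh, reset applied to the recurrent term).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit as _sigmoid

from .encoding import N_FEATURES, N_ROWS, N_TARGETS, EncodedSequence

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "BiGRURegressor",
    "train",
    "mse",
]

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Network sizes.  ``gru_units`` counts units per direction."""

    gru_units: int = 128
    dense_units: int = 64
    dropout_rate: float = 0.1
    output_units: int = N_TARGETS

    def __post_init__(self) -> None:
        if self.output_units != N_TARGETS:
            raise ValueError(f"output_units is fixed at {N_TARGETS}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.gru_units < 1 or self.dense_units < 1:
            raise ValueError("layer sizes must be positive")


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 20
    patience: int = 20
    max_epochs: int = 500
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


class BiGRURegressor:
    """The masked Bi-GRU network with explicit forward/backward passes."""

    def __init__(self, config: ModelConfig | None = None,
                 n_features: int = N_FEATURES, seed: int = 0) -> None:
        self.config = config or ModelConfig()
        self.n_features = n_features
        self.seed = seed
        rng = np.random.default_rng(seed)
        H, F = self.config.gru_units, n_features
        D, O = self.config.dense_units, self.config.output_units
        p: dict[str, np.ndarray] = {}
        for d in ("fwd", "bwd"):
            p[f"{d}/W"] = _glorot(rng, F, H, (F, 3 * H))
            p[f"{d}/U_zr"] = np.concatenate(
                [_orthogonal(rng, H), _orthogonal(rng, H)], axis=1)
            p[f"{d}/U_c"] = _orthogonal(rng, H)
            p[f"{d}/b"] = np.zeros(3 * H)
        p["W1"] = _glorot(rng, 2 * H, D, (2 * H, D))
        p["b1"] = np.zeros(D)
        p["W2"] = _glorot(rng, D, O, (D, O))
        p["b2"] = np.zeros(O)
        self.params = p

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _lengths(X: np.ndarray) -> np.ndarray:
        """Number of valid (non-all-zero) leading rows per sample."""
        return X.any(axis=2).sum(axis=1)

    @staticmethod
    def _reverse_valid(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """Reverse each sample's valid prefix, leaving trailing padding."""
        B, T, _ = X.shape
        t = np.arange(T)[None, :]
        rev = np.where(t < lengths[:, None], lengths[:, None] - 1 - t, t)
        return X[np.arange(B)[:, None], rev]

    def _gru_direction(self, X: np.ndarray, mask: np.ndarray, d: str,
                       want_cache: bool):
        """Run one GRU direction over (B, T, F) with (B, T) row mask."""
        p = self.params
        W, U_zr, U_c, b = p[f"{d}/W"], p[f"{d}/U_zr"], p[f"{d}/U_c"], p[f"{d}/b"]
        H = self.config.gru_units
        B, T, _ = X.shape
        h = np.zeros((B, H))
        cache = [] if want_cache else None
        S = X.reshape(B * T, -1) @ W
        S = S.reshape(B, T, 3 * H) + b
        for t in range(T):
            m = mask[:, t:t + 1].astype(float)
            h_prev = h
            u = h_prev @ U_zr
            z = _sigmoid(S[:, t, :H] + u[:, :H])
            r = _sigmoid(S[:, t, H:2 * H] + u[:, H:])
            c = np.tanh(S[:, t, 2 * H:] + (r * h_prev) @ U_c)
            h = m * ((1.0 - z) * h_prev + z * c) + (1.0 - m) * h_prev
            if want_cache:
                cache.append((h_prev, z, r, c, m))
        return h, cache

    def _forward(self, X: np.ndarray, *, train: bool = False,
                 dropout_rng: np.random.Generator | None = None,
                 want_cache: bool = False):
        if X.ndim != 3 or X.shape[2] != self.n_features:
            raise ValueError(
                f"input must be (batch, rows, {self.n_features}), got {X.shape}")
        lengths = self._lengths(X)
        T_max = max(int(lengths.max(initial=0)), 1)
        X = X[:, :T_max]
        mask = X.any(axis=2)
        X_rev = self._reverse_valid(X, lengths)
        hf, cache_f = self._gru_direction(X, mask, "fwd", want_cache)
        hb, cache_b = self._gru_direction(X_rev, mask, "bwd", want_cache)
        Dvec = np.concatenate([hf, hb], axis=1)
        p = self.params
        a1 = Dvec @ p["W1"] + p["b1"]
        z1 = np.tanh(a1)
        rate = self.config.dropout_rate
        if train and rate > 0.0:
            if dropout_rng is None:
                raise ValueError("dropout requires an rng in training mode")
            keep = (dropout_rng.random(z1.shape) >= rate) / (1.0 - rate)
        else:
            keep = None
        z1d = z1 if keep is None else z1 * keep
        y = np.tanh(z1d @ p["W2"] + p["b2"])
        if not want_cache:
            return y, None
        cache = {
            "X": X, "X_rev": X_rev, "mask": mask, "lengths": lengths,
            "cache_f": cache_f, "cache_b": cache_b,
            "Dvec": Dvec, "z1": z1, "z1d": z1d, "keep": keep, "y": y,
        }
        return y, cache

    # -- public inference --------------------------------------------------

    def predict(self, enc: EncodedSequence | np.ndarray) -> np.ndarray:
        """Predict the 57-value normalized target for one encoded input."""
        X = enc.matrix if isinstance(enc, EncodedSequence) else np.asarray(enc, float)
        if X.ndim != 2:
            raise ValueError(f"expected a 2-D input, got shape {X.shape}")
        y, _ = self._forward(X[None])
        return y[0]

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        y, _ = self._forward(np.asarray(X, dtype=float))
        return y

    # -- backpropagation ---------------------------------------------------

    def _backward_direction(self, d: str, cache_dir, X: np.ndarray,
                            dh: np.ndarray, grads: dict[str, np.ndarray]) -> None:
        p = self.params
        U_zr, U_c = p[f"{d}/U_zr"], p[f"{d}/U_c"]
        H = self.config.gru_units
        T = len(cache_dir)
        gW, gU_zr, gU_c, gb = (grads[f"{d}/W"], grads[f"{d}/U_zr"],
                               grads[f"{d}/U_c"], grads[f"{d}/b"])
        for t in range(T - 1, -1, -1):
            h_prev, z, r, c, m = cache_dir[t]
            x_t = X[:, t]
            dh_new = dh * m
            dh_prev = dh * (1.0 - m)
            dz = dh_new * (c - h_prev)
            dc = dh_new * z
            dh_prev = dh_prev + dh_new * (1.0 - z)
            dac = dc * (1.0 - c * c)
            drh = dac @ U_c.T
            gU_c += (r * h_prev).T @ dac
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            da = np.concatenate([daz, dar, dac], axis=1)
            gW += x_t.T @ da
            gb += da.sum(axis=0)
            gU_zr[:, :H] += h_prev.T @ daz
            gU_zr[:, H:] += h_prev.T @ dar
            dh_prev = dh_prev + daz @ U_zr[:, :H].T + dar @ U_zr[:, H:].T
            dh = dh_prev

    def backward(self, cache: dict, dY: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. all parameters, given dL/dy."""
        p = self.params
        H = self.config.gru_units
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        y, z1d, z1, Dvec = cache["y"], cache["z1d"], cache["z1"], cache["Dvec"]
        da2 = dY * (1.0 - y * y)
        grads["W2"] += z1d.T @ da2
        grads["b2"] += da2.sum(axis=0)
        dz1d = da2 @ p["W2"].T
        dz1 = dz1d if cache["keep"] is None else dz1d * cache["keep"]
        da1 = dz1 * (1.0 - z1 * z1)
        grads["W1"] += Dvec.T @ da1
        grads["b1"] += da1.sum(axis=0)
        dD = da1 @ p["W1"].T
        self._backward_direction("fwd", cache["cache_f"], cache["X"],
                                 dD[:, :H], grads)
        self._backward_direction("bwd", cache["cache_b"], cache["X_rev"],
                                 dD[:, H:], grads)
        return grads

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save weights (.npz) plus a JSON manifest alongside."""
        path = Path(path)
        np.savez(path, **self.params)
        manifest = {
            "format": "vfforecast-bigru-v1",
            "config": asdict(self.config),
            "n_features": self.n_features,
            "seed": self.seed,
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "BiGRURegressor":
        path = Path(path)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            manifest = json.load(fh)
        model = cls(ModelConfig(**manifest["config"]),
                    n_features=manifest["n_features"],
                    seed=manifest.get("seed", 0))
        with np.load(path if path.exists() else path.with_suffix(".npz")) as data:
            for k in model.params:
                model.params[k] = data[k]
        return model


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)


def _batched_loss(model: BiGRURegressor, X: np.ndarray, Y: np.ndarray,
                  batch: int = 256) -> float:
    total = 0.0
    for i in range(0, len(X), batch):
        pred = model.predict_batch(X[i:i + batch])
        total += float(np.sum((pred - Y[i:i + batch]) ** 2))
    return total / (len(X) * Y.shape[1])


def train(model: BiGRURegressor, X: np.ndarray, Y: np.ndarray,
          config: TrainConfig | None = None) -> dict:
    """Train with Adam on MSE; 9:1 train/validation split by sample; early
    stopping on validation loss with best-weight restoration.

    ``X``: (N, rows, 115) encoded inputs; ``Y``: (N, 57) normalized targets.
    Returns a history dict with per-epoch train/validation losses.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(X) == 0:
        raise ValueError("empty training dataset")
    if len(X) != len(Y) or Y.ndim != 2 or Y.shape[1] != model.config.output_units:
        raise ValueError(f"shape mismatch: X {X.shape}, Y {Y.shape}")

    rng = np.random.default_rng(config.seed)
    n = len(X)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n))) if n > 1 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx = perm
    Xtr, Ytr = X[tr_idx], Y[tr_idx]
    Xval, Yval = X[val_idx], Y[val_idx]
    monitor_val = len(val_idx) > 0

    opt = _Adam(model.params, config.learning_rate)
    history: dict = {"train_loss": [], "val_loss": [], "epochs": 0,
                     "best_epoch": 0, "stopped_early": False}
    best_loss = np.inf
    best_params = copy.deepcopy(model.params)
    wait = 0
    out_units = model.config.output_units

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        running, count = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            pred, cache = model._forward(xb, train=True, dropout_rng=rng,
                                         want_cache=True)
            loss = mse(pred, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; aborting")
            dY = 2.0 * (pred - yb) / (len(xb) * out_units)
            grads = model.backward(cache, dY)
            opt.step(model.params, grads)
            running += loss * len(xb)
            count += len(xb)
        train_loss = running / count
        val_loss = _batched_loss(model, Xval, Yval) if monitor_val else train_loss
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["epochs"] = epoch + 1
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_params = copy.deepcopy(model.params)
            history["best_epoch"] = epoch + 1
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                history["stopped_early"] = True
                logger.info("early stopping at epoch %d (best %d, val %.3g)",
                            epoch + 1, history["best_epoch"], best_loss)
                break
    model.params = best_params
    history["best_val_loss"] = float(best_loss)
    return history
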