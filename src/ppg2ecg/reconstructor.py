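"""Subject-specific sequence-to-sequence BiLSTM: n-second PPG window in,
n-second ECG window out.

Architecture: a bidirectional LSTM layer (25 hidden units per direction,
sequence output, L1+L2 regularization on the input kernels) followed by a
per-timestep linear map from the 50 concatenated features to one mV
output value.  Trained with per-timestep mean squared error and Adam
(learning rate 0.001), batch size 1, at most 1000 epochs with early
stopping on validation loss and best-weight restoration.

The network is implemented directly on numpy arrays with numba-compiled
forward/backward-through-time kernels; with a fixed seed, training is
bit-reproducible on the same platform.  The estimator follows the
scikit-learn fit/predict protocol so it composes with sklearn tooling.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ReconstructorConfig",
    "BiLSTMRegressor",
    "build",
    "train",
    "reconstruct",
    "save_model",
    "load_model",
]

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


# ---------------------------------------------------------------------------
# LSTM forward / backward-through-time kernels (input dimension 1)
# Gate order follows the i, f, g (cell candidate), o convention.

@njit(cache=True)
def _lstm_fwd(x, W, U, b, H):
    T = x.shape[0]
    I = np.empty((T, H))
    F = np.empty((T, H))
    G = np.empty((T, H))
    O = np.empty((T, H))
    C = np.empty((T, H))
    TC = np.empty((T, H))
    Hs = np.empty((T, H))
    h = np.zeros(H)
    c = np.zeros(H)
    for t in range(T):
        z = W * x[t] + h @ U + b
        i = 1.0 / (1.0 + np.exp(-z[:H]))
        f = 1.0 / (1.0 + np.exp(-z[H:2 * H]))
        g = np.tanh(z[2 * H:3 * H])
        o = 1.0 / (1.0 + np.exp(-z[3 * H:]))
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        I[t] = i
        F[t] = f
        G[t] = g
        O[t] = o
        C[t] = c
        TC[t] = tc
        Hs[t] = h
    return I, F, G, O, C, TC, Hs


@njit(cache=True)
def _lstm_bwd(x, dh_ext, I, F, G, O, C, TC, Hs, U, H):
    T = x.shape[0]
    dW = np.zeros(4 * H)
    dU = np.zeros((H, 4 * H))
    db = np.zeros(4 * H)
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    zeros = np.zeros(H)
    dz = np.empty(4 * H)
    for t in range(T - 1, -1, -1):
        dh = dh_ext[t] + dh_next
        do = dh * TC[t]
        dc = dh * O[t] * (1.0 - TC[t] ** 2) + dc_next
        di = dc * G[t]
        dg = dc * I[t]
        c_prev = C[t - 1] if t > 0 else zeros
        df = dc * c_prev
        dz[:H] = di * I[t] * (1.0 - I[t])
        dz[H:2 * H] = df * F[t] * (1.0 - F[t])
        dz[2 * H:3 * H] = dg * (1.0 - G[t] ** 2)
        dz[3 * H:] = do * O[t] * (1.0 - O[t])
        dW += x[t] * dz
        h_prev = Hs[t - 1] if t > 0 else zeros
        dU += np.outer(h_prev, dz)
        db += dz
        dh_next = U @ dz
        dc_next = dc * F[t]
    return dW, dU, db


@dataclass(frozen=True)
class ReconstructorConfig:
    """BiLSTM hyperparameters (defaults are the model's operating point)."""

    hidden_units: int = 25
    l1: float = 1e-4
    l2: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 1
    max_epochs: int = 1000
    loss: str = "mse"
    seed: int = 0
    early_stop_patience: int = 50

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1 or self.learning_rate <= 0:
            raise ValueError("max_epochs and learning_rate must be positive")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("regularizer weights must be >= 0")
        if self.loss != "mse":
            raise ValueError(f"unsupported loss {self.loss!r}")


class BiLSTMRegressor(BaseEstimator, RegressorMixin):
    """Sequence-to-sequence BiLSTM regressor on fixed-length windows.

    X and y are 2-D arrays of shape (n_windows, window_length); each row
    is one window treated as an independent sample (no state is carried
    across windows).  Fitted attributes carry a trailing underscore.

    Parameters mirror ReconstructorConfig; ``early_stop_patience=None``
    disables early stopping and runs the full max_epochs.
    """

    def __init__(self, hidden_units: int = 25, l1: float = 1e-4, l2: float = 1e-4,
                 learning_rate: float = 1e-3, batch_size: int = 1,
                 max_epochs: int = 1000, early_stop_patience: int | None = 50,
                 shuffle: bool = True, seed: int = 0, verbose: int = 0):
        self.hidden_units = hidden_units
        self.l1 = l1
        self.l2 = l2
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.shuffle = shuffle
        self.seed = seed
        self.verbose = verbose

    # -- parameter initialization -------------------------------------
    def _init_weights(self, input_length: int) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if input_length < 1:
            raise ValueError("input_length must be >= 1")
        H = self.hidden_units
        rng = np.random.default_rng(self.seed)

        def glorot(fan_in, fan_out, shape):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)

        def orthogonal(H):
            blocks = []
            for _ in range(4):
                q, _r = np.linalg.qr(rng.normal(size=(H, H)))
                blocks.append(q)
            return np.concatenate(blocks, axis=1)  # (H, 4H)

        def bias(H):
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias
            return b

        self.weights_ = {
            "Wf": glorot(1, 4 * H, 4 * H),
            "Uf": orthogonal(H),
            "bf": bias(H),
            "Wb": glorot(1, 4 * H, 4 * H),
            "Ub": orthogonal(H),
            "bb": bias(H),
            "Wd": glorot(2 * H, 1, 2 * H),
            "bd": np.zeros(1),
        }
        self.input_length_ = int(input_length)

    # -- forward -------------------------------------------------------
    def _forward(self, x: np.ndarray):
        H = self.hidden_units
        w = self.weights_
        fwd = _lstm_fwd(x, w["Wf"], w["Uf"], w["bf"], H)
        xb = x[::-1].copy()
        bwd = _lstm_fwd(xb, w["Wb"], w["Ub"], w["bb"], H)
        h_cat = np.concatenate([fwd[6], bwd[6][::-1]], axis=1)  # (T, 2H)
        y = h_cat @ w["Wd"] + w["bd"][0]
        return y, h_cat, fwd, bwd, xb

    def _predict_window(self, x: np.ndarray) -> np.ndarray:
        return self._forward(x)[0]

    def _grads(self, x: np.ndarray, target: np.ndarray):
        H = self.hidden_units
        w = self.weights_
        y, h_cat, fwd, bwd, xb = self._forward(x)
        err = y - target
        T = len(x)
        mse = float(np.mean(err**2))
        dy = 2.0 * err / T
        dWd = h_cat.T @ dy
        dbd = np.array([np.sum(dy)])
        dh_cat = np.outer(dy, w["Wd"])
        dWf, dUf, dbf = _lstm_bwd(x, np.ascontiguousarray(dh_cat[:, :H]), *fwd, w["Uf"], H)
        dh_b = np.ascontiguousarray(dh_cat[:, H:][::-1])
        dWb, dUb, dbb = _lstm_bwd(xb, dh_b, *bwd, w["Ub"], H)
        # L1+L2 kernel regularization on the recurrent layer's input kernels
        for name, dW in (("Wf", dWf), ("Wb", dWb)):
            dW += self.l1 * np.sign(w[name]) + 2.0 * self.l2 * w[name]
        grads = {"Wf": dWf, "Uf": dUf, "bf": dbf,
                 "Wb": dWb, "Ub": dUb, "bb": dbb, "Wd": dWd, "bd": dbd}
        return mse, grads

    def _penalty(self) -> float:
        w = self.weights_
        return float(sum(self.l1 * np.sum(np.abs(w[k])) + self.l2 * np.sum(w[k] ** 2)
                         for k in ("Wf", "Wb")))

    @staticmethod
    def _validate_xy(X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
            raise ValueError("X must be a non-empty 2-D array (n_windows, window_length)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if y is None:
            return X
        y = np.asarray(y, dtype=np.float64)
        if y.shape != X.shape:
            raise ValueError(f"y shape {y.shape} must match X shape {X.shape}")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        return X, y

    # -- training ------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train on (PPG window, ECG window) pairs by per-timestep MSE.

        If a validation set is given, early stopping monitors its loss
        and the best-validation weights are restored at the end.
        """
        X, y = self._validate_xy(X, y)
        has_val = X_val is not None and y_val is not None
        if has_val:
            X_val, y_val = self._validate_xy(X_val, y_val)
            if X_val.shape[1] != X.shape[1]:
                raise ValueError("validation window length differs from training")

        self._init_weights(X.shape[1])
        rng = np.random.default_rng(self.seed + 1)
        n = X.shape[0]
        adam_m = {k: np.zeros_like(v) for k, v in self.weights_.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.weights_.items()}
        b1, b2, eps = 0.9, 0.999, 1e-7
        step = 0

        history: dict[str, list[float]] = {"loss": [], "val_loss": []}
        best_val = np.inf
        best_weights = None
        best_epoch = -1
        wait = 0
        patience = self.early_stop_patience

        for epoch in range(self.max_epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            epoch_mse = 0.0
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                acc = None
                batch_mse = 0.0
                for idx in batch:
                    mse, grads = self._grads(X[idx], y[idx])
                    batch_mse += mse
                    if acc is None:
                        acc = grads
                    else:
                        for k in acc:
                            acc[k] += grads[k]
                epoch_mse += batch_mse
                if not np.isfinite(batch_mse):
                    raise RuntimeError(f"NaN/inf loss at epoch {epoch}; "
                                       "reduce the learning rate")
                scale = 1.0 / len(batch)
                step += 1
                lr_t = self.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
                for k, wk in self.weights_.items():
                    g = acc[k] * scale
                    adam_m[k] = b1 * adam_m[k] + (1 - b1) * g
                    adam_v[k] = b2 * adam_v[k] + (1 - b2) * g * g
                    wk -= lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + eps)

            train_loss = epoch_mse / n + self._penalty()
            history["loss"].append(train_loss)

            if has_val:
                val_loss = float(np.mean(
                    [np.mean((self._predict_window(xv) - yv) ** 2)
                     for xv, yv in zip(X_val, y_val)]))
            else:
                val_loss = train_loss
            history["val_loss"].append(val_loss)
            if self.verbose and (epoch % 10 == 0 or epoch == self.max_epochs - 1):
                print(f"epoch {epoch}: loss {train_loss:.6f} val {val_loss:.6f}")

            if val_loss < best_val:
                best_val = val_loss
                best_weights = {k: v.copy() for k, v in self.weights_.items()}
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if patience is not None and wait >= patience:
                    break

        if best_weights is not None:
            self.weights_ = best_weights
        self.history_ = history
        self.n_epochs_run_ = len(history["loss"])
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_val)
        return self

    # -- inference -----------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Reconstruct one mV ECG window per PPG window, order preserved."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("model has no weights; call fit() or build() first")
        X = self._validate_xy(X)
        if X.shape[1] != self.input_length_:
            raise ValueError(f"window length {X.shape[1]} does not match the "
                             f"model input length {self.input_length_}")
        return np.stack([self._predict_window(x) for x in X])


# ---------------------------------------------------------------------------
# Functional surface

def build(config: ReconstructorConfig, input_length: int) -> BiLSTMRegressor:
    """Instantiate a reconstructor with seeded initial parameters."""
    model = BiLSTMRegressor(
        hidden_units=config.hidden_units, l1=config.l1, l2=config.l2,
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        max_epochs=config.max_epochs, early_stop_patience=config.early_stop_patience,
        seed=config.seed)
    model._init_weights(input_length)
    return model


def train(model: BiLSTMRegressor, train_set, val_set=None) -> BiLSTMRegressor:
    """Fit on a training SegmentSet (PPG -> ECG), validating on another."""
    if train_set.n_segments == 0:
        raise ValueError("empty training set")
    if val_set is not None:
        return model.fit(train_set.ppg, train_set.ecg, val_set.ppg, val_set.ecg)
    return model.fit(train_set.ppg, train_set.ecg)


def reconstruct(model: BiLSTMRegressor, ppg_segments) -> np.ndarray:
    """Map ordered PPG windows to reconstructed ECG windows."""
    ppg = ppg_segments.ppg if hasattr(ppg_segments, "ppg") else np.asarray(ppg_segments)
    if len(ppg) == 0:
        return np.empty((0, model.input_length_))
    return model.predict(ppg)


def save_model(model: BiLSTMRegressor, path: str | os.PathLike) -> None:
    """Save weights (npz) + hyperparameters (json) under a directory."""
    os.makedirs(path, exist_ok=True)
    np.savez(os.path.join(path, "weights.npz"), **model.weights_)
    meta = {"params": model.get_params(), "input_length": model.input_length_}
    with open(os.path.join(path, "config.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path: str | os.PathLike) -> BiLSTMRegressor:
    with open(os.path.join(path, "config.json")) as fh:
        meta = json.load(fh)
    model = BiLSTMRegressor(**meta["params"])
    with np.load(os.path.join(path, "weights.npz")) as npz:
        model.weights_ = {k: npz[k] for k in npz.files}
    model.input_length_ = int(meta["input_length"])
    return model
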