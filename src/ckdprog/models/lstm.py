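"""LSTM sequence classifier for progression prediction.

Architecture: a single masked LSTM layer over the padded feature-vector
sequence, followed by a stack of dense ReLU layers with dropout, and a
two-node softmax output.  Training minimizes weighted cross-entropy (control
weight 1, case weight = control/case count ratio of the training split) with
Adam and early stopping on validation loss.  The dropout rate — shared by
all dense layers — is the only tuned hyper-parameter, selected from a fixed
grid by validation loss.

Implemented directly in numpy (forward pass and backpropagation through
time); the model is small enough that this is fast on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DROPOUT_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.7)


@dataclass(frozen=True)
class LSTMConfig:
    """Hyper-parameters of the LSTM classifier.

    The all-variables variant uses a wider LSTM and a deeper dense stack
    than the essential-variables variant, reflecting the different input
    widths.  ``dropout_grid`` defaults to the full 7-point grid; experiments
    may restrict it.
    """

    variant: str = "all_variables"
    lstm_units: int = 64
    dense_layer_sizes: tuple[int, ...] = (64, 32, 16)
    dropout_grid: tuple[float, ...] = DROPOUT_GRID
    max_epochs: int = 60
    patience: int = 5
    batch_size: int = 64
    learning_rate: float = 1e-3
    max_len: int = 100
    seed: int = 0

    def validate(self) -> None:
        if any(d not in DROPOUT_GRID for d in self.dropout_grid):
            raise ValueError(f"dropout rates must come from {DROPOUT_GRID}")
        if any(s <= 0 for s in self.dense_layer_sizes):
            raise ValueError("dense layer sizes must be positive")
        if self.lstm_units <= 0:
            raise ValueError("lstm_units must be positive")

    @classmethod
    def for_variant(cls, variant: str, **overrides) -> "LSTMConfig":
        """Preset architectures for the two variable sets."""
        if variant == "essential_variables":
            base = dict(variant=variant, lstm_units=32, dense_layer_sizes=(16,))
        elif variant == "all_variables":
            base = dict(variant=variant, lstm_units=64, dense_layer_sizes=(64, 32, 16))
        else:
            raise ValueError(f"unknown variant {variant!r}")
        base.update(overrides)
        return cls(**base)


def class_weights(y: np.ndarray) -> tuple[float, float]:
    """(control_weight, case_weight): 1 and the control/case count ratio."""
    y = np.asarray(y)
    n_case = int((y == 1).sum())
    n_ctrl = int((y == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("training labels must contain both classes")
    return 1.0, n_ctrl / n_case


def _glorot(rng, fan_in, fan_out, shape):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(np.float64)


class _Params(dict):
    """Named parameter arrays with elementwise copy."""

    def copy_all(self) -> "_Params":
        return _Params({k: v.copy() for k, v in self.items()})


def _init_params(rng: np.random.Generator, D: int, H: int,
                 dense: tuple[int, ...]) -> _Params:
    p = _Params()
    p["Wx"] = _glorot(rng, D, 4 * H, (D, 4 * H))
    p["Wh"] = _glorot(rng, H, 4 * H, (H, 4 * H))
    b = np.zeros(4 * H)
    b[H:2 * H] = 1.0  # forget-gate bias
    p["b"] = b
    sizes = [H, *dense, 2]
    for li in range(len(sizes) - 1):
        p[f"W{li}"] = _glorot(rng, sizes[li], sizes[li + 1],
                              (sizes[li], sizes[li + 1]))
        p[f"b{li}"] = np.zeros(sizes[li + 1])
    return p


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _lstm_forward(p: _Params, X: np.ndarray, mask: np.ndarray, cache: bool):
    """Masked LSTM forward.  X (B,T,D), mask (B,T) float; returns final h."""
    B, T, D = X.shape
    H = p["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    caches = [] if cache else None
    xw = X.reshape(B * T, D) @ p["Wx"]
    xw = xw.reshape(B, T, 4 * H)
    for t in range(T):
        m = mask[:, t][:, None]
        z = xw[:, t] + h @ p["Wh"] + p["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        if cache:
            caches.append((h, c, i, f, g, o, tc, m))
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h
    return h, caches


def _lstm_backward(p: _Params, grads: _Params, X: np.ndarray, caches,
                   dh_final: np.ndarray) -> None:
    B, T, D = X.shape
    H = p["Wh"].shape[0]
    dh = dh_final
    dc = np.zeros_like(dh)
    dWx = np.zeros_like(p["Wx"])
    dWh = np.zeros_like(p["Wh"])
    db = np.zeros_like(p["b"])
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, i, f, g, o, tc, m = caches[t]
        dh_t = m * dh
        dc_t = m * dc
        dh_pass = (1.0 - m) * dh
        dc_pass = (1.0 - m) * dc
        do = dh_t * tc
        dct = dc_t + dh_t * o * (1.0 - tc * tc)
        di = dct * g
        df = dct * c_prev
        dg = dct * i
        dc_prev = dct * f
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g),
             do * o * (1 - o)], axis=1)
        dWx += X[:, t].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh = dz @ p["Wh"].T + dh_pass
        dc = dc_prev + dc_pass
    grads["Wx"] += dWx
    grads["Wh"] += dWh
    grads["b"] += db


def _head_forward(p: _Params, h: np.ndarray, n_dense: int, dropout: float,
                  rng: np.random.Generator | None):
    """Dense ReLU stack with inverted dropout, then softmax logits."""
    a = h
    cache = []
    for li in range(n_dense):
        z = a @ p[f"W{li}"] + p[f"b{li}"]
        r = np.maximum(z, 0.0)
        if rng is not None and dropout > 0.0:
            keep = (rng.random(r.shape) >= dropout) / (1.0 - dropout)
            rd = r * keep
        else:
            keep = None
            rd = r
        cache.append((a, z, keep))
        a = rd
    lo = n_dense
    logits = a @ p[f"W{lo}"] + p[f"b{lo}"]
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    cache.append((a, None, None))
    return probs, cache


def _head_backward(p: _Params, grads: _Params, cache, dlogits: np.ndarray,
                   n_dense: int) -> np.ndarray:
    a_last = cache[n_dense][0]
    lo = n_dense
    grads[f"W{lo}"] += a_last.T @ dlogits
    grads[f"b{lo}"] += dlogits.sum(axis=0)
    da = dlogits @ p[f"W{lo}"].T
    for li in range(n_dense - 1, -1, -1):
        a_in, z, keep = cache[li]
        if keep is not None:
            da = da * keep
        dz = da * (z > 0)
        grads[f"W{li}"] += a_in.T @ dz
        grads[f"b{li}"] += dz.sum(axis=0)
        da = dz @ p[f"W{li}"].T
    return da


class _Adam:
    def __init__(self, params: _Params, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: _Params, grads: _Params) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


class LSTMClassifier:
    """Masked-LSTM progression classifier with dropout-grid selection.

    ``fit`` trains one model per dropout rate in ``config.dropout_grid``
    (each with early stopping on validation weighted cross-entropy) and
    keeps the rate with the best validation loss.  ``selected_dropout`` and
    ``epochs_run`` are recorded after fitting.
    """

    kind = "lstm"

    def __init__(self, config: LSTMConfig = LSTMConfig()):
        config.validate()
        self.config = config
        self.params: _Params | None = None
        self.selected_dropout: float | None = None
        self.epochs_run: int | None = None
        self.weights_: tuple[float, float] | None = None

    # -- loss helpers -------------------------------------------------

    def _loss_and_dlogits(self, probs, y, w):
        B = len(y)
        wi = np.where(y == 1, w[1], w[0])
        eps = 1e-12
        ce = -np.log(probs[np.arange(B), y] + eps)
        loss = float((wi * ce).sum() / B)
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), y] = 1.0
        dlogits = (probs - onehot) * wi[:, None] / B
        return loss, dlogits

    def _eval_loss(self, params, X, mask, y, w):
        h, _ = _lstm_forward(params, X, mask, cache=False)
        probs, _ = _head_forward(params, h, len(self.config.dense_layer_sizes),
                                 0.0, None)
        loss, _ = self._loss_and_dlogits(probs, y, w)
        return loss

    def _train_one(self, X, mask, y, Xv, maskv, yv, dropout, seed):
        cfg = self.config
        rng = np.random.default_rng(seed)
        D = X.shape[2]
        params = _init_params(rng, D, cfg.lstm_units, cfg.dense_layer_sizes)
        opt = _Adam(params, cfg.learning_rate)
        w = class_weights(y)
        n_dense = len(cfg.dense_layer_sizes)

        best_loss = np.inf
        best_params = params.copy_all()
        best_epoch = 0
        since_improve = 0
        lr_patience = max(2, cfg.patience // 2)
        n = len(y)
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            for s in range(0, n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                Xb, mb, yb = X[idx], mask[idx], y[idx]
                h, caches = _lstm_forward(params, Xb, mb, cache=True)
                probs, hcache = _head_forward(params, h, n_dense, dropout, rng)
                _, dlogits = self._loss_and_dlogits(probs, yb, w)
                grads = _Params({k: np.zeros_like(v) for k, v in params.items()})
                dh = _head_backward(params, grads, hcache, dlogits, n_dense)
                _lstm_backward(params, grads, Xb, caches, dh)
                opt.step(params, grads)
            val_loss = self._eval_loss(params, Xv, maskv, yv, w)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = params.copy_all()
                best_epoch = epoch + 1
                since_improve = 0
            else:
                since_improve += 1
                if since_improve > cfg.patience:
                    break
                # plateau: restart from the best weights at a halved rate
                if since_improve % lr_patience == 0 and opt.lr > 1e-4:
                    params = best_params.copy_all()
                    opt.lr *= 0.5
        return best_params, best_loss, best_epoch, w

    def fit(self, X, seq_mask, y, X_val, seq_mask_val, y_val) -> "LSTMClassifier":
        """Train over the dropout grid; keep the best-validation-loss model."""
        X = np.asarray(X, dtype=np.float64)
        X_val = np.asarray(X_val, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        y_val = np.asarray(y_val, dtype=int)
        if X.shape[1] > self.config.max_len:
            raise ValueError(
                f"sequence length {X.shape[1]} exceeds max_len {self.config.max_len}")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels must contain both classes")
        mask = np.asarray(seq_mask, dtype=np.float64)
        maskv = np.asarray(seq_mask_val, dtype=np.float64)

        best = None
        for k, dropout in enumerate(self.config.dropout_grid):
            params, loss, epochs, w = self._train_one(
                X, mask, y, X_val, maskv, y_val, dropout, self.config.seed)
            if best is None or loss < best[1]:
                best = (params, loss, epochs, w, dropout)
        self.params, _, self.epochs_run, self.weights_, self.selected_dropout = best
        return self

    def predict_proba(self, X, seq_mask) -> np.ndarray:
        """Softmax class probabilities, shape (n, 2); rows sum to one."""
        if self.params is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=np.float64)
        mask = np.asarray(seq_mask, dtype=np.float64)
        h, _ = _lstm_forward(self.params, X, mask, cache=False)
        probs, _ = _head_forward(self.params, h,
                                 len(self.config.dense_layer_sizes), 0.0, None)
        return probs

    def score(self, X, seq_mask) -> np.ndarray:
        """Predicted progression probability per patient."""
        return self.predict_proba(X, seq_mask)[:, 1]
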