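"""Feedforward and LSTM regressors mapping IMU gait cycles to EMG envelopes.

Two estimators, one per muscle:

* **FNN** — the 101x24 cycle flattened to a 2424-vector, then a stack of
  fully connected hidden layers (tanh) with a dropout layer between each,
  and a 101-unit sigmoid output layer (one value per % of gait cycle).
* **LSTM** — the cycle consumed as a 101-step sequence of 24-channel
  vectors through stacked LSTM layers (dropout between layers); the final
  step's hidden state feeds the 101-unit sigmoid output layer.

Both minimize mean squared error with the Adam optimizer and early-stop on
validation loss.  The implementation is plain numpy with hand-written
gradients (backpropagation through time for the LSTM), which keeps the
package dependency-light and fully deterministic under a seed; correctness
is pinned by numerical gradient checks and closed-form parameter counts in
the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

N_OUTPUT = 101


@dataclass
class ModelConfig:
    architecture: str = "lstm"            # 'fnn' | 'lstm'
    hidden_layers: int = 4
    hidden_units: int = 256
    dropout_rate: float = 0.2
    hidden_activation: str = "tanh"
    output_activation: str = "sigmoid"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 300
    early_stop_patience: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("fnn", "lstm"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.hidden_layers < 1:
            raise ValueError("hidden_layers must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.hidden_activation != "tanh" or self.output_activation != "sigmoid":
            raise ValueError("supported activations: hidden 'tanh', output 'sigmoid'")
        if self.optimizer != "adam":
            raise ValueError("supported optimizer: 'adam'")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


class _BaseEstimator:
    """Shared training loop: minibatch Adam + early stopping on val MSE."""

    #: training/inference dtype; float32 is precise enough for these
    #: regressions and roughly halves CPU time (tests override to float64
    #: for numerical gradient checks)
    dtype = np.float32

    def __init__(self, config: ModelConfig, input_shape: tuple):
        self.config = config
        self.input_shape = tuple(input_shape)
        self.muscle: str | None = None
        self.history: dict = {"train_loss": [], "val_loss": []}
        self.params: dict = {}
        self._rng = np.random.default_rng(config.seed)
        self._init_params()
        self.params = {k: v.astype(self.dtype) for k, v in self.params.items()}

    # subclass hooks -------------------------------------------------------
    def _init_params(self) -> None:
        raise NotImplementedError

    def _forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, object]:
        raise NotImplementedError

    def _backward(self, cache, dy: np.ndarray) -> dict:
        raise NotImplementedError

    # ----------------------------------------------------------------------
    @property
    def num_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        x = np.asarray(x, dtype=self.params["by" if "by" in self.params else "b0"].dtype)
        single = x.ndim == len(self.input_shape)
        if single:
            x = x[None]
        out = np.concatenate(
            [self._forward(x[i: i + batch_size], train=False)[0]
             for i in range(0, len(x), batch_size)]
        )
        return out[0] if single else out

    def _loss(self, y_hat: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean((y_hat - y) ** 2))

    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
    ) -> "_BaseEstimator":
        cfg = self.config
        dt = next(iter(self.params.values())).dtype
        x_train = np.asarray(x_train, dtype=dt)
        y_train = np.asarray(y_train, dtype=dt)
        x_val = np.asarray(x_val, dtype=dt)
        y_val = np.asarray(y_val, dtype=dt)
        opt = _Adam(self.params, cfg.learning_rate)
        best_val = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        stale = 0
        n = len(x_train)
        for epoch in range(cfg.max_epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for bi, i in enumerate(range(0, n, cfg.batch_size)):
                idx = order[i: i + cfg.batch_size]
                xb, yb = x_train[idx], y_train[idx]
                y_hat, cache = self._forward(xb, train=True)
                loss = self._loss(y_hat, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {bi} "
                        f"(learning rate {cfg.learning_rate:g}); "
                        "lower the learning rate or inspect the inputs"
                    )
                dy = 2.0 * (y_hat - yb) / y_hat.size
                grads = self._backward(cache, dy)
                opt.step(self.params, grads)
                epoch_loss += loss * len(idx)
            val_loss = self._loss(self.predict(x_val), y_val)
            self.history["train_loss"].append(epoch_loss / n)
            self.history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stop_patience:
                    break
        self.params = best_params
        return self

    # persistence ----------------------------------------------------------
    def save(self, path: Path) -> None:
        """Weights as .npz plus a sidecar .json with config and history."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {
            "config": asdict(self.config),
            "input_shape": list(self.input_shape),
            "muscle": self.muscle,
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: Path) -> "_BaseEstimator":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        est = build_estimator(ModelConfig(**meta["config"]), meta["input_shape"])
        with np.load(path.with_suffix(".npz")) as data:
            est.params = {k: data[k] for k in data.files}
        est.muscle = meta["muscle"]
        est.history = meta["history"]
        return est


class FNNEstimator(_BaseEstimator):
    """Dense network on the flattened 101x24 cycle."""

    def _init_params(self) -> None:
        cfg = self.config
        n_in = int(np.prod(self.input_shape))
        dims = [n_in] + [cfg.hidden_units] * cfg.hidden_layers + [N_OUTPUT]
        for li, (d0, d1) in enumerate(zip(dims[:-1], dims[1:])):
            # Glorot init, suited to tanh/sigmoid units
            limit = np.sqrt(6.0 / (d0 + d1))
            self.params[f"W{li}"] = self._rng.uniform(-limit, limit, size=(d0, d1))
            self.params[f"b{li}"] = np.zeros(d1)
        self._n_layers = len(dims) - 1

    def _forward(self, x: np.ndarray, train: bool):
        cfg = self.config
        h = np.asarray(x, dtype=self.params["b0"].dtype).reshape(len(x), -1)
        acts, masks = [h], []
        for li in range(self._n_layers - 1):
            h = np.tanh(h @ self.params[f"W{li}"] + self.params[f"b{li}"])
            if train and cfg.dropout_rate > 0:
                keep = 1.0 - cfg.dropout_rate
                mask = ((self._rng.random(h.shape) < keep) / keep).astype(h.dtype)
                h = h * mask
            else:
                mask = None
            masks.append(mask)
            acts.append(h)
        lo = self._n_layers - 1
        y = _sigmoid(h @ self.params[f"W{lo}"] + self.params[f"b{lo}"])
        return y, (acts, masks, y)

    def _backward(self, cache, dy: np.ndarray) -> dict:
        acts, masks, y = cache
        grads: dict = {}
        lo = self._n_layers - 1
        dz = dy * y * (1.0 - y)
        grads[f"W{lo}"] = acts[-1].T @ dz
        grads[f"b{lo}"] = dz.sum(axis=0)
        dh = dz @ self.params[f"W{lo}"].T
        for li in range(self._n_layers - 2, -1, -1):
            if masks[li] is not None:
                dh = dh * masks[li]
            h = acts[li + 1]
            # undo dropout scaling to recover tanh output for the derivative
            a = h if masks[li] is None else h / np.where(masks[li] == 0, 1.0, masks[li])
            dz = dh * (1.0 - a * a)
            grads[f"W{li}"] = acts[li].T @ dz
            grads[f"b{li}"] = dz.sum(axis=0)
            if li > 0:
                dh = dz @ self.params[f"W{li}"].T
        return grads


class LSTMEstimator(_BaseEstimator):
    """Stacked LSTM over the 101-step sequence; final hidden state -> output."""

    def _init_params(self) -> None:
        cfg = self.config
        n_in = self.input_shape[-1]
        h = cfg.hidden_units
        dims = [n_in] + [h] * cfg.hidden_layers
        for li, (d0, d1) in enumerate(zip(dims[:-1], dims[1:])):
            lim_x = np.sqrt(6.0 / (d0 + d1))
            self.params[f"Wx{li}"] = self._rng.uniform(-lim_x, lim_x, size=(d0, 4 * d1))
            self.params[f"Wh{li}"] = self._rng.uniform(
                -np.sqrt(6.0 / (2 * d1)), np.sqrt(6.0 / (2 * d1)), size=(d1, 4 * d1)
            )
            b = np.zeros(4 * d1)
            b[d1: 2 * d1] = 1.0  # forget-gate bias: retain memory early in training
            self.params[f"b{li}"] = b
        lim = np.sqrt(6.0 / (h + N_OUTPUT))
        self.params["Wy"] = self._rng.uniform(-lim, lim, size=(h, N_OUTPUT))
        self.params["by"] = np.zeros(N_OUTPUT)

    # gate column layout: [i | f | o | g] — the three sigmoid gates are
    # contiguous, so each step needs one sigmoid over (B, 3H) and one tanh
    def _layer_forward(self, x_seq: np.ndarray, li: int):
        """x_seq: (T, B, d_in) -> h_seq (T, B, H) plus per-step caches."""
        Wx, Wh, b = (self.params[f"Wx{li}"], self.params[f"Wh{li}"],
                     self.params[f"b{li}"])
        T, B, _ = x_seq.shape
        H = Wh.shape[0]
        dt = Wh.dtype
        h = np.zeros((B, H), dt)
        c = np.zeros((B, H), dt)
        h_seq = np.empty((T, B, H), dt)
        gates = np.empty((T, B, 4 * H), dt)
        c_seq = np.empty((T, B, H), dt)
        tc_seq = np.empty((T, B, H), dt)
        xz = x_seq @ Wx + b  # input contribution for all steps at once
        for t in range(T):
            z = xz[t] + h @ Wh
            z[:, : 3 * H] = _sigmoid(z[:, : 3 * H])
            z[:, 3 * H:] = np.tanh(z[:, 3 * H:])
            i, f = z[:, :H], z[:, H: 2 * H]
            o, g = z[:, 2 * H: 3 * H], z[:, 3 * H:]
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            gates[t] = z
            c_seq[t] = c
            tc_seq[t] = tc
            h_seq[t] = h
        return h_seq, (gates, c_seq, tc_seq)

    def _layer_backward(self, x_seq, h_seq, cache, li: int, dh_seq):
        Wx, Wh = self.params[f"Wx{li}"], self.params[f"Wh{li}"]
        gates, c_seq, tc_seq = cache
        T, B, H = h_seq.shape
        dt = Wh.dtype
        dz_seq = np.empty((T, B, 4 * H), dt)
        dh_next = np.zeros((B, H), dt)
        dc = np.zeros((B, H), dt)
        for t in range(T - 1, -1, -1):
            z = gates[t]
            i, f = z[:, :H], z[:, H: 2 * H]
            o, g = z[:, 2 * H: 3 * H], z[:, 3 * H:]
            tc = tc_seq[t]
            c_prev = c_seq[t - 1] if t > 0 else np.zeros((B, H), dt)
            dh = dh_seq[t] + dh_next
            dc = dc + dh * o * (1.0 - tc * tc)
            dz = dz_seq[t]
            dz[:, :H] = dc * g * i * (1 - i)
            dz[:, H: 2 * H] = dc * c_prev * f * (1 - f)
            dz[:, 2 * H: 3 * H] = dh * tc * o * (1 - o)
            dz[:, 3 * H:] = dc * i * (1 - g * g)
            dh_next = dz @ Wh.T
            dc = dc * f
        # weight gradients batched over all steps (recurrence already unrolled)
        dWx = np.tensordot(x_seq, dz_seq, axes=([0, 1], [0, 1]))
        h_prev_seq = np.concatenate([np.zeros((1, B, H), dt), h_seq[:-1]])
        dWh = np.tensordot(h_prev_seq, dz_seq, axes=([0, 1], [0, 1]))
        db = dz_seq.sum(axis=(0, 1))
        dx_seq = dz_seq @ Wx.T
        return dx_seq, {f"Wx{li}": dWx, f"Wh{li}": dWh, f"b{li}": db}

    def _forward(self, x: np.ndarray, train: bool):
        cfg = self.config
        dt = self.params["by"].dtype
        x_seq = np.transpose(np.asarray(x, dtype=dt), (1, 0, 2))  # (T, B, C)
        layers = []
        for li in range(cfg.hidden_layers):
            h_seq, steps = self._layer_forward(x_seq, li)
            if train and cfg.dropout_rate > 0:
                keep = 1.0 - cfg.dropout_rate
                mask = ((self._rng.random(h_seq.shape) < keep) / keep).astype(h_seq.dtype)
                out_seq = h_seq * mask
            else:
                mask = None
                out_seq = h_seq
            layers.append((x_seq, h_seq, steps, mask))
            x_seq = out_seq
        h_last = x_seq[-1]
        y = _sigmoid(h_last @ self.params["Wy"] + self.params["by"])
        return y, (layers, h_last, y)

    def _backward(self, cache, dy: np.ndarray) -> dict:
        layers, h_last, y = cache
        grads: dict = {}
        dz = dy * y * (1.0 - y)
        grads["Wy"] = h_last.T @ dz
        grads["by"] = dz.sum(axis=0)
        dout = dz @ self.params["Wy"].T
        T = layers[0][1].shape[0]
        dh_seq = np.zeros_like(layers[-1][1])
        dh_seq[T - 1] = dout
        for li in range(len(layers) - 1, -1, -1):
            x_seq, h_seq, steps, mask = layers[li]
            if mask is not None:
                dh_seq = dh_seq * mask
            dx_seq, g = self._layer_backward(x_seq, h_seq, steps, li, dh_seq)
            grads.update(g)
            dh_seq = dx_seq
        return grads


def load_estimator(path: Path) -> _BaseEstimator:
    """Load a saved estimator (``.npz`` weights + ``.json`` sidecar)."""
    return _BaseEstimator.load(path)


def build_estimator(config: ModelConfig, input_shape: tuple) -> _BaseEstimator:
    """Untrained estimator for the given architecture and input shape."""
    if config.architecture == "fnn":
        return FNNEstimator(config, input_shape)
    if config.architecture == "lstm":
        return LSTMEstimator(config, input_shape)
    raise ValueError(f"unknown architecture {config.architecture!r}")


def train(estimator: _BaseEstimator, split, muscle: str) -> _BaseEstimator:
    """Fit one estimator on a DatasetSplit for one muscle."""
    from .datasets import stack_features, stack_targets

    if not split.train or not split.validation:
        raise ValueError("split must have non-empty train and validation groups")
    if muscle not in split.train[0].targets:
        raise KeyError(f"muscle {muscle!r} absent from the sample targets")
    flat = estimator.config.architecture == "fnn"
    estimator.muscle = muscle
    estimator.fit(
        stack_features(split.train, flatten=flat),
        stack_targets(split.train, muscle),
        stack_features(split.validation, flatten=flat),
        stack_targets(split.validation, muscle),
    )
    return estimator
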