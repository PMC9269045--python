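"""LSTM sequence regressor for joint-angle estimation, in pure numpy.

The recurrence is the classic forget-gate LSTM:

    f(t) = sigmoid(W1f x(t) + W2f h(t-1) + bf)
    i(t) = sigmoid(W1i x(t) + W2i h(t-1) + bi)
    o(t) = sigmoid(W1o x(t) + W2o h(t-1) + bo)
    g(t) = tanh   (W1g x(t) + W2g h(t-1) + bg)
    s(t) = g(t) * i(t) + s(t-1) * f(t)
    h(t) = tanh(s(t)) * o(t)

with a one-unit linear output y(t) = Wy h(t) + by and zero initial
hidden and cell state.  Training minimizes mean squared error by
truncated backpropagation through time over fixed-length windows with
an Adam optimizer; everything is deterministic given the seed.

Targets are standardized internally with training statistics so the
optimizer sees unit-scale residuals; predictions are returned in
degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import SequenceDataset

GATES = ("f", "i", "o", "g")


@dataclass(frozen=True)
class LstmConfig:
    hidden: int = 50
    epochs: int = 50
    learning_rate: float = 1e-3
    window: int = 200
    batch_size: int = 16
    grad_clip: float = 5.0
    seed: int = 0


def init_params(n_channels: int, hidden: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    r = 1.0 / np.sqrt(hidden)
    p = {
        "Wx": rng.uniform(-r, r, (4 * hidden, n_channels)),
        "Wh": rng.uniform(-r, r, (4 * hidden, hidden)),
        "b": np.zeros(4 * hidden),
        "Wy": rng.uniform(-r, r, (1, hidden)),
        "by": np.zeros(1),
    }
    p["b"][:hidden] = 1.0  # forget-gate bias: start remembering
    return p


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def lstm_forward(
    params: dict[str, np.ndarray], X: np.ndarray, return_states: bool = False
):
    """Run the LSTM over an input batch.

    ``X`` is (T, C) or (B, T, C); returns predictions of shape (T,) or
    (B, T) (plus the per-step gate/state cache when requested).
    """
    single = X.ndim == 2
    Xb = X[None, ...] if single else X
    B, T, C = Xb.shape
    H = params["Wh"].shape[1]
    h = np.zeros((B, H))
    s = np.zeros((B, H))
    ys = np.empty((B, T))
    cache = []
    for t in range(T):
        z = Xb[:, t, :] @ params["Wx"].T + h @ params["Wh"].T + params["b"]
        zf, zi, zo, zg = np.split(z, 4, axis=1)
        f, i, o = _sigmoid(zf), _sigmoid(zi), _sigmoid(zo)
        g = np.tanh(zg)
        s_prev = s
        s = g * i + s_prev * f
        ts = np.tanh(s)
        h_prev = h
        h = ts * o
        ys[:, t] = (h @ params["Wy"].T + params["by"])[:, 0]
        if return_states:
            cache.append((f, i, o, g, s_prev, s, ts, h_prev, h))
    ys = ys[0] if single else ys
    return (ys, cache) if return_states else ys


def _backward(params, Xb, targets, preds, cache):
    """Gradients of mean squared error w.r.t. all parameters."""
    B, T, C = Xb.shape
    H = params["Wh"].shape[1]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dh_carry = np.zeros((B, H))
    ds_carry = np.zeros((B, H))
    dy = 2.0 * (preds - targets) / (B * T)  # (B, T)
    for t in range(T - 1, -1, -1):
        f, i, o, g, s_prev, s, ts, h_prev, h = cache[t]
        dyt = dy[:, t : t + 1]
        grads["Wy"] += dyt.T @ h
        grads["by"] += dyt.sum(axis=0)
        dh = dyt @ params["Wy"] + dh_carry
        do = dh * ts
        ds = dh * o * (1.0 - ts**2) + ds_carry
        df = ds * s_prev
        di = ds * g
        dg = ds * i
        ds_carry = ds * f
        dz = np.concatenate(
            [
                df * f * (1.0 - f),
                di * i * (1.0 - i),
                do * o * (1.0 - o),
                dg * (1.0 - g**2),
            ],
            axis=1,
        )
        grads["Wx"] += dz.T @ Xb[:, t, :]
        grads["Wh"] += dz.T @ h_prev
        grads["b"] += dz.sum(axis=0)
        dh_carry = dz @ params["Wh"]
    return grads


def _make_windows(ds: SequenceDataset, window: int) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for s in ds.subjects:
        X, y = ds.inputs[s], ds.targets[s]
        T = len(y)
        if T < window:
            xs.append(X[None, ...])
            ys.append(y[None, ...])
            continue
        n_win = T // window
        xs.append(X[: n_win * window].reshape(n_win, window, -1))
        ys.append(y[: n_win * window].reshape(n_win, window))
    widths = {x.shape[1] for x in xs}
    if len(widths) > 1:  # ragged short subjects: fall back to the minimum
        w = min(widths)
        xs = [x[:, :w, :] for x in xs]
        ys = [y[:, :w] for y in ys]
    return np.concatenate(xs), np.concatenate(ys)


class LstmSynergy:
    """LSTM synergy model (statsmodels-style Model class).

    ``fit`` trains on all subjects in ``dataset`` and returns a
    :class:`LstmSynergyResults` carrying the trained weights, the loss
    history and prediction/summary methods.
    """

    def __init__(self, dataset: SequenceDataset, config: LstmConfig | None = None):
        if len(dataset.subjects) < 1:
            raise ValueError("training dataset is empty")
        self.dataset = dataset
        self.config = config or LstmConfig()

    def fit(self, seed: int | None = None) -> "LstmSynergyResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        Xw, Yw = _make_windows(self.dataset, cfg.window)
        y_mean = float(Yw.mean())
        y_sd = float(Yw.std())
        if y_sd < 1e-12:
            y_sd = 1.0
        Yn = (Yw - y_mean) / y_sd

        params = init_params(Xw.shape[2], cfg.hidden, rng)
        adam_m = {k: np.zeros_like(v) for k, v in params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in params.items()}
        step = 0
        losses = []
        n_win = Xw.shape[0]
        bs = min(cfg.batch_size, n_win)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n_win)
            epoch_loss = 0.0
            for lo in range(0, n_win, bs):
                idx = order[lo : lo + bs]
                xb, yb = Xw[idx], Yn[idx]
                preds, cache = lstm_forward(params, xb, return_states=True)
                loss = float(np.mean((preds - yb) ** 2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        "LSTM training diverged (non-finite loss); "
                        "reduce the learning rate or gradient-clip threshold"
                    )
                epoch_loss += loss * len(idx)
                grads = _backward(params, xb, yb, preds, cache)
                norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
                if norm > cfg.grad_clip:
                    scale = cfg.grad_clip / norm
                    grads = {k: g * scale for k, g in grads.items()}
                step += 1
                for k in params:
                    adam_m[k] = 0.9 * adam_m[k] + 0.1 * grads[k]
                    adam_v[k] = 0.999 * adam_v[k] + 0.001 * grads[k] ** 2
                    m_hat = adam_m[k] / (1.0 - 0.9**step)
                    v_hat = adam_v[k] / (1.0 - 0.999**step)
                    params[k] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + 1e-8)
            losses.append(epoch_loss / n_win)
        return LstmSynergyResults(
            model=self,
            params=params,
            target_mean=y_mean,
            target_sd=y_sd,
            loss_history=np.asarray(losses),
            seed=seed,
        )


@dataclass
class LstmSynergyResults:
    """Trained LSTM synergy estimator."""

    model: LstmSynergy | None
    params: dict[str, np.ndarray]
    target_mean: float = 0.0
    target_sd: float = 1.0
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int = 0

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        """Estimate the target series (degrees) for an input matrix (T, C)."""
        inputs = np.asarray(inputs, dtype=float)
        if inputs.shape[-1] != self.params["Wx"].shape[1]:
            raise ValueError("input channel count does not match the fitted model")
        return lstm_forward(self.params, inputs) * self.target_sd + self.target_mean

    def summary(self) -> pd.DataFrame:
        cfg = self.model.config if self.model is not None else LstmConfig()
        rows = {
            "hidden_units": self.params["Wh"].shape[1],
            "epochs": cfg.epochs,
            "final_training_mse": float(self.loss_history[-1]) if len(self.loss_history) else float("nan"),
            "seed": self.seed,
        }
        return pd.DataFrame({"value": rows})
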