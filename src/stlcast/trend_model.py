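"""LSTM forecaster for the trend component.

The STL trend of a microclimate channel varies slowly and has a small
standard deviation, so a deliberately small recurrent model suffices: one
LSTM layer (default hidden size 4) over the trend windows of *all* input
channels, followed by a dense head that emits the ``pred_len`` future trend
values of the target channel in one shot (direct multi-output strategy).

:func:`lstm_cell_step` exposes the bare gate equations on plain numpy arrays;
the trainable :class:`TrendModel` runs the same recurrence on the package's
autodiff tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Parameter, Tensor, uniform_fan_in
from .data_io import WindowBatch

__all__ = ["LSTMCellWeights", "TrendModelConfig", "lstm_cell_step", "TrendModel", "train_trend", "predict_trend"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LSTMCellWeights:
    """Gate weights for a single LSTM cell.

    Each gate g ∈ {f, i, g, o} has an input matrix ``Wx_g`` [C_in, H], a
    recurrent matrix ``Wh_g`` [H, H] and a bias ``b_g`` [H].
    """

    Wx_f: np.ndarray; Wh_f: np.ndarray; b_f: np.ndarray
    Wx_i: np.ndarray; Wh_i: np.ndarray; b_i: np.ndarray
    Wx_g: np.ndarray; Wh_g: np.ndarray; b_g: np.ndarray
    Wx_o: np.ndarray; Wh_o: np.ndarray; b_o: np.ndarray

    def __post_init__(self):
        C, H = self.Wx_f.shape
        for name in ("f", "i", "g", "o"):
            if getattr(self, f"Wx_{name}").shape != (C, H):
                raise ValueError("inconsistent input-weight shapes")
            if getattr(self, f"Wh_{name}").shape != (H, H):
                raise ValueError("inconsistent recurrent-weight shapes")
            if getattr(self, f"b_{name}").shape != (H,):
                raise ValueError("inconsistent bias shapes")

    @property
    def hidden_size(self) -> int:
        return self.Wx_f.shape[1]

    @property
    def input_size(self) -> int:
        return self.Wx_f.shape[0]


def lstm_cell_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, w: LSTMCellWeights
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the LSTM gate equations.

    f, i, o = σ(affine); g = tanh(affine); c_t = f⊙c_prev + i⊙g;
    h_t = o⊙tanh(c_t).  The forget gate decides what of the previous cell
    state survives, the input gate admits the candidate update, and the
    output gate exposes the (squashed) state as the hidden value.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    if x_t.shape[-1] != w.input_size or h_prev.shape[-1] != w.hidden_size:
        raise ValueError("input/hidden shapes do not match the weights")
    if h_prev.shape != c_prev.shape:
        raise ValueError("h_prev and c_prev shapes differ")
    f = _sigmoid(x_t @ w.Wx_f + h_prev @ w.Wh_f + w.b_f)
    i = _sigmoid(x_t @ w.Wx_i + h_prev @ w.Wh_i + w.b_i)
    g = np.tanh(x_t @ w.Wx_g + h_prev @ w.Wh_g + w.b_g)
    o = _sigmoid(x_t @ w.Wx_o + h_prev @ w.Wh_o + w.b_o)
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


@dataclass
class TrendModelConfig:
    """Configuration of the trend LSTM.

    ``hidden_size`` defaults to 4 — the small recurrent width appropriate for
    the low-variance trend.  Training settings mirror the residual model's:
    Adam, initial rate 1e-3 halved each epoch, batch 96, 6 epochs, MSE loss.
    """

    input_size: int = 3
    hidden_size: int = 4
    pred_len: int = 7
    num_layers: int = 1
    lr: float = 1e-3
    epochs: int = 6
    batch_size: int = 96
    steps_per_epoch: int | None = None

    def __post_init__(self):
        if min(self.input_size, self.hidden_size, self.pred_len, self.num_layers) < 1:
            raise ValueError("all sizes must be positive")


def _epoch_batches(n: int, batch_size: int, steps_per_epoch: int | None,
                   rng: np.random.Generator):
    """Yield index batches for one epoch.

    By default one shuffled pass over the ``n`` windows.  With
    ``steps_per_epoch`` set, exactly that many batches are drawn by cycling
    reshuffled passes — this holds the optimization trajectory (step count
    and learning-rate schedule) fixed when the training set is scaled down.
    """
    order = rng.permutation(n)
    pos = 0
    n_steps = steps_per_epoch if steps_per_epoch else int(np.ceil(n / batch_size))
    for _ in range(n_steps):
        if pos >= n:
            order = rng.permutation(n)
            pos = 0
        yield order[pos : pos + batch_size]
        pos += batch_size


class TrendModel:
    """Stacked-able LSTM + dense multi-output head on autodiff tensors."""

    def __init__(self, cfg: TrendModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.layers: list[dict[str, Parameter]] = []
        in_size = cfg.input_size
        H = cfg.hidden_size
        for _ in range(cfg.num_layers):
            fan = in_size + H
            layer = {}
            for gate in ("f", "i", "g", "o"):
                layer[f"Wx_{gate}"] = uniform_fan_in(rng, (in_size, H), fan)
                layer[f"Wh_{gate}"] = uniform_fan_in(rng, (H, H), fan)
                layer[f"b_{gate}"] = uniform_fan_in(rng, (H,), fan)
            self.layers.append(layer)
            in_size = H
        # near-zero head: the untrained model forecasts ≈0, which is the
        # right starting point for increment-style targets
        self.W_out = uniform_fan_in(rng, (H, cfg.pred_len), H)
        self.W_out.data *= 0.01
        self.b_out = uniform_fan_in(rng, (cfg.pred_len,), H)
        self.b_out.data *= 0.01
        self.loss_history: list[float] = []
        self.lr_history: list[float] = []

    def parameters(self) -> list[Parameter]:
        ps = [p for layer in self.layers for p in layer.values()]
        return ps + [self.W_out, self.b_out]

    def cell_weights(self, layer: int = 0) -> LSTMCellWeights:
        """The numpy view of one layer's gates (for the plain-cell oracle)."""
        L = self.layers[layer]
        return LSTMCellWeights(**{k: v.data for k, v in L.items()})

    def forward(self, enc_x: np.ndarray | Tensor) -> Tensor:
        """enc_x [B, seq_len, C_in] → prediction [B, pred_len]."""
        x = Tensor.as_tensor(enc_x)
        if x.shape[-1] != self.cfg.input_size:
            raise ValueError("enc_x channel count does not match the model")
        B, L, _ = x.shape
        H = self.cfg.hidden_size
        seq = [x[:, t, :] for t in range(L)]
        for layer in self.layers:
            h = Tensor(np.zeros((B, H)))
            c = Tensor(np.zeros((B, H)))
            outs = []
            for x_t in seq:
                f = (x_t @ layer["Wx_f"] + h @ layer["Wh_f"] + layer["b_f"]).sigmoid()
                i = (x_t @ layer["Wx_i"] + h @ layer["Wh_i"] + layer["b_i"]).sigmoid()
                g = (x_t @ layer["Wx_g"] + h @ layer["Wh_g"] + layer["b_g"]).tanh()
                o = (x_t @ layer["Wx_o"] + h @ layer["Wh_o"] + layer["b_o"]).sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                outs.append(h)
            seq = outs
        return seq[-1] @ self.W_out + self.b_out


def train_trend(windows: WindowBatch, cfg: TrendModelConfig, seed: int = 0,
                inputs: np.ndarray | None = None,
                targets: np.ndarray | None = None) -> TrendModel:
    """Train the trend LSTM on (trend-component) windows.

    ``inputs``/``targets`` default to ``windows.enc_x`` / ``windows.target``.
    Per-epoch learning rate is ``cfg.lr · 0.5^(epoch−1)``; the per-epoch mean
    batch loss is recorded on ``model.loss_history``.  ``epochs=0`` returns
    the untrained (freshly initialized) model.
    """
    X = windows.enc_x if inputs is None else inputs
    Y = windows.target if targets is None else targets
    if X.shape[0] == 0:
        raise ValueError("empty window batch")
    model = TrendModel(cfg, seed=seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(seed + 1)
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * 0.5**epoch
        model.lr_history.append(opt.lr)
        losses = []
        for idx in _epoch_batches(n, cfg.batch_size, cfg.steps_per_epoch, rng):
            pred = model.forward(X[idx])
            err = pred - Tensor(Y[idx])
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.loss_history.append(float(np.mean(losses)))
    return model


def predict_trend(model: TrendModel, enc_x: np.ndarray) -> np.ndarray:
    """Forecast ``pred_len`` trend values from one or more encoder windows.

    Accepts ``[seq_len, C_in]`` (returns ``[pred_len]``) or a batch
    ``[B, seq_len, C_in]`` (returns ``[B, pred_len]``).  Deterministic given
    fixed weights.
    """
    x = np.asarray(enc_x, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    out = model.forward(x).data
    return out[0] if single else out
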