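"""Miniature Informer-style encoder–decoder for the residual component.

The STL residual of a microclimate channel is the irregular, strongly
cross-coupled part of the signal; it is forecast with a compact
encoder–decoder attention network in the Informer family:

* input embedding = value projection + calendar-feature projection +
  sinusoidal positional encoding;
* encoder: a pyramid of replicas on progressively halved input lengths,
  each replica a multi-head ProbSparse self-attention layer followed by a
  distillation block (conv1d + nonlinearity + stride-2 max-pool); replica
  outputs are concatenated along the length axis into the feature sequence
  ``Ve``;
* decoder: one layer of causal (masked) ProbSparse self-attention over the
  ``label_len + pred_len`` context, full cross-attention against ``Ve``, a
  position-wise feed-forward sublayer, and a dense head; the forecast is the
  last ``pred_len`` positions — one-shot generative decoding, no
  autoregression.

ProbSparse attention scores each query by max−mean of its scaled dot
products; only the top-u queries (u = c·⌈ln L_Q⌉) receive exact softmax
attention, the rest fall back to the (cumulative, if causal) mean of the
values.  Scores are computed exactly — no key subsampling — because desk-
scale sequence lengths are small and exactness makes the full-attention
equivalence testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Parameter, Tensor, concatenate, uniform_fan_in
from .data_io import N_TIME_FEATURES, WindowBatch

__all__ = [
    "InformerConfig",
    "full_attention",
    "prob_sparse_attention",
    "positional_encoding",
    "Embedding",
    "DistillBlock",
    "InformerModel",
    "train_residual",
]

_NEG_INF = -1e30


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class InformerConfig:
    """Architecture and training settings.

    Defaults follow the full-size profile (d_model 512, 8 heads, encoder
    stack levels (3, 2, 1), one full-attention decoder layer, sampling factor
    5, dropout 0.05; Adam at 1e-3 halved each epoch, batch 96, 6 epochs, MSE
    loss).  ``reduced()`` gives the desk-scale test profile (d_model 32,
    2 heads).
    """

    input_size: int = 3
    pred_len: int = 7
    d_model: int = 512
    n_heads: int = 8
    stack_levels: tuple[int, ...] = (3, 2, 1)
    enc_attention_layers: int = 1
    distill: bool = True
    factor_c: int = 5
    d_ff: int | None = None
    dropout: float = 0.05
    lr: float = 1e-3
    epochs: int = 6
    batch_size: int = 96
    steps_per_epoch: int | None = None

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if min(self.input_size, self.pred_len, self.d_model, self.n_heads,
               self.factor_c, self.enc_attention_layers) < 1:
            raise ValueError("all counts must be positive")
        if self.d_ff is None:
            self.d_ff = self.d_model

    @classmethod
    def reduced(cls, **kw) -> "InformerConfig":
        """Desk-scale profile: narrow model, full-scale optimization trajectory.

        ``steps_per_epoch=80`` reproduces the batch count of an epoch over
        the full 7680-sample training set, so scaling the dataset down does
        not silently scale training down with it.
        """
        kw.setdefault("d_model", 32)
        kw.setdefault("n_heads", 2)
        kw.setdefault("steps_per_epoch", 80)
        return cls(**kw)


# ---------------------------------------------------------------------------
# attention primitives
# ---------------------------------------------------------------------------

def _causal_mask(L_q: int, L_k: int) -> np.ndarray:
    """Additive mask: position i may attend to keys j ≤ i (aligned ends)."""
    j = np.arange(L_k)[None, :]
    i = np.arange(L_q)[:, None] + (L_k - L_q)
    return np.where(j > i, _NEG_INF, 0.0)


def full_attention(Q, K, V, causal_mask: bool = False):
    """Scaled dot-product attention ``softmax(QKᵀ/√d)V``.

    Works on numpy arrays or autodiff tensors of shape [..., L, d]; with
    ``causal_mask`` position i attends only to positions ≤ i.
    """
    q, k, v = Tensor.as_tensor(Q), Tensor.as_tensor(K), Tensor.as_tensor(V)
    d = q.shape[-1]
    if k.shape[-1] != d or k.shape[-2] != v.shape[-2]:
        raise ValueError("attention dimensions disagree")
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(d))
    if causal_mask:
        scores = scores + Tensor(_causal_mask(q.shape[-2], k.shape[-2]))
    out = scores.softmax(axis=-1) @ v
    return out if isinstance(Q, Tensor) else out.data


def prob_sparse_attention(Q, K, V, factor_c: int = 5, causal: bool = False):
    """ProbSparse attention: exact attention for the top-u queries only.

    Each query's sparsity score is ``M(q_i) = max_j s_ij − mean_j s_ij`` with
    ``s_ij = q_i·k_j/√d`` (restricted to j ≤ i when causal).  The
    ``u = min(L_Q, c·⌈ln L_Q⌉)`` highest-scoring queries (ties broken by
    lowest index) receive exact softmax attention; the remaining queries
    output the mean of V (non-causal) or the cumulative mean of V up to their
    position (causal).  Scores are exact — no key sampling.
    """
    q, k, v = Tensor.as_tensor(Q), Tensor.as_tensor(K), Tensor.as_tensor(V)
    d = q.shape[-1]
    if k.shape[-1] != d or k.shape[-2] != v.shape[-2]:
        raise ValueError("attention dimensions disagree")
    L_q, L_k = q.shape[-2], k.shape[-2]
    u = min(L_q, factor_c * max(1, math.ceil(math.log(L_q)))) if L_q > 1 else 1

    scores_np = (q.data @ np.swapaxes(k.data, -1, -2)) / math.sqrt(d)
    if causal:
        cm = _causal_mask(L_q, L_k)
        masked = scores_np + cm
        counts = np.sum(cm == 0.0, axis=-1)  # keys visible to each query
        M = masked.max(axis=-1) - np.where(masked > _NEG_INF / 2, scores_np, 0.0).sum(axis=-1) / counts
    else:
        M = scores_np.max(axis=-1) - scores_np.mean(axis=-1)

    # top-u queries, stable sort → lowest index wins ties
    order = np.argsort(-M, axis=-1, kind="stable")
    sel = np.zeros(M.shape, dtype=np.float64)
    np.put_along_axis(sel, order[..., :u], 1.0, axis=-1)
    sel_mask = Tensor(sel[..., None])  # [..., L_q, 1]

    exact = full_attention(q, k, v, causal_mask=causal)
    if causal:
        csum = v.cumsum(axis=-2)
        counts_t = Tensor((np.arange(L_k) + 1.0)[(L_k - L_q):, None])
        fallback = csum[..., (L_k - L_q):, :] / counts_t
    else:
        fallback = v.mean(axis=-2, keepdims=True) + Tensor(np.zeros((L_q, 1)))
    out = sel_mask * exact + (1.0 - sel_mask) * fallback
    return out if isinstance(Q, Tensor) else out.data


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def positional_encoding(L: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional encoding [L, d_model]."""
    pos = np.arange(L)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((L, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


class Embedding:
    """Value + time-feature + positional embedding, summed.

    Both projections are bias-free linear maps into ``d_model``, so a
    zero-value/zero-feature input embeds to the positional encoding alone,
    and the value term is exactly linear in the values.
    """

    def __init__(self, input_size: int, d_model: int, rng: np.random.Generator,
                 n_time_features: int = N_TIME_FEATURES):
        self.W_val = uniform_fan_in(rng, (input_size, d_model), input_size)
        self.W_time = uniform_fan_in(rng, (n_time_features, d_model), n_time_features)
        self.d_model = d_model

    def parameters(self) -> list[Parameter]:
        return [self.W_val, self.W_time]

    def __call__(self, values, timefeat) -> Tensor:
        x = Tensor.as_tensor(values)
        t = Tensor.as_tensor(timefeat)
        if x.shape[-1] != self.W_val.shape[0] or t.shape[-1] != self.W_time.shape[0]:
            raise ValueError("embedding input widths do not match the config")
        if x.shape[-2] != t.shape[-2]:
            raise ValueError("values and time features disagree on length")
        pe = Tensor(positional_encoding(x.shape[-2], self.d_model))
        return x @ self.W_val + t @ self.W_time + pe


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class LayerNorm:
    def __init__(self, d: int):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + 1e-5).sqrt() * self.gamma + self.beta


class MultiHeadAttention:
    """Multi-head wrapper around a full or ProbSparse attention primitive."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 sparse: bool = False, factor_c: int = 5, causal: bool = False):
        self.h = n_heads
        self.dh = d_model // n_heads
        self.sparse = sparse
        self.factor_c = factor_c
        self.causal = causal
        self.W_q = uniform_fan_in(rng, (d_model, d_model), d_model)
        self.W_k = uniform_fan_in(rng, (d_model, d_model), d_model)
        self.W_v = uniform_fan_in(rng, (d_model, d_model), d_model)
        self.W_o = uniform_fan_in(rng, (d_model, d_model), d_model)

    def parameters(self) -> list[Parameter]:
        return [self.W_q, self.W_k, self.W_v, self.W_o]

    def _split(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        return x.reshape(B, L, self.h, self.dh).swapaxes(1, 2)  # [B, h, L, dh]

    def __call__(self, q_in: Tensor, k_in: Tensor, v_in: Tensor) -> Tensor:
        q = self._split(q_in @ self.W_q)
        k = self._split(k_in @ self.W_k)
        v = self._split(v_in @ self.W_v)
        if self.sparse:
            out = prob_sparse_attention(q, k, v, factor_c=self.factor_c, causal=self.causal)
        else:
            out = full_attention(q, k, v, causal_mask=self.causal)
        B, _, L, _ = out.shape
        merged = out.swapaxes(1, 2).reshape(B, L, self.h * self.dh)
        return merged @ self.W_o


class FeedForward:
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.W1 = uniform_fan_in(rng, (d_model, d_ff), d_model)
        self.b1 = uniform_fan_in(rng, (d_ff,), d_model)
        self.W2 = uniform_fan_in(rng, (d_ff, d_model), d_ff)
        self.b2 = uniform_fan_in(rng, (d_model,), d_ff)

    def parameters(self) -> list[Parameter]:
        return [self.W1, self.b1, self.W2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.W1 + self.b1).relu() @ self.W2 + self.b2


class DistillBlock:
    """Conv1d (kernel 3, same padding) + ReLU + max-pool (kernel 3, stride 2).

    Halves the sequence length to ⌈L/2⌉ between encoder attention layers.
    """

    def __init__(self, d_model: int, rng: np.random.Generator | None = None):
        if rng is None:
            # identity initialization: centre tap passes the input through
            w = np.zeros((3, d_model, d_model))
            w[1] = np.eye(d_model)
            self.weight = Parameter(w)
            self.bias = Parameter(np.zeros(d_model))
        else:
            self.weight = uniform_fan_in(rng, (3, d_model, d_model), 3 * d_model)
            self.bias = uniform_fan_in(rng, (d_model,), 3 * d_model)

    @classmethod
    def identity(cls, d_model: int) -> "DistillBlock":
        return cls(d_model, rng=None)

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-2] < 2:
            raise ValueError("distillation requires sequence length >= 2")
        h = x.conv1d_same(self.weight, self.bias).relu()
        return h.maxpool1d_half()


def distill_block(x, d_model: int | None = None):
    """Functional identity-conv distillation (numpy in, numpy out)."""
    t = Tensor.as_tensor(x)
    block = DistillBlock.identity(t.shape[-1] if d_model is None else d_model)
    out = block(t)
    return out if isinstance(x, Tensor) else out.data


class EncoderLayer:
    def __init__(self, cfg: InformerConfig, rng: np.random.Generator):
        self.attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng,
                                       sparse=True, factor_c=cfg.factor_c)
        self.norm1 = LayerNorm(cfg.d_model)
        self.ff = FeedForward(cfg.d_model, cfg.d_ff, rng)
        self.norm2 = LayerNorm(cfg.d_model)

    def parameters(self) -> list[Parameter]:
        return (self.attn.parameters() + self.norm1.parameters()
                + self.ff.parameters() + self.norm2.parameters())

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x, x, x))
        return self.norm2(x + self.ff(x))


class DecoderLayer:
    def __init__(self, cfg: InformerConfig, rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng,
                                            sparse=True, factor_c=cfg.factor_c,
                                            causal=True)
        self.norm1 = LayerNorm(cfg.d_model)
        self.cross_attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng,
                                             sparse=False)
        self.norm2 = LayerNorm(cfg.d_model)
        self.ff = FeedForward(cfg.d_model, cfg.d_ff, rng)
        self.norm3 = LayerNorm(cfg.d_model)

    def parameters(self) -> list[Parameter]:
        return (self.self_attn.parameters() + self.norm1.parameters()
                + self.cross_attn.parameters() + self.norm2.parameters()
                + self.ff.parameters() + self.norm3.parameters())

    def __call__(self, x: Tensor, Ve: Tensor) -> Tensor:
        x = self.norm1(x + self.self_attn(x, x, x))
        x = self.norm2(x + self.cross_attn(x, Ve, Ve))
        return self.norm3(x + self.ff(x))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class InformerModel:
    """Encoder–decoder network over residual windows (one-shot decoding)."""

    def __init__(self, cfg: InformerConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.enc_embed = Embedding(cfg.input_size, cfg.d_model, rng)
        self.dec_embed = Embedding(cfg.input_size, cfg.d_model, rng)
        n_stacks = len(cfg.stack_levels)
        self.stacks: list[dict] = []
        for _ in range(n_stacks):
            layers = [EncoderLayer(cfg, rng) for _ in range(cfg.enc_attention_layers)]
            dist = DistillBlock(cfg.d_model, rng) if cfg.distill else None
            self.stacks.append({"layers": layers, "distill": dist})
        self.decoder = DecoderLayer(cfg, rng)
        # near-zero head: untrained output ≈ 0, the natural prior for the
        # zero-mean residual component
        self.W_head = uniform_fan_in(rng, (cfg.d_model, 1), cfg.d_model)
        self.W_head.data *= 0.01
        self.b_head = uniform_fan_in(rng, (1,), cfg.d_model)
        self.b_head.data *= 0.01
        self.training = False
        self._drop_rng = np.random.default_rng(seed + 1000)
        self.loss_history: list[float] = []
        self.lr_history: list[float] = []

    def parameters(self) -> list[Parameter]:
        ps = self.enc_embed.parameters() + self.dec_embed.parameters()
        for st in self.stacks:
            for layer in st["layers"]:
                ps += layer.parameters()
            if st["distill"] is not None:
                ps += st["distill"].parameters()
        ps += self.decoder.parameters()
        return ps + [self.W_head, self.b_head]

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.cfg.dropout
        if not self.training or p <= 0:
            return x
        keep = self._drop_rng.random(x.shape) >= p
        return x * Tensor(keep / (1.0 - p))

    def encode(self, enc_x, enc_time) -> Tensor:
        """Embed the encoder window and run the distillation pyramid → Ve.

        Replica k consumes the last ⌈L/2^(k−1)⌉ embedded rows; each replica is
        its attention layer(s) followed by a distillation halving; replica
        outputs are concatenated along the length axis.
        """
        emb = self._dropout(self.enc_embed(enc_x, enc_time))
        L = emb.shape[-2]
        outs = []
        for k, st in enumerate(self.stacks):
            Lk = math.ceil(L / 2**k)
            x = emb[:, L - Lk :, :]
            for layer in st["layers"]:
                x = self._dropout(layer(x))
            if st["distill"] is not None and x.shape[-2] >= 2:
                x = st["distill"](x)  # length-1 replicas pass through
            outs.append(x)
        return outs[0] if len(outs) == 1 else concatenate(outs, axis=-2)

    def decode(self, Ve: Tensor, dec_x, dec_time) -> Tensor:
        """Masked self-attention + cross-attention + head; last pred_len rows."""
        emb = self._dropout(self.dec_embed(dec_x, dec_time))
        h = self.decoder(emb, Ve)
        out = h @ self.W_head + self.b_head  # [B, L_dec, 1]
        p = self.cfg.pred_len
        return out[:, -p:, 0]

    def forward(self, enc_x, enc_time, dec_x, dec_time) -> Tensor:
        return self.decode(self.encode(enc_x, enc_time), dec_x, dec_time)

    def predict(self, windows: WindowBatch) -> np.ndarray:
        """Deterministic inference on a window batch → [B, pred_len]."""
        self.training = False
        return self.forward(windows.enc_x, windows.enc_time,
                            windows.dec_x, windows.dec_time).data


def encoder_output_length(L: int, stack_levels: tuple[int, ...], distill: bool = True) -> int:
    """Closed-form length of Ve for encoder input length L."""
    total = 0
    for k in range(len(stack_levels)):
        Lk = math.ceil(L / 2**k)
        total += math.ceil(Lk / 2) if distill and Lk >= 2 else Lk
    return total


def train_residual(windows: WindowBatch, cfg: InformerConfig, seed: int = 0) -> InformerModel:
    """Train the residual Informer on (residual-component) windows.

    Adam with per-epoch learning rate ``cfg.lr · 0.5^(epoch−1)``, MSE loss,
    seeded shuffling; per-epoch mean batch loss is recorded on
    ``model.loss_history``.  ``epochs=0`` returns the untrained model.
    """
    if windows.n_windows == 0:
        raise ValueError("empty window batch")
    model = InformerModel(cfg, seed=seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(seed + 1)
    n = windows.n_windows
    from .trend_model import _epoch_batches

    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * 0.5**epoch
        model.lr_history.append(opt.lr)
        model.training = True
        losses = []
        for idx in _epoch_batches(n, cfg.batch_size, cfg.steps_per_epoch, rng):
            pred = model.forward(windows.enc_x[idx], windows.enc_time[idx],
                                 windows.dec_x[idx], windows.dec_time[idx])
            err = pred - Tensor(windows.target[idx])
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.loss_history.append(float(np.mean(losses)))
    model.training = False
    return model
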