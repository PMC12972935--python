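"""Neural-network building blocks on top of :mod:`dualscreen.autodiff`.

Contains the generic layers shared by the multitask screening network and
the conditional text VAE: embeddings, affine layers, layer normalisation,
multihead self-attention, post-LN transformer blocks and recurrent cells.
All randomness (initialisation, dropout masks) flows through explicitly
passed ``numpy.random.Generator`` objects so runs are reproducible from a
single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, softmax

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "dropout",
    "MultiHeadSelfAttention",
    "TransformerLayer",
    "BiLSTM",
    "GRUCell",
]


class Module:
    """Base class with recursive parameter registry and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, p in self._params.items():
            out[name] = p
        for name, mod in self._modules.items():
            for sub, p in mod.parameters().items():
                out[f"{name}.{sub}"] = p
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.grad = None

    def train(self):
        object.__setattr__(self, "training", True)
        for m in self._modules.values():
            m.train()
        return self

    def eval(self):
        object.__setattr__(self, "training", False)
        for m in self._modules.values():
            m.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(n_embeddings, dim)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return self.gamma * (centered / (var + self.eps).sqrt()) + self.beta


def dropout(x: Tensor, p: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    """Inverted dropout; identity in eval mode or when p == 0."""
    if not training or p <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with ``h`` parallel heads.

    Padding is handled by an additive mask on the attention logits so that
    padded key positions receive (numerically) zero weight.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError("hidden dim must be divisible by the number of heads")
        self.dim, self.n_heads, self.d_k = dim, n_heads, dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def _split(self, x: Tensor, batch: int, length: int) -> Tensor:
        # (B, L, d) -> (B, h, L, d_k)
        return x.reshape(batch, length, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def __call__(
        self,
        h: Tensor,
        mask: np.ndarray | None = None,
        attn_dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        batch, length, _ = h.shape
        q = self._split(self.wq(h), batch, length)
        k = self._split(self.wk(h), batch, length)
        v = self._split(self.wv(h), batch, length)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_k))
        if mask is not None:
            bias = (1.0 - np.asarray(mask, dtype=np.float64))[:, None, None, :] * -1e9
            scores = scores + Tensor(bias)
        attn = softmax(scores, axis=-1)
        attn = dropout(attn, attn_dropout, rng, self.training)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(batch, length, self.dim)
        return self.wo(out)


class TransformerLayer(Module):
    """Post-LN transformer encoder block (attention + position-wise FFN).

    ``keep`` switches implement stochastic depth: a skipped sub-block passes
    its residual input through unchanged (training-time only).
    """

    def __init__(self, dim: int, n_heads: int, ff_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_hidden, rng)
        self.ff2 = Linear(ff_hidden, dim, rng)
        self.ln2 = LayerNorm(dim)

    def __call__(
        self,
        h: Tensor,
        mask: np.ndarray | None = None,
        p_drop: float = 0.0,
        rng: np.random.Generator | None = None,
        keep_attn: bool = True,
        keep_ff: bool = True,
    ) -> Tensor:
        if keep_attn:
            a = self.attn(h, mask, attn_dropout=p_drop, rng=rng)
            h = self.ln1(h + dropout(a, p_drop, rng, self.training))
        if keep_ff:
            f = self.ff2(dropout(self.ff1(h).relu(), p_drop, rng, self.training))
            h = self.ln2(h + dropout(f, p_drop, rng, self.training))
        return h


class _LSTMDirection(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.wx = Linear(n_in, 4 * hidden, rng)
        self.wh = Linear(hidden, 4 * hidden, rng, bias=False)

    def step(self, x_t: Tensor, h: Tensor, c: Tensor, m_t: Tensor):
        gates = self.wx(x_t) + self.wh(h)
        H = self.hidden
        i = gates[:, 0 * H:1 * H].sigmoid()
        f = gates[:, 1 * H:2 * H].sigmoid()
        g = gates[:, 2 * H:3 * H].tanh()
        o = gates[:, 3 * H:4 * H].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        # hold the previous state at padded positions
        one_minus = 1.0 - m_t
        return m_t * h_new + one_minus * h, m_t * c_new + one_minus * c


class BiLSTM(Module):
    """Bidirectional LSTM over padded batches; returns the concatenated
    final hidden states of both directions, shape ``(B, 2*hidden)``."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = _LSTMDirection(n_in, hidden, rng)
        self.bwd = _LSTMDirection(n_in, hidden, rng)
        self.hidden = hidden

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        batch, length, _ = x.shape
        mask = np.asarray(mask, dtype=np.float64)
        finals = []
        for direction, order in ((self.fwd, range(length)), (self.bwd, range(length - 1, -1, -1))):
            h = Tensor(np.zeros((batch, direction.hidden)))
            c = Tensor(np.zeros((batch, direction.hidden)))
            for t in order:
                m_t = Tensor(mask[:, t:t + 1])
                h, c = direction.step(x[:, t, :], h, c, m_t)
            finals.append(h)
        return concat(finals, axis=-1)


class GRUCell(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.wx = Linear(n_in, 3 * hidden, rng)
        self.wh = Linear(hidden, 3 * hidden, rng, bias=False)

    def __call__(self, x_t: Tensor, h: Tensor) -> Tensor:
        gx, gh = self.wx(x_t), self.wh(h)
        H = self.hidden
        r = (gx[:, :H] + gh[:, :H]).sigmoid()
        z = (gx[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
        n = (gx[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
        return (1.0 - z) * n + z * h
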