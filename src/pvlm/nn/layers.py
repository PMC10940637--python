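"""Transformer building blocks on top of the autograd engine.

Includes the scaled-dot-product attention primitive (the same formula used by
BERT-style encoders), multi-head self/cross attention, pre-norm and post-norm
transformer blocks, and a fusion block whose layers interleave self-attention,
cross-attention and a feed-forward network.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, concat

NEG_INF = -1e9


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------
class Module:
    """Base class: recursive parameter discovery + train/eval mode flag."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self):
        self._set_mode(True)

    def eval(self):
        self._set_mode(False)

    def _set_mode(self, training: bool):
        self.training = training
        for value in vars(self).items():
            pass
        for value in vars(self).values():
            if isinstance(value, Module):
                value._set_mode(training)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._set_mode(training)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"parameter-set mismatch: {sorted(missing)[:5]} ...")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(np.float64).copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = 1.0 / np.sqrt(in_dim)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gain = Parameter(np.ones(dim))
        self.shift = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps).pow(-0.5)
        return centered * inv * self.gain + self.shift


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator, scale: float = 0.02):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, scale, size=(n, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids, dtype=np.intp)]


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         mask: np.ndarray | None = None,
                         return_weights: bool = False):
    """Softmax(QK^T / sqrt(d_k)) V with an optional additive pre-softmax mask.

    ``mask`` is broadcastable to the attention-score shape and holds 0 for
    permitted and ``NEG_INF`` for excluded key positions.  Raises if the mask
    excludes every key for some query (degenerate softmax).
    """
    d_k = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    if mask is not None:
        if not np.any(np.broadcast_to(mask, scores.shape) > NEG_INF / 2, axis=-1).all():
            raise ValueError("attention mask excludes all keys for some query")
        scores = scores + Tensor(mask)
    weights = softmax(scores, axis=-1)
    out = weights @ v
    if return_weights:
        return out, weights
    return out


def causal_mask(n: int) -> np.ndarray:
    """Additive mask letting position i attend to positions <= i."""
    m = np.zeros((n, n))
    m[np.triu_indices(n, k=1)] = NEG_INF
    return m


def padding_mask(valid: np.ndarray) -> np.ndarray:
    """(B, L) boolean validity -> (B, 1, 1, L) additive key mask."""
    m = np.where(np.asarray(valid, dtype=bool), 0.0, NEG_INF)
    return m[:, None, None, :]


class MultiHeadAttention(Module):
    """Multi-head attention usable for both self- and cross-attention.

    Stores the attention probabilities of the latest forward pass in
    ``last_weights`` (shape B x heads x len_q x len_k) for inspection.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError("hidden dim must be divisible by the head count")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)
        self.last_weights: np.ndarray | None = None

    def _split(self, x: Tensor) -> Tensor:
        b, l, d = x.shape
        return x.reshape(b, l, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor,
                 mask: np.ndarray | None = None) -> Tensor:
        b, lq, d = query.shape
        q = self._split(self.q_proj(query))
        k = self._split(self.k_proj(key))
        v = self._split(self.v_proj(value))
        ctx, w = scaled_dot_attention(q, k, v, mask=mask, return_weights=True)
        self.last_weights = w.data
        ctx = ctx.transpose(0, 2, 1, 3).reshape(b, lq, d)
        return self.out_proj(ctx)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class TransformerLayer(Module):
    """Self-attention + feed-forward block.

    ``norm_style='pre'`` (default; stable at small scale) or ``'post'``
    (classic BERT ordering).
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 ff_mult: int = 4, norm_style: str = "pre"):
        super().__init__()
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.ff = FeedForward(dim, dim * ff_mult, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.norm_style = norm_style

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        if self.norm_style == "pre":
            h = self.norm1(x)
            x = x + self.attn(h, h, h, mask=mask)
            x = x + self.ff(self.norm2(x))
        else:
            x = self.norm1(x + self.attn(x, x, x, mask=mask))
            x = self.norm2(x + self.ff(x))
        return x


class FusionLayer(Module):
    """Self-attention -> cross-attention -> feed-forward block."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 ff_mult: int = 4, norm_style: str = "pre"):
        super().__init__()
        self.self_attn = MultiHeadAttention(dim, n_heads, rng)
        self.cross_attn = MultiHeadAttention(dim, n_heads, rng)
        self.ff = FeedForward(dim, dim * ff_mult, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.norm3 = LayerNorm(dim)
        self.norm_style = norm_style

    def __call__(self, x: Tensor, kv: Tensor, self_mask: np.ndarray | None = None,
                 cross_mask: np.ndarray | None = None) -> Tensor:
        if self.norm_style == "pre":
            h = self.norm1(x)
            x = x + self.self_attn(h, h, h, mask=self_mask)
            x = x + self.cross_attn(self.norm2(x), kv, kv, mask=cross_mask)
            x = x + self.ff(self.norm3(x))
        else:
            x = self.norm1(x + self.self_attn(x, x, x, mask=self_mask))
            x = self.norm2(x + self.cross_attn(x, kv, kv, mask=cross_mask))
            x = self.norm3(x + self.ff(x))
        return x


class Encoder(Module):
    def __init__(self, n_layers: int, dim: int, n_heads: int, rng: np.random.Generator,
                 norm_style: str = "pre"):
        super().__init__()
        self.layers = [TransformerLayer(dim, n_heads, rng, norm_style=norm_style)
                       for _ in range(n_layers)]
        self.final_norm = LayerNorm(dim) if norm_style == "pre" else None

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        for layer in self.layers:
            x = layer(x, mask=mask)
        if self.final_norm is not None:
            x = self.final_norm(x)
        return x


class FusionEncoder(Module):
    def __init__(self, n_layers: int, dim: int, n_heads: int, rng: np.random.Generator,
                 norm_style: str = "pre"):
        super().__init__()
        self.layers = [FusionLayer(dim, n_heads, rng, norm_style=norm_style)
                       for _ in range(n_layers)]
        self.final_norm = LayerNorm(dim) if norm_style == "pre" else None

    def __call__(self, x: Tensor, kv: Tensor, self_mask: np.ndarray | None = None,
                 cross_mask: np.ndarray | None = None) -> Tensor:
        for layer in self.layers:
            x = layer(x, kv, self_mask=self_mask, cross_mask=cross_mask)
        if self.final_norm is not None:
            x = self.final_norm(x)
        return x

    @property
    def last_cross_attention(self) -> np.ndarray | None:
        """Attention probabilities of the final layer's cross-attention."""
        return self.layers[-1].cross_attn.last_weights


def l2_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    norm = (x * x).sum(axis=-1, keepdims=True).pow(0.5)
    if np.any(norm.data < eps):
        raise ValueError("zero-norm feature cannot be L2-normalized")
    return x / norm
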