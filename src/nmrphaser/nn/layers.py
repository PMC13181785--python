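"""NumPy layers with explicit forward/backward passes.

Every layer owns its parameters in ``self.params`` (name -> array) and
accumulates gradients in ``self.grads`` under the same keys.  ``forward``
caches whatever the matching ``backward`` needs; layers are stateful and
not reentrant, which is fine for plain sequential training loops.
"""

from __future__ import annotations

import math
from typing import Dict, List

import numpy as np


class Layer:
    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def named_parameters(self, prefix: str = ""):
        for k in self.params:
            yield prefix + k, self

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv1d(Layer):
    """Strided 1D convolution with 'same'-style zero padding.

    Output length is ``ceil(L / stride)`` when ``L`` is a multiple of the
    stride (the model pads inputs so it always is).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        scale = math.sqrt(2.0 / (c_in * kernel))
        self.params["W"] = (rng.standard_normal((c_out, c_in, kernel)) * scale).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, C_in, L) with L divisible by stride
        B, C, L = x.shape
        k, s = self.kernel, self.stride
        pad_l = (k - 1) // 2
        pad_r = k - 1 - pad_l
        xp = np.pad(x, ((0, 0), (0, 0), (pad_l, pad_r)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::s]
        self._win = win
        self._in_shape = x.shape
        self._pad = (pad_l, pad_r)
        out = np.einsum("bclk,ock->bol", win, self.params["W"], optimize=True)
        out += self.params["b"][None, :, None]
        return out

    def backward(self, g_out: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        B, C, L = self._in_shape
        pad_l, pad_r = self._pad
        self.grads["W"] += np.einsum("bclk,bol->ock", self._win, g_out, optimize=True)
        self.grads["b"] += g_out.sum(axis=(0, 2))
        g_win = np.einsum("ock,bol->bclk", self.params["W"], g_out, optimize=True)
        g_xp = np.zeros((B, C, L + pad_l + pad_r), dtype=g_out.dtype)
        L_out = g_out.shape[2]
        for j in range(k):
            g_xp[:, :, j : j + s * L_out : s] += g_win[:, :, :, j]
        self._win = None
        return g_xp[:, :, pad_l : pad_l + L]


class Dropout(Layer):
    """Inverted dropout; active only when ``self.training`` is True."""

    def __init__(self, p: float, seed: int = 0) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.training = False
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        out = g * self._mask
        self._mask = None
        return out


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = g * self._mask
        self._mask = None
        return out


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        scale = math.sqrt(1.0 / d_in)
        self.params["W"] = (rng.standard_normal((d_in, d_out)) * scale).astype(dtype)
        self.params["b"] = np.zeros(d_out, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.grads["W"] += x2.T @ g2
        self.grads["b"] += g2.sum(axis=0)
        self._x = None
        return g @ self.params["W"].T


class LayerNorm(Layer):
    def __init__(self, dim: int, dtype=np.float32, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(dim, dtype=dtype)
        self.params["beta"] = np.zeros(dim, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] += (g * xhat).reshape(-1, g.shape[-1]).sum(axis=0)
        self.grads["beta"] += g.reshape(-1, g.shape[-1]).sum(axis=0)
        gh = g * self.params["gamma"]
        d = g.shape[-1]
        gx = inv * (
            gh
            - gh.mean(axis=-1, keepdims=True)
            - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
        )
        self._xhat = self._inv = None
        return gx


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def relative_bucket_index_1d(ad: np.ndarray, n_buckets: int,
                             max_distance: int) -> np.ndarray:
    """Unsigned bucket index (0..n_buckets-1) for absolute offsets >= 1."""
    exact = max(1, n_buckets // 2)
    idx = np.where(ad <= exact, np.maximum(ad - 1, 0), 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_idx = exact + np.floor(
            np.log(np.maximum(ad, 1) / exact)
            / math.log(max(max_distance, exact + 1) / exact)
            * (n_buckets - exact)
        ).astype(int)
    return np.where(ad > exact, np.minimum(log_idx, n_buckets - 1), idx)


def relative_bucket_index(n_tokens: int, n_buckets: int, max_distance: int) -> np.ndarray:
    """Signed log-spaced bucket index for every (query, key) token offset.

    Offset ``d = i - j`` maps to one of ``2*n_buckets + 1`` buckets: the
    center bucket for ``d = 0``, and for each sign ``n_buckets`` buckets of
    which the first half cover small offsets exactly and the second half are
    logarithmically spaced out to ``max_distance``.  The mapping depends only
    on the offset, which is what makes the resulting attention bias
    translation invariant while still encoding order (sign) and distance.
    """
    i = np.arange(n_tokens)
    d = i[:, None] - i[None, :]
    ad = np.abs(d)
    idx = relative_bucket_index_1d(ad, n_buckets, max_distance)
    return (n_buckets + np.sign(d) * (idx + 1) * (ad > 0)).astype(np.intp)


class MultiHeadSelfAttention(Layer):
    """Multi-head self-attention with a learned relative positional bias.

    The bias table has ``2 * rel_bias_buckets + 1`` scalars per head;
    ``bias[i, j]`` depends only on ``i - j`` (shift invariant, sign aware).
    """

    def __init__(self, dim: int, n_heads: int, rel_bias_buckets: int,
                 max_distance: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.n_heads = dim, n_heads
        self.d_head = dim // n_heads
        self.n_buckets = rel_bias_buckets
        self.max_distance = max_distance
        scale = math.sqrt(1.0 / dim)
        self.params["Wqkv"] = (rng.standard_normal((dim, 3 * dim)) * scale).astype(dtype)
        self.params["bqkv"] = np.zeros(3 * dim, dtype=dtype)
        self.params["Wo"] = (rng.standard_normal((dim, dim)) * scale).astype(dtype)
        self.params["bo"] = np.zeros(dim, dtype=dtype)
        self.params["rel_bias"] = np.zeros(
            (2 * rel_bias_buckets + 1, n_heads), dtype=dtype
        )
        self.zero_grad()
        self._bucket_cache: dict[int, np.ndarray] = {}
        self.last_attention: np.ndarray | None = None

    def bucket_index(self, n_tokens: int) -> np.ndarray:
        if n_tokens not in self._bucket_cache:
            self._bucket_cache[n_tokens] = relative_bucket_index(
                n_tokens, self.n_buckets, self.max_distance
            )
        return self._bucket_cache[n_tokens]

    def bias_matrix(self, n_tokens: int) -> np.ndarray:
        """(n_heads, T, T) additive attention bias."""
        idx = self.bucket_index(n_tokens)
        return self.params["rel_bias"][idx].transpose(2, 0, 1)

    def forward(self, x: np.ndarray, keep_attention: bool = False) -> np.ndarray:
        B, T, D = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = x @ self.params["Wqkv"] + self.params["bqkv"]
        qkv = qkv.reshape(B, T, 3, h, dh).transpose(2, 0, 3, 1, 4)  # (3,B,h,T,dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scale = 1.0 / math.sqrt(dh)
        scores = np.einsum("bhtd,bhsd->bhts", q, k, optimize=True) * scale
        scores += self.bias_matrix(T)[None]
        attn = softmax(scores, axis=-1)
        out = np.einsum("bhts,bhsd->bhtd", attn, v, optimize=True)
        merged = out.transpose(0, 2, 1, 3).reshape(B, T, D)
        y = merged @ self.params["Wo"] + self.params["bo"]
        self._cache = (x, q, k, v, attn, merged)
        if keep_attention:
            self.last_attention = attn.copy()
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, q, k, v, attn, merged = self._cache
        B, T, D = x.shape
        h, dh = self.n_heads, self.d_head
        scale = 1.0 / math.sqrt(dh)

        g2 = g.reshape(-1, D)
        self.grads["Wo"] += merged.reshape(-1, D).T @ g2
        self.grads["bo"] += g2.sum(axis=0)
        g_merged = (g @ self.params["Wo"].T).reshape(B, T, h, dh).transpose(0, 2, 1, 3)

        g_attn = np.einsum("bhtd,bhsd->bhts", g_merged, v, optimize=True)
        g_v = np.einsum("bhts,bhtd->bhsd", attn, g_merged, optimize=True)
        g_scores = attn * (g_attn - np.sum(g_attn * attn, axis=-1, keepdims=True))

        idx = self.bucket_index(T)
        g_bias = g_scores.sum(axis=0)  # (h, T, T)
        flat = g_bias.reshape(h, -1)
        n_slots = self.params["rel_bias"].shape[0]
        for hi in range(h):
            self.grads["rel_bias"][:, hi] += np.bincount(
                idx.ravel(), weights=flat[hi], minlength=n_slots
            ).astype(self.grads["rel_bias"].dtype)

        g_q = np.einsum("bhts,bhsd->bhtd", g_scores, k, optimize=True) * scale
        g_k = np.einsum("bhts,bhtd->bhsd", g_scores, q, optimize=True) * scale

        g_qkv = np.stack([g_q, g_k, g_v])  # (3,B,h,T,dh)
        g_qkv = g_qkv.transpose(1, 3, 0, 2, 4).reshape(B, T, 3 * D)
        self.grads["Wqkv"] += x.reshape(-1, D).T @ g_qkv.reshape(-1, 3 * D)
        self.grads["bqkv"] += g_qkv.reshape(-1, 3 * D).sum(axis=0)
        g_x = g_qkv @ self.params["Wqkv"].T
        self._cache = None
        return g_x


class FeedForward(Layer):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32, dropout: float = 0.0, seed: int = 0) -> None:
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng, dtype)
        self.fc2 = Linear(hidden, dim, rng, dtype)
        self.act = ReLU()
        self.drop = Dropout(dropout, seed)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.fc2.forward(self.drop.forward(self.act.forward(self.fc1.forward(x))))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.act.backward(self.drop.backward(self.fc2.backward(g))))

    def children(self) -> List[Layer]:
        return [self.fc1, self.fc2]


class TransformerBlock(Layer):
    """Pre-norm transformer encoder block with relative-bias attention."""

    def __init__(self, dim: int, n_heads: int, ffn_mult: int,
                 rel_bias_buckets: int, max_distance: int,
                 rng: np.random.Generator, dtype=np.float32,
                 dropout: float = 0.0, seed: int = 0) -> None:
        super().__init__()
        self.ln1 = LayerNorm(dim, dtype)
        self.attn = MultiHeadSelfAttention(
            dim, n_heads, rel_bias_buckets, max_distance, rng, dtype
        )
        self.drop1 = Dropout(dropout, seed)
        self.ln2 = LayerNorm(dim, dtype)
        self.ffn = FeedForward(dim, ffn_mult * dim, rng, dtype, dropout, seed + 1)

    def forward(self, x: np.ndarray, keep_attention: bool = False) -> np.ndarray:
        x = x + self.drop1.forward(self.attn.forward(self.ln1.forward(x), keep_attention))
        x = x + self.ffn.forward(self.ln2.forward(x))
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = g + self.ln2.backward(self.ffn.backward(g))
        g = g + self.ln1.backward(self.attn.backward(self.drop1.backward(g)))
        return g

    def children(self) -> List[Layer]:
        return [self.ln1, self.attn, self.ln2, *self.ffn.children()]

    def dropout_layers(self) -> List[Dropout]:
        return [self.drop1, self.ffn.drop]


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          label_smoothing: float = 0.0):
    """Mean categorical cross-entropy and its gradient w.r.t. the logits.

    ``labels`` are integer class indices.  With ``label_smoothing = e`` the
    target distribution is ``(1-e) * onehot + e/K``.  Returns
    ``(loss, grad)``.
    """
    probs = softmax(logits, axis=-1)
    n, k = logits.shape
    eps = np.finfo(probs.dtype).tiny
    logp = np.log(probs + eps)
    if label_smoothing:
        target = np.full_like(probs, label_smoothing / k)
        target[np.arange(n), labels] += 1.0 - label_smoothing
        loss = -np.mean(np.sum(target * logp, axis=-1))
        grad = probs - target
    else:
        loss = -np.mean(logp[np.arange(n), labels])
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n
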