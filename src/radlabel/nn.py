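"""Minimal NumPy neural-network core used by the report classifier.

Implements exactly the pieces the classifier architecture needs — dense
layers, layer normalisation, multi-head self-attention with key padding
masks, learned token/position embeddings, binary cross-entropy on logits,
and the Adam optimizer — with explicit reverse-mode gradients. Gradients
are verified against central finite differences in the test suite.

All arrays are float64 for reproducibility; shapes follow the convention
``(batch, tokens, d_model)``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Param", "Module", "Dense", "LayerNorm", "Embedding", "PositionalEmbedding",
    "MultiHeadSelfAttention", "FeedForward", "TransformerBlock", "Adam",
    "sigmoid", "bce_with_logits", "relu",
]

NEG_INF = -1e9


def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x):
    return np.maximum(x, 0.0)


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = np.asarray(logits, dtype=float)
    y = np.asarray(targets, dtype=float)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - y) / z.size
    return float(loss.mean()), dz


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value, name=""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Module:
    def params(self):
        out = []
        for attr in vars(self).values():
            if isinstance(attr, Param):
                out.append(attr)
            elif isinstance(attr, Module):
                out.extend(attr.params())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def state(self):
        return [p.value.copy() for p in self.params()]

    def load_state(self, state):
        params = self.params()
        if len(state) != len(params):
            raise ValueError("state does not match parameter count")
        for p, v in zip(params, state):
            p.value[...] = v


class Dense(Module):
    def __init__(self, rng, d_in, d_out, scale=0.02, name="dense"):
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)), f"{name}.W")
        self.b = Param(np.zeros(d_out), f"{name}.b")

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return (g2 @ self.W.value.T).reshape(self._x.shape)


class LayerNorm(Module):
    def __init__(self, d, eps=1e-5, name="ln"):
        self.gain = Param(np.ones(d), f"{name}.g")
        self.bias = Param(np.zeros(d), f"{name}.b")
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = xc * self._inv
        return self.gain.value * self._xhat + self.bias.value

    def backward(self, g):
        xhat, inv = self._xhat, self._inv
        axes = tuple(range(g.ndim - 1))
        self.gain.grad += (g * xhat).sum(axis=axes)
        self.bias.grad += g.sum(axis=axes)
        dxhat = g * self.gain.value
        mean_dxhat = dxhat.mean(axis=-1, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


class Embedding(Module):
    def __init__(self, rng, n_vocab, d, name="emb"):
        self.W = Param(rng.normal(0.0, 0.02, size=(n_vocab, d)), f"{name}.W")

    def forward(self, ids):
        self._ids = ids
        return self.W.value[ids]

    def backward(self, g):
        np.add.at(self.W.grad, self._ids, g)
        return None


class PositionalEmbedding(Module):
    def __init__(self, rng, max_len, d, name="pos"):
        self.P = Param(rng.normal(0.0, 0.02, size=(max_len, d)), f"{name}.P")

    def forward(self, x):
        return x + self.P.value[: x.shape[1]]

    def backward(self, g):
        self.P.grad[: g.shape[1]] += g.sum(axis=0)
        return g


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention; padded key positions are masked
    out so padding never leaks into real positions."""

    def __init__(self, rng, d, n_heads, name="mha"):
        if d % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.q = Dense(rng, d, d, name=f"{name}.q")
        self.k = Dense(rng, d, d, name=f"{name}.k")
        self.v = Dense(rng, d, d, name=f"{name}.v")
        self.o = Dense(rng, d, d, name=f"{name}.o")

    def _split(self, x):
        B, T, D = x.shape
        return x.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _join(self, x):
        B, H, T, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)

    def forward(self, x, mask):
        q = self._split(self.q.forward(x))
        k = self._split(self.k.forward(x))
        v = self._split(self.v.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(self.d_head)
        scores = scores + (mask[:, None, None, :] - 1.0) * -NEG_INF
        scores = scores - scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=-1, keepdims=True)
        self._attn, self._q, self._k, self._v = attn, q, k, v
        ctx = attn @ v
        return self.o.forward(self._join(ctx))

    def backward(self, g):
        attn, q, k, v = self._attn, self._q, self._k, self._v
        dctx = self._split(self.o.backward(g))
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        ds = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        ds = ds / math.sqrt(self.d_head)
        dq = ds @ k
        dk = ds.transpose(0, 1, 3, 2) @ q
        dx = self.q.backward(self._join(dq))
        dx = dx + self.k.backward(self._join(dk))
        dx = dx + self.v.backward(self._join(dv))
        return dx


class FeedForward(Module):
    def __init__(self, rng, d, d_ff, name="ff"):
        self.lin1 = Dense(rng, d, d_ff, name=f"{name}.1")
        self.lin2 = Dense(rng, d_ff, d, name=f"{name}.2")

    def forward(self, x):
        a = self.lin1.forward(x)
        self._mask = a > 0
        return self.lin2.forward(a * self._mask)

    def backward(self, g):
        da = self.lin2.backward(g) * self._mask
        return self.lin1.backward(da)


class TransformerBlock(Module):
    """Post-norm block: x -> LN(x + MHA(x)) -> LN(. + FF(.))."""

    def __init__(self, rng, d, n_heads, d_ff, name="block"):
        self.mha = MultiHeadSelfAttention(rng, d, n_heads, name=f"{name}.mha")
        self.ln1 = LayerNorm(d, name=f"{name}.ln1")
        self.ff = FeedForward(rng, d, d_ff, name=f"{name}.ff")
        self.ln2 = LayerNorm(d, name=f"{name}.ln2")

    def forward(self, x, mask):
        x1 = self.ln1.forward(x + self.mha.forward(x, mask))
        return self.ln2.forward(x1 + self.ff.forward(x1))

    def backward(self, g):
        g1 = self.ln2.backward(g)
        g1 = g1 + self.ff.backward(g1)
        g0 = self.ln1.backward(g1)
        return g0 + self.mha.backward(g0)


class Adam:
    """Adam with bias correction; state keyed by parameter identity."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
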