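"""The report classifier: contextual encoder -> additive attention pooling
-> single-hidden-layer classification head.

The encoder maps each token of a report to a contextualised d-dimensional
vector. A learned attention scorer ``u_i = v^T tanh(W h_i + b)`` assigns a
softmax-normalised weight to every non-padding token; the report
representation is the attention-weighted sum of token vectors, and a small
fully connected network with one hidden layer converts it to the
probability that the report describes the category of interest. One such
model is trained per category — eight in total for the abnormal flag plus
the seven specialised abnormality categories.

At full scale the encoder would be a large pretrained biomedical
transformer (768-dimensional embeddings); this package ships a desk-scale
randomly initialised transformer (2 layers, d=64, 4 heads) — the
architecture and its contracts, not pretrained weights, are what is tested
and shipped here. Pre-trained encoder weights are not bundled.
"""

from __future__ import annotations

import html as _html
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .preprocess import TokenizedReport, Vocabulary, normalise_and_tokenize, word_tokenize

__all__ = [
    "EncoderConfig", "TokenEmbeddings", "AttentionPooled",
    "TransformerEncoder", "AdditiveAttentionPool", "ClassifierHead",
    "ReportClassifier", "encode", "attention_pool", "classify",
    "attention_report", "masked_softmax_pool",
    "save_model", "load_model",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Desk-scale defaults: 2 layers, d=64, 4 heads."""

    vocab_size: int
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 256
    max_len: int = 512
    d_attention: int = 64
    d_hidden: int = 256
    seed: int = 0


@dataclass(frozen=True)
class TokenEmbeddings:
    """One d-vector per token position (padding positions included)."""

    vectors: np.ndarray  # (T, d) or (B, T, d)

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", v)
        if not np.isfinite(v).all():
            raise ValueError("embeddings must be finite")

    @property
    def d(self):
        return self.vectors.shape[-1]


@dataclass(frozen=True)
class AttentionPooled:
    """Per-token attention weights and the pooled report vector."""

    weights: np.ndarray
    pooled: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        p = np.asarray(self.pooled, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "pooled", p)
        if (w < 0).any():
            raise ValueError("attention weights must be non-negative")


class TransformerEncoder(nn.Module):
    def __init__(self, config):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.emb = nn.Embedding(rng, config.vocab_size, config.d_model)
        self.pos = nn.PositionalEmbedding(rng, config.max_len, config.d_model)
        self.blocks = [
            nn.TransformerBlock(rng, config.d_model, config.n_heads, config.d_ff,
                                name=f"block{i}")
            for i in range(config.n_layers)
        ]

    def forward(self, ids, mask):
        if ids.max(initial=0) >= self.config.vocab_size or ids.min(initial=0) < 0:
            raise ValueError("token id outside encoder vocabulary")
        x = self.pos.forward(self.emb.forward(ids))
        fmask = mask.astype(float)
        for block in self.blocks:
            x = block.forward(x, fmask)
        return x

    def backward(self, g):
        for block in reversed(self.blocks):
            g = block.backward(g)
        g = self.pos.backward(g)
        self.emb.backward(g)


class AdditiveAttentionPool(nn.Module):
    """u_i = v^T tanh(W h_i + b); alpha = softmax over non-padding tokens."""

    def __init__(self, d, d_att=64, seed=0):
        rng = np.random.default_rng(seed + 101)
        self.W = nn.Param(rng.normal(0.0, 0.02, size=(d, d_att)), "pool.W")
        self.b = nn.Param(np.zeros(d_att), "pool.b")
        self.v = nn.Param(rng.normal(0.0, 0.02, size=(d_att,)), "pool.v")

    def scores(self, h):
        t = np.tanh(h @ self.W.value + self.b.value)
        return t @ self.v.value

    def forward(self, h, mask):
        fmask = mask.astype(float)
        if (fmask.sum(axis=-1) == 0).any():
            raise ValueError("attention pooling over an all-padding mask")
        self._h, self._mask = h, fmask
        self._t = np.tanh(h @ self.W.value + self.b.value)
        u = self._t @ self.v.value
        alpha = _masked_softmax(u, fmask)
        self._alpha = alpha
        pooled = (alpha[..., None] * h).sum(axis=-2)
        return pooled, alpha

    def backward(self, dpooled, dalpha=None):
        h, alpha, t = self._h, self._alpha, self._t
        dalpha_total = (dpooled[..., None, :] * h).sum(axis=-1)
        if dalpha is not None:
            dalpha_total = dalpha_total + dalpha
        dh = alpha[..., None] * dpooled[..., None, :]
        du = alpha * (dalpha_total - (dalpha_total * alpha).sum(axis=-1, keepdims=True))
        dt = du[..., None] * self.v.value
        dz = dt * (1.0 - t * t)
        self.v.grad += (t * du[..., None]).reshape(-1, t.shape[-1]).sum(axis=0)
        self.W.grad += h.reshape(-1, h.shape[-1]).T @ dz.reshape(-1, dz.shape[-1])
        self.b.grad += dz.reshape(-1, dz.shape[-1]).sum(axis=0)
        dh = dh + dz @ self.W.value.T
        return dh


class ClassifierHead(nn.Module):
    """One hidden rectified layer and a single sigmoid output unit."""

    def __init__(self, d, d_hidden=256, seed=0):
        rng = np.random.default_rng(seed + 202)
        self.lin1 = nn.Dense(rng, d, d_hidden, scale=float(np.sqrt(2.0 / d)),
                             name="head.1")
        self.lin2 = nn.Dense(rng, d_hidden, 1, scale=float(np.sqrt(2.0 / d_hidden)),
                             name="head.2")

    def forward(self, pooled):
        a = self.lin1.forward(pooled)
        self._relu_mask = a > 0
        return self.lin2.forward(a * self._relu_mask)[..., 0]

    def backward(self, dlogit):
        da = self.lin2.backward(dlogit[..., None]) * self._relu_mask
        return self.lin1.backward(da)


def _masked_softmax(u, fmask):
    u = u + (fmask - 1.0) * -nn.NEG_INF
    u = u - u.max(axis=-1, keepdims=True)
    e = np.exp(u) * fmask
    return e / e.sum(axis=-1, keepdims=True)


def masked_softmax_pool(vectors, scores, mask):
    """Definitional pooling: softmax ``scores`` over non-padding positions,
    weight the ``vectors``, and sum. Returns :class:`AttentionPooled`."""
    v = np.asarray(vectors, dtype=float)
    fmask = np.asarray(mask, dtype=float)
    if fmask.sum() == 0:
        raise ValueError("attention pooling over an all-padding mask")
    alpha = _masked_softmax(np.asarray(scores, dtype=float), fmask)
    pooled = (alpha[..., None] * v).sum(axis=-2)
    return AttentionPooled(weights=alpha, pooled=pooled)


class ReportClassifier(nn.Module):
    """Encoder + attention pooling + head for one category."""

    def __init__(self, vocabulary, config=None, category="abnormal"):
        if config is None:
            config = EncoderConfig(vocab_size=len(vocabulary))
        if config.vocab_size != len(vocabulary):
            raise ValueError("config.vocab_size must match the vocabulary")
        self.vocabulary = vocabulary
        self.config = config
        self.category = category
        self.encoder = TransformerEncoder(config)
        self.pool = AdditiveAttentionPool(config.d_model, config.d_attention,
                                          seed=config.seed)
        self.head = ClassifierHead(config.d_model, config.d_hidden,
                                   seed=config.seed)

    # -- forward / backward -------------------------------------------------

    def forward(self, ids, mask):
        h = self.encoder.forward(ids, mask)
        pooled, alpha = self.pool.forward(h, mask)
        logits = self.head.forward(pooled)
        self._alpha = alpha
        self._pooled = pooled
        return logits

    def backward(self, dlogits):
        dpooled = self.head.backward(dlogits)
        dh = self.pool.backward(dpooled)
        self.encoder.backward(dh)

    # -- inference ----------------------------------------------------------

    def _batch(self, texts, max_len=None):
        max_len = max_len or self.config.max_len
        toks = [normalise_and_tokenize(t, self.vocabulary, max_len=max_len)
                for t in texts]
        T = max(tk.length for tk in toks)
        ids = np.stack([tk.token_ids[:T] for tk in toks])
        mask = np.stack([tk.mask[:T] for tk in toks])
        return ids, mask

    def predict_proba(self, texts, batch_size=64):
        """Deterministic inference probabilities for raw report texts."""
        out = []
        for i in range(0, len(texts), batch_size):
            ids, mask = self._batch(texts[i:i + batch_size])
            out.append(nn.sigmoid(self.forward(ids, mask)))
        return np.concatenate(out) if out else np.empty(0)

    def pooled_embeddings(self, texts, batch_size=64):
        """Report-level pooled vectors (for 2-D visualisation export)."""
        out = []
        for i in range(0, len(texts), batch_size):
            ids, mask = self._batch(texts[i:i + batch_size])
            self.forward(ids, mask)
            out.append(self._pooled.copy())
        return np.vstack(out) if out else np.empty((0, self.config.d_model))


# -- operations on explicit pieces ------------------------------------------


def encode(tokens, encoder):
    """Contextual embeddings for one tokenized report."""
    ids = tokens.token_ids[None, :]
    mask = tokens.mask[None, :]
    h = encoder.forward(ids, mask)
    return TokenEmbeddings(vectors=h[0])


def attention_pool(emb, mask, pooler):
    """Apply a learned additive attention pooler to token embeddings."""
    vectors = emb.vectors if isinstance(emb, TokenEmbeddings) else np.asarray(emb)
    pooled, alpha = pooler.forward(vectors[None, ...] if vectors.ndim == 2 else vectors,
                                   np.atleast_2d(np.asarray(mask)))
    if vectors.ndim == 2:
        return AttentionPooled(weights=alpha[0], pooled=pooled[0])
    return AttentionPooled(weights=alpha, pooled=pooled)


def classify(pooled, head):
    """Probability that the pooled report vector describes the category."""
    p = np.asarray(pooled, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("pooled vector must be finite")
    if p.shape[-1] != head.lin1.W.value.shape[0]:
        raise ValueError("pooled vector dimension does not match the head")
    return nn.sigmoid(head.forward(p))


def attention_report(report, model):
    """Surface tokens of ``report`` with their attention weights.

    Returns an ordered list of ``(token, weight)`` pairs covering every
    model token (including the sequence-boundary tokens); weights sum to 1.
    """
    text = getattr(report, "text", report)
    words = word_tokenize(text)
    if not words:
        raise ValueError("cannot explain an empty report")
    tokens = normalise_and_tokenize(text, model.vocabulary,
                                    max_len=model.config.max_len)
    ids = tokens.token_ids[None, : tokens.length]
    mask = tokens.mask[None, : tokens.length]
    model.forward(ids, mask)
    alpha = model._alpha[0]
    from .preprocess import RESERVED_TOKENS

    pairs = []
    for i, a in zip(ids[0], alpha):
        tok = model.vocabulary.id_to_token[int(i)]
        if tok in RESERVED_TOKENS:
            continue
        pairs.append((tok, float(a)))
    total = sum(w for _, w in pairs)
    if total <= 0:
        raise ValueError("no attention mass on surface tokens")
    return [(t, w / total) for t, w in pairs]


def attention_to_csv(pairs, path):
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["token", "weight"])
        writer.writerows(pairs)


def attention_to_html(pairs):
    """Heatmap of attention weights as a standalone HTML snippet."""
    wmax = max(w for _, w in pairs) or 1.0
    spans = []
    for tok, w in pairs:
        alpha = w / wmax
        spans.append(
            f'<span style="background: rgba(178, 24, 43, {alpha:.3f})" '
            f'title="{w:.4f}">{_html.escape(tok)}</span>'
        )
    return "<div>" + " ".join(spans) + "</div>"


# -- persistence -------------------------------------------------------------


def save_model(model, path):
    """Single self-describing archive: parameter arrays + config echo."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    meta = {
        "config": asdict(model.config),
        "category": model.category,
        "vocab_mode": model.vocabulary.mode,
        "vocab_merges": model.vocabulary.merges,
        "vocab_tokens": model.vocabulary.content_tokens(),
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        state = [data[f"param_{i}"] for i in range(len(data.files) - 1)]
    vocab = Vocabulary(meta["vocab_tokens"], mode=meta["vocab_mode"],
                       merges=[tuple(m) for m in meta["vocab_merges"]])
    config = EncoderConfig(**meta["config"])
    model = ReportClassifier(vocab, config=config, category=meta["category"])
    model.load_state(state)
    return model
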