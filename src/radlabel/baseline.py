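"""Bag-of-words comparator: mean static word embeddings + N-gram counts
feeding a logistic regression.

This reproduces the classical report-classification recipe the attention
model is compared against. Its defining property — and its weakness on
reports full of distant negation — is context independence: the mean
embedding of a report depends only on its bag of words, so "no features
suggestive of acute stroke" and a genuinely positive mention contribute
nearly identical features.

Static embedding tables come in two flavours: fixed random vectors, or
PPMI co-occurrence factorised by truncated SVD (the classical static
embedding construction; like skip-gram, it factorises a pointwise mutual
information matrix).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .preprocess import word_tokenize

__all__ = [
    "BaselineFeatures", "random_embeddings", "svd_embeddings",
    "save_embeddings", "load_embeddings", "build_ngram_vectorizer",
    "featurize_baseline", "featurize_corpus", "fit_predict_baseline",
    "BaselineClassifier",
]


@dataclass(frozen=True)
class BaselineFeatures:
    """Dense mean-embedding block plus sparse N-gram counts."""

    mean_vec: np.ndarray
    ngram_counts: sp.spmatrix

    def stacked(self):
        return sp.hstack([sp.csr_matrix(self.mean_vec[None, :]),
                          self.ngram_counts], format="csr")


# -- static embedding tables -------------------------------------------------


def random_embeddings(tokens, d=100, seed=0):
    """Fixed random unit-scale vectors, one per token; deterministic in
    (tokens, seed) regardless of token order."""
    rng = np.random.default_rng(seed)
    table = {}
    for tok in sorted(set(tokens)):
        table[tok] = rng.normal(0.0, 1.0, size=d) / np.sqrt(d)
    return table


def svd_embeddings(texts, d=100, window=5, min_count=1, seed=0):
    """PPMI co-occurrence + truncated SVD static embeddings."""
    docs = [word_tokenize(t) for t in texts]
    counts = Counter(tok for doc in docs for tok in doc)
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    index = {t: i for i, t in enumerate(vocab)}
    rows, cols, vals = [], [], []
    for doc in docs:
        idx = [index[t] for t in doc if t in index]
        for i, a in enumerate(idx):
            for b in idx[max(0, i - window): i]:
                rows.extend((a, b))
                cols.extend((b, a))
                vals.extend((1.0, 1.0))
    n = len(vocab)
    C = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    total = C.sum()
    if total == 0:
        raise ValueError("no co-occurrences: corpus too small for SVD embeddings")
    row_sum = np.asarray(C.sum(axis=1)).ravel()
    C = C.tocoo()
    pmi = np.log((C.data * total) / (row_sum[C.row] * row_sum[C.col]))
    ppmi = sp.coo_matrix((np.maximum(pmi, 0.0), (C.row, C.col)), shape=(n, n)).tocsr()
    k = min(d, n - 1)
    svd = TruncatedSVD(n_components=k, random_state=seed)
    vecs = svd.fit_transform(ppmi)
    if k < d:
        vecs = np.hstack([vecs, np.zeros((n, d - k))])
    return {t: vecs[i] for t, i in index.items()}


def save_embeddings(table, path):
    """Conventional text format: token followed by its floats, one per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for tok in sorted(table):
            vals = " ".join(f"{x:.8g}" for x in table[tok])
            fh.write(f"{tok} {vals}\n")


def load_embeddings(path):
    table = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            table[parts[0]] = np.asarray([float(x) for x in parts[1:]])
    return table


# -- featurisation -----------------------------------------------------------


def build_ngram_vectorizer(texts, ngram_range=(1, 3), min_count=1):
    """Count vectorizer over word tokens with N-grams joined by spaces."""
    vec = CountVectorizer(tokenizer=word_tokenize, token_pattern=None,
                          lowercase=False, ngram_range=ngram_range,
                          min_df=min_count)
    vec.fit(texts)
    return vec


def mean_embedding(text, table):
    """Arithmetic mean of in-table token vectors; zero vector if every
    token is out of vocabulary (declared convention)."""
    d = len(next(iter(table.values())))
    vecs = [table[t] for t in word_tokenize(text) if t in table]
    if not vecs:
        return np.zeros(d)
    return np.mean(vecs, axis=0)


def featurize_baseline(text, table, vectorizer):
    if not table:
        raise ValueError("embedding table must be non-empty")
    return BaselineFeatures(
        mean_vec=mean_embedding(text, table),
        ngram_counts=vectorizer.transform([text]),
    )


def featurize_corpus(texts, table, vectorizer):
    if not table:
        raise ValueError("embedding table must be non-empty")
    means = np.vstack([mean_embedding(t, table) for t in texts]) if texts \
        else np.zeros((0, len(next(iter(table.values())))))
    return sp.hstack([sp.csr_matrix(means), vectorizer.transform(texts)],
                     format="csr")


# -- fitting -----------------------------------------------------------------


def _make_lr(penalty, seed):
    # penalty None -> unregularised (C = inf); a float sets the L2 strength C
    C = np.inf if penalty is None else float(penalty)
    return LogisticRegression(C=C, solver="lbfgs", max_iter=1000,
                              random_state=seed)


def fit_predict_baseline(train_features, train_labels, test_features, *,
                         penalty=None, seed=0):
    """Fit (unregularised by default) logistic regression; return test
    probabilities for the positive class."""
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    lr = _make_lr(penalty, seed)
    lr.fit(train_features, y)
    return lr.predict_proba(test_features)[:, 1]


class BaselineClassifier:
    """Convenience wrapper: texts in, probabilities out.

    ``embedding_mode`` is ``"random"``, ``"svd"``, or a ready-made table.
    """

    def __init__(self, embedding_mode="random", d_embed=100,
                 ngram_range=(1, 3), min_count=1, penalty=None, seed=0):
        self.embedding_mode = embedding_mode
        self.d_embed = d_embed
        self.ngram_range = ngram_range
        self.min_count = min_count
        self.penalty = penalty
        self.seed = seed

    def fit(self, texts, labels):
        if isinstance(self.embedding_mode, dict):
            self.table_ = self.embedding_mode
        elif self.embedding_mode == "random":
            toks = {t for text in texts for t in word_tokenize(text)}
            self.table_ = random_embeddings(toks, d=self.d_embed, seed=self.seed)
        elif self.embedding_mode == "svd":
            self.table_ = svd_embeddings(texts, d=self.d_embed, seed=self.seed)
        else:
            raise ValueError(f"unknown embedding mode {self.embedding_mode!r}")
        self.vectorizer_ = build_ngram_vectorizer(texts, self.ngram_range,
                                                  self.min_count)
        X = featurize_corpus(texts, self.table_, self.vectorizer_)
        y = np.asarray(labels)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self.lr_ = _make_lr(self.penalty, self.seed)
        self.lr_.fit(X, y)
        return self

    def predict_proba(self, texts):
        X = featurize_corpus(texts, self.table_, self.vectorizer_)
        return self.lr_.predict_proba(X)[:, 1]
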