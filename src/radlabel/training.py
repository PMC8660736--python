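"""End-to-end training of encoder + attention pooling + head.

The whole network is trained on the binary cross-entropy between predicted
probabilities and reference-standard report labels with the Adam
optimizer. A checkpoint is recorded after every epoch and the checkpoint
with the lowest validation loss is returned — later epochs that overfit
are discarded.

The dataclass default learning rate (1e-5) is the fine-tuning rate
appropriate when the encoder carries pretrained weights that a larger rate
would catastrophically overwrite. The desk-scale encoder is randomly
initialised, so :func:`desk_hyperparams` raises the rate to 1e-3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .model import EncoderConfig, ReportClassifier
from .preprocess import build_vocabulary, normalise_and_tokenize

__all__ = [
    "Hyperparams", "TrainingHistory", "LeakageError", "DegenerateDataWarning",
    "desk_hyperparams", "train_model",
]


class LeakageError(ValueError):
    """Train and validation sets share a patient."""


class DegenerateDataWarning(UserWarning):
    """Training labels contain a single class."""


@dataclass
class Hyperparams:
    learning_rate: float = 1e-5
    batch_size: int = 16
    max_epochs: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")


def desk_hyperparams(max_epochs=5, seed=0):
    """Defaults for the randomly initialised desk-scale encoder."""
    return Hyperparams(learning_rate=1e-3, batch_size=16,
                       max_epochs=max_epochs, seed=seed)


@dataclass
class TrainingHistory:
    """One entry per completed epoch, plus the selected checkpoint."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self):
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "selected": [i == self.best_epoch for i in range(len(self.train_loss))],
        })

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def _tokenize_all(texts, vocab, max_len):
    toks = [normalise_and_tokenize(t, vocab, max_len=max_len) for t in texts]
    ids = np.stack([t.token_ids for t in toks])
    mask = np.stack([t.mask for t in toks])
    lengths = np.array([t.length for t in toks])
    return ids, mask, lengths


def _batch_loss(model, ids, mask, lengths, y, train, optimizer=None):
    T = int(lengths.max())
    logits = model.forward(ids[:, :T], mask[:, :T])
    loss, dlogits = nn.bce_with_logits(logits, y)
    if train:
        model.zero_grad()
        model.backward(dlogits)
        optimizer.step()
    return loss


def train_model(train_frame, val_frame, category, hp=None, *,
                vocabulary=None, encoder_config=None, max_len=128,
                log=None):
    """Train one category classifier; return ``(model, history)``.

    ``train_frame`` / ``val_frame`` are report tables with at least
    ``text``, ``patient_id`` and the ``category`` label column (0/1). The
    two tables must not share a patient. The returned model carries the
    parameters of the epoch with minimum validation loss.
    """
    hp = hp or Hyperparams()
    if len(train_frame) == 0 or len(val_frame) == 0:
        raise ValueError("train and validation corpora must be non-empty")
    for frame, name in ((train_frame, "train"), (val_frame, "validation")):
        if category not in frame.columns:
            raise ValueError(f"category {category!r} missing from {name} labels")
    overlap = set(train_frame["patient_id"]) & set(val_frame["patient_id"])
    if overlap:
        raise LeakageError(f"patients in both train and validation: {sorted(overlap)[:5]}")
    if hp.max_epochs < 1:
        raise ValueError("max_epochs must be >= 1: nothing would be trained")

    y_train = train_frame[category].to_numpy(dtype=float)
    y_val = val_frame[category].to_numpy(dtype=float)
    if len(np.unique(y_train)) < 2:
        warnings.warn("training labels contain a single class",
                      DegenerateDataWarning, stacklevel=2)

    vocab = vocabulary or build_vocabulary(train_frame["text"].tolist())
    config = encoder_config or EncoderConfig(vocab_size=len(vocab),
                                             max_len=max_len, seed=hp.seed)
    model = ReportClassifier(vocab, config=config, category=category)
    optimizer = nn.Adam(model.params(), lr=hp.learning_rate)

    tr_ids, tr_mask, tr_len = _tokenize_all(train_frame["text"].tolist(), vocab,
                                            config.max_len)
    va_ids, va_mask, va_len = _tokenize_all(val_frame["text"].tolist(), vocab,
                                            config.max_len)

    history = TrainingHistory()
    best_state, best_val = None, np.inf
    n = len(train_frame)
    for epoch in range(hp.max_epochs):
        order = np.random.default_rng([hp.seed, epoch]).permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            loss = _batch_loss(model, tr_ids[idx], tr_mask[idx], tr_len[idx],
                               y_train[idx], train=True, optimizer=optimizer)
            epoch_loss += loss * len(idx)
            seen += len(idx)
        train_loss = epoch_loss / seen

        val_losses, val_seen = 0.0, 0
        for start in range(0, len(val_frame), 256):
            sl = slice(start, start + 256)
            loss = _batch_loss(model, va_ids[sl], va_mask[sl], va_len[sl],
                               y_val[sl], train=False)
            k = len(y_val[sl])
            val_losses += loss * k
            val_seen += k
        val_loss = val_losses / val_seen

        history.train_loss.append(float(train_loss))
        history.val_loss.append(float(val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state()
            history.best_epoch = epoch
        if log:
            log(f"epoch {epoch + 1}/{hp.max_epochs} "
                f"train_loss={train_loss:.4f} val_loss={val_loss:.4f}")

    model.load_state(best_state)
    return model, history
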