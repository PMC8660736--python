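"""Report normalisation and conversion to integer token-id sequences.

Only the steps a transformer encoder needs are applied: lower-casing and
tokenisation. No stop-word removal, stemming, or spelling correction.
Two vocabulary modes are supported: ``whitespace`` (word-level, used by the
desk-scale encoder and the baseline) and ``subword`` (byte-pair encoding
learned from the corpus).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PAD", "UNK", "CLS", "SEP", "RESERVED_TOKENS",
    "EmptyReportError", "TokenizedReport", "Vocabulary",
    "normalise", "word_tokenize", "build_vocabulary", "normalise_and_tokenize",
]

PAD, UNK, CLS, SEP = "[pad]", "[unk]", "[cls]", "[sep]"
RESERVED_TOKENS = (PAD, UNK, CLS, SEP)

_WORD_RE = re.compile(r"[a-z0-9]+|[^\sa-z0-9]")


class EmptyReportError(ValueError):
    """Raised when a report is empty after normalisation."""


def normalise(text):
    """Lower-case and collapse whitespace."""
    return " ".join(str(text).lower().split())


def word_tokenize(text):
    """Lower-cased word/punctuation tokens (deterministic)."""
    return _WORD_RE.findall(normalise(text))


@dataclass(frozen=True)
class TokenizedReport:
    """Integer token ids with a parallel padding mask.

    ``length`` counts real tokens (including the sequence-boundary tokens);
    positions beyond ``length`` carry the pad id and mask 0.
    """

    token_ids: np.ndarray
    mask: np.ndarray
    length: int

    def __post_init__(self):
        object.__setattr__(self, "token_ids", np.asarray(self.token_ids, dtype=np.int64))
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=np.int64))
        if self.token_ids.shape != self.mask.shape:
            raise ValueError("token_ids and mask must be parallel")
        if int(self.mask.sum()) != self.length:
            raise ValueError("length must equal sum(mask)")


class Vocabulary:
    """Bijective token <-> id map with reserved pad/unk/boundary entries."""

    def __init__(self, tokens, mode="whitespace", merges=None):
        self.mode = mode
        self.merges = list(merges) if merges else []
        self._tokens = list(RESERVED_TOKENS) + [
            t for t in tokens if t not in RESERVED_TOKENS
        ]
        self.token_to_id = {t: i for i, t in enumerate(self._tokens)}
        if len(self.token_to_id) != len(self._tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}
        self._merge_ranks = {tuple(m): r for r, m in enumerate(self.merges)}

    def __len__(self):
        return len(self._tokens)

    def __contains__(self, token):
        return token in self.token_to_id

    @property
    def pad_id(self):
        return self.token_to_id[PAD]

    @property
    def unk_id(self):
        return self.token_to_id[UNK]

    @property
    def cls_id(self):
        return self.token_to_id[CLS]

    @property
    def sep_id(self):
        return self.token_to_id[SEP]

    def content_tokens(self):
        return [t for t in self._tokens if t not in RESERVED_TOKENS]

    # -- encoding ----------------------------------------------------------

    def encode_word(self, word):
        """Ids for one surface word (one id in whitespace mode; possibly
        several in subword mode)."""
        if self.mode == "whitespace":
            return [self.token_to_id.get(word, self.unk_id)]
        pieces = _bpe_segment(word, self._merge_ranks)
        return [self.token_to_id.get(p, self.unk_id) for p in pieces]

    def decode(self, ids):
        """Surface tokens for a sequence of ids (reserved tokens skipped)."""
        out = []
        for i in ids:
            tok = self.id_to_token[int(i)]
            if tok in RESERVED_TOKENS:
                continue
            out.append(tok)
        if self.mode == "whitespace":
            return " ".join(out)
        return "".join(out).replace("▁", " ").strip()

    # -- persistence (two-column text file) ---------------------------------

    def save(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#mode\t{self.mode}\n")
            for pair in self.merges:
                fh.write(f"#merge\t{pair[0]} {pair[1]}\n")
            for tok, idx in sorted(self.token_to_id.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{idx}\n")

    @classmethod
    def load(cls, path):
        mode, merges, tokens = "whitespace", [], []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#mode\t"):
                    mode = line.split("\t", 1)[1]
                elif line.startswith("#merge\t"):
                    merges.append(tuple(line.split("\t", 1)[1].split(" ")))
                else:
                    tok, idx = line.split("\t")
                    tokens.append((int(idx), tok))
        tokens.sort()
        ordered = [t for _, t in tokens if t not in RESERVED_TOKENS]
        return cls(ordered, mode=mode, merges=merges)


# -- byte-pair encoding (subword mode) ---------------------------------------

_WORD_MARK = "▁"  # word-initial marker


def _bpe_segment(word, merge_ranks):
    symbols = [_WORD_MARK + word[0]] + list(word[1:]) if word else []
    while len(symbols) > 1:
        best, best_rank = None, None
        for i in range(len(symbols) - 1):
            pair = (symbols[i], symbols[i + 1])
            rank = merge_ranks.get(pair)
            if rank is not None and (best_rank is None or rank < best_rank):
                best, best_rank = i, rank
        if best is None:
            break
        symbols[best:best + 2] = [symbols[best] + symbols[best + 1]]
    return symbols


def _train_bpe(word_counts, vocab_size):
    words = {tuple([_WORD_MARK + w[0]] + list(w[1:])): c for w, c in word_counts.items() if w}
    symbols = set()
    for sym_word in words:
        symbols.update(sym_word)
    merges = []
    while len(symbols) < vocab_size:
        pair_counts = Counter()
        for sym_word, c in words.items():
            for i in range(len(sym_word) - 1):
                pair_counts[(sym_word[i], sym_word[i + 1])] += c
        if not pair_counts:
            break
        # deterministic tie-break: highest count, then lexicographic
        (a, b), _ = min(pair_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        merges.append((a, b))
        merged = a + b
        symbols.add(merged)
        new_words = {}
        for sym_word, c in words.items():
            out, i = [], 0
            while i < len(sym_word):
                if i + 1 < len(sym_word) and sym_word[i] == a and sym_word[i + 1] == b:
                    out.append(merged)
                    i += 2
                else:
                    out.append(sym_word[i])
                    i += 1
            new_words[tuple(out)] = new_words.get(tuple(out), 0) + c
        words = new_words
    return sorted(symbols), merges


# -- public builders ---------------------------------------------------------


def build_vocabulary(corpus, mode="whitespace", min_count=1, vocab_size=512):
    """Learn a :class:`Vocabulary` from reports (or raw strings).

    Whitespace mode keeps every lower-cased token seen at least
    ``min_count`` times; subword mode learns byte-pair merges until
    ``vocab_size`` symbols exist.
    """
    texts = [getattr(r, "text", r) for r in corpus]
    if not texts:
        raise ValueError("corpus must be non-empty")
    counts = Counter()
    for t in texts:
        counts.update(word_tokenize(t))
    if mode == "whitespace":
        kept = sorted(t for t, c in counts.items() if c >= min_count)
        return Vocabulary(kept, mode="whitespace")
    if mode == "subword":
        symbols, merges = _train_bpe(counts, vocab_size)
        return Vocabulary(symbols, mode="subword", merges=merges)
    raise ValueError(f"unknown vocabulary mode {mode!r}")


def normalise_and_tokenize(text, vocabulary, max_len=512, truncate="tail"):
    """Lower-case, tokenize and pad one report to ``max_len`` ids.

    Boundary tokens are always retained; ``truncate='tail'`` drops tokens
    from the end of over-long reports (findings sentences dominate early,
    conclusions repeat them late), ``'head'`` drops from the start.
    """
    words = word_tokenize(text)
    if not words:
        raise EmptyReportError("report is empty after normalisation")
    ids = []
    for w in words:
        ids.extend(vocabulary.encode_word(w))
    budget = max_len - 2
    if budget < 1:
        raise ValueError("max_len must allow at least one content token")
    if len(ids) > budget:
        ids = ids[:budget] if truncate == "tail" else ids[-budget:]
    ids = [vocabulary.cls_id] + ids + [vocabulary.sep_id]
    length = len(ids)
    pad = [vocabulary.pad_id] * (max_len - length)
    mask = [1] * length + [0] * (max_len - length)
    return TokenizedReport(
        token_ids=np.asarray(ids + pad), mask=np.asarray(mask), length=length
    )
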